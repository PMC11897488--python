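"""Persistent homology of weighted graphs under a sublevel filter.

The filter assigns each edge its (optionally transformed) weight and each
vertex the minimum over its incident edge values, so vertices always enter
the sublevel filtration no later than their edges. Two diagrams are computed:

* the 0-th ordinary diagram Dg0: births and deaths of connected components
  in the sublevel filtration (union-find sweep with the elder rule), plus one
  essential (birth, +inf) class per connected component;
* the 1-st extended diagram ExDg1: one point per independent cycle, with
  birth >= death. A cycle class is born in the ascending (sublevel)
  filtration when its last edge appears and dies in the descending
  (superlevel, relative) part; for a lone cycle this is simply (max, min)
  filter value along the loop, but when cycles share edges the death is
  determined by the best homologous representative, so the diagram is
  computed exactly by reducing the boundary matrix of the coned extended
  filtration (ascending sweep of vertices and edges, then a cone over every
  simplex in descending order). Columns are bit sets; the reduction is
  deterministic under the canonical (value, dimension, lexicographic) order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import WeightedGraph
from .diagram import EXTENDED, ORDINARY, PersistenceDiagram

TRANSFORMS = ("identity", "one_minus_w")


@dataclass
class GraphFilter:
    """Filter values on the vertices and edges of a weighted graph."""

    nodes: list
    edge_value: dict   # canonical (i, j) -> f(e)
    vertex_value: dict  # v -> f(v)
    transform: str = "identity"


def build_filter(graph: WeightedGraph, transform: str = "identity") -> GraphFilter:
    """Edge values = transform(w); vertex values = min incident edge value.

    Isolated vertices carry f(v) = 0 by convention. ``one_minus_w`` maps a
    correlation weight w to 1 - w so that strong correlations enter the
    sublevel filtration first.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    graph.validate()
    fe = {}
    for (a, b), w in graph.edges.items():
        fe[(a, b)] = float(1.0 - w) if transform == "one_minus_w" else float(w)
    fv = {v: 0.0 for v in graph.nodes}
    seen = {v: False for v in graph.nodes}
    for (a, b), val in fe.items():
        for v in (a, b):
            fv[v] = val if not seen[v] else min(fv[v], val)
            seen[v] = True
    return GraphFilter(nodes=list(graph.nodes), edge_value=fe,
                       vertex_value=fv, transform=transform)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _sorted_edges(filt: GraphFilter):
    pos = {v: i for i, v in enumerate(filt.nodes)}
    return sorted(filt.edge_value.items(),
                  key=lambda kv: (kv[1], pos[kv[0][0]], pos[kv[0][1]]))


def ordinary_persistence_0(filt: GraphFilter,
                           keep_zero: bool = False) -> PersistenceDiagram:
    """0-th ordinary persistence diagram of the sublevel filtration.

    Edges are swept in non-decreasing filter value; at each merge the
    component with the larger birth dies (elder rule; ties broken by the
    component whose minimum vertex is lexicographically larger dying). Every
    connected component contributes one essential (min birth, +inf) pair.
    Zero-persistence pairs are dropped unless ``keep_zero``.
    """
    uf = _UnionFind(filt.nodes)
    birth = {v: filt.vertex_value[v] for v in filt.nodes}
    minvert = {v: v for v in filt.nodes}
    pairs = []
    for (a, b), val in _sorted_edges(filt):
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        # component with larger birth dies; tie -> larger min vertex dies
        if (birth[ra], str(minvert[ra])) > (birth[rb], str(minvert[rb])):
            dying, surviving = ra, rb
        else:
            dying, surviving = rb, ra
        if keep_zero or val > birth[dying]:
            pairs.append((birth[dying], val))
        uf.parent[dying] = surviving
        birth[surviving] = min(birth[surviving], birth[dying])
        minvert[surviving] = min(minvert[surviving], minvert[dying],
                                 key=str)
    roots = {uf.find(v) for v in filt.nodes}
    pairs.extend((birth[r], np.inf) for r in roots)
    return PersistenceDiagram(0, pairs, ORDINARY)


def extended_persistence_1(filt: GraphFilter) -> PersistenceDiagram:
    """1-st extended persistence diagram of the graph filter.

    One (birth, death) point per independent cycle, birth >= death: the
    ascending sublevel sweep creates each cycle class at the value of the
    edge completing it; the class dies in the relative (superlevel) part at
    the value recorded by the coned-filtration reduction. For a single
    isolated loop this reduces to (max, min) filter value along the loop.
    """
    pos = {v: i for i, v in enumerate(filt.nodes)}
    # superlevel vertex value: max incident edge value (0 when isolated)
    desc_v = {v: 0.0 for v in filt.nodes}
    seen = {v: False for v in filt.nodes}
    for (a, b), val in filt.edge_value.items():
        for v in (a, b):
            desc_v[v] = val if not seen[v] else max(desc_v[v], val)
            seen[v] = True

    # global simplex order: ascending part, apex, descending cone part
    asc = [(filt.vertex_value[v], 0, ("v", v)) for v in filt.nodes]
    asc += [(val, 1, ("e", e)) for e, val in filt.edge_value.items()]
    asc.sort(key=lambda s: (s[0], s[1], _canon(s[2], pos)))
    desc = [(desc_v[v], 1, ("cv", v)) for v in filt.nodes]
    desc += [(val, 2, ("ce", e)) for e, val in filt.edge_value.items()]
    desc.sort(key=lambda s: (-s[0], s[1], _canon(s[2], pos)))
    order = asc + [(0.0, 0, ("apex", None))] + desc
    index = {key: i for i, (_, _, key) in enumerate(order)}
    apex = index[("apex", None)]

    pivot_owner: dict[int, int] = {}
    pairs = []
    for j, (val, _, (tag, obj)) in enumerate(order):
        if tag in ("v", "apex"):
            continue
        if tag == "e":
            a, b = obj
            col = (1 << index[("v", a)]) | (1 << index[("v", b)])
        elif tag == "cv":
            col = (1 << index[("v", obj)]) | (1 << apex)
        else:  # cone triangle over edge obj
            a, b = obj
            col = ((1 << index[("e", obj)])
                   | (1 << index[("cv", a)]) | (1 << index[("cv", b)]))
        while col:
            low = col.bit_length() - 1
            other = pivot_owner.get(low)
            if other is None:
                break
            col ^= other
        if col:
            pivot_owner[low] = col
            birth_tag = order[low][2][0]
            if tag == "ce" and birth_tag == "e":
                pairs.append((order[low][0], val))
    return PersistenceDiagram(1, pairs, EXTENDED)


def _canon(key, pos):
    tag, obj = key
    if obj is None:
        return (-1, -1)
    if tag in ("v", "cv"):
        return (pos[obj], -1)
    return (pos[obj[0]], pos[obj[1]])
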