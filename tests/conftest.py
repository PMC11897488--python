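import numpy as np
import pytest

from topobrain.connectivity import WeightedGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_graph(edges: dict, extra_nodes=()) -> WeightedGraph:
    """Graph from an edge dict; nodes ordered alphabetically."""
    nodes = sorted({v for e in edges for v in e} | set(extra_nodes))
    pos = {v: i for i, v in enumerate(nodes)}
    canon = {}
    for (a, b), w in edges.items():
        if pos[a] > pos[b]:
            a, b = b, a
        canon[(a, b)] = float(w)
    return WeightedGraph(nodes=nodes, edges=canon)


@pytest.fixture
def fig_style_path_graph():
    """4-vertex graph with edges a-b:1, c-d:2, b-c:4 (two merging components)."""
    return make_graph({("a", "b"): 1.0, ("c", "d"): 2.0, ("b", "c"): 4.0})


def random_weighted_graph(rng, max_nodes=10, p_edge=0.5, integer=True):
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w = float(rng.integers(1, 8)) if integer else float(rng.random())
                edges[(nodes[i], nodes[j])] = w
    return WeightedGraph(nodes=nodes, edges=edges)
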