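"""Independent brute-force oracles used only by the test suite.

Everything here is written as a direct transcription of textbook definitions
— full boundary-matrix reduction over GF(2) with dense numpy columns,
exhaustive matching enumeration, regression residuals — deliberately sharing
no code with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


# ------------------------------------------------------------------ rips

def naive_rips_diagrams(points: np.ndarray, max_dim: int,
                        max_scale: float | None = None):
    """Textbook persistence: enumerate every simplex, reduce one big matrix.

    Returns {dim: list of (birth, death)} with death=inf for essential
    classes and zero-persistence pairs dropped.
    """
    n = len(points)
    dist = squareform(pdist(points))
    if max_scale is None:
        max_scale = float(np.min(np.max(dist, axis=1))) if n > 1 else 0.0

    simplices = []  # (filtration value, dim, vertex tuple)
    for d in range(0, min(max_dim + 1, n - 1) + 1):
        for verts in combinations(range(n), d + 1):
            val = max((dist[a, b] for a, b in combinations(verts, 2)),
                      default=0.0)
            if val <= max_scale:
                simplices.append((val, d, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}

    N = len(simplices)
    cols = np.zeros((N, N), dtype=bool)
    for j, (_, d, verts) in enumerate(simplices):
        if d == 0:
            continue
        for face in combinations(verts, d):
            cols[index[face], j] = True

    low_of = {}
    pairs = []
    paired = set()
    for j in range(N):
        while cols[:, j].any():
            low = int(np.flatnonzero(cols[:, j])[-1])
            if low not in low_of:
                low_of[low] = j
                pairs.append((low, j))
                paired.add(low)
                paired.add(j)
                break
            cols[:, j] ^= cols[:, low_of[low]]

    out = {d: [] for d in range(max_dim + 1)}
    for i, j in pairs:
        birth, d, _ = simplices[i]
        death = simplices[j][0]
        if d <= max_dim and death > birth:
            out[d].append((birth, death))
    for j, (val, d, _) in enumerate(simplices):
        if d <= max_dim and j not in paired:
            out[d].append((val, np.inf))
    for d in out:
        out[d].sort()
    return out


# ------------------------------------------------- extended persistence

def extended_persistence_oracle(nodes, edge_values: dict):
    """ExDg1 of a graph filter by reduction of the coned extended filtration.

    The ascending part inserts vertices (at their min incident edge value)
    and edges (at their value) in increasing order; the descending part then
    cones every simplex over a dummy apex in decreasing order of the
    superlevel values (vertices at their max incident edge value). Reduction
    pairs each essential ascending cycle (an unpaired edge) with a cone
    triangle; the pair of filter values is the (birth >= death) extended
    point. Returns a sorted list of (birth, death).
    """
    nodes = list(nodes)
    asc_v = {v: 0.0 for v in nodes}
    desc_v = {v: 0.0 for v in nodes}
    seen = set()
    for (a, b), val in edge_values.items():
        for v in (a, b):
            if v in seen:
                asc_v[v] = min(asc_v[v], val)
                desc_v[v] = max(desc_v[v], val)
            else:
                asc_v[v] = desc_v[v] = val
                seen.add(v)

    asc = [ (asc_v[v], 0, ("v", v)) for v in nodes ]
    asc += [ (val, 1, ("e", e)) for e, val in edge_values.items() ]
    asc.sort(key=lambda s: (s[0], s[1], str(s[2])))

    desc = [ (desc_v[v], 1, ("cv", v)) for v in nodes ]
    desc += [ (val, 2, ("ce", e)) for e, val in edge_values.items() ]
    desc.sort(key=lambda s: (-s[0], s[1], str(s[2])))

    order = asc + [(0.0, 1, ("apex", None))] + desc
    index = {s[2]: i for i, s in enumerate(order)}

    N = len(order)
    cols = np.zeros((N, N), dtype=bool)
    apex_col = len(asc)
    for j, (_, _, (tag, obj)) in enumerate(order):
        if tag == "v" or tag == "apex":
            continue
        if tag == "e":
            a, b = obj
            cols[index[("v", a)], j] = True
            cols[index[("v", b)], j] = True
        elif tag == "cv":
            cols[index[("v", obj)], j] = True
            # the apex is a vertex of every cone simplex; the cone edge
            # (apex, v) has boundary {apex, v}
            cols[apex_col, j] = True
        else:  # cone triangle over edge obj = (a, b)
            a, b = obj
            cols[index[("e", obj)], j] = True
            cols[index[("cv", a)], j] = True
            cols[index[("cv", b)], j] = True

    low_of = {}
    pairs = []
    for j in range(N):
        while cols[:, j].any():
            low = int(np.flatnonzero(cols[:, j])[-1])
            if low not in low_of:
                low_of[low] = j
                pairs.append((low, j))
                break
            cols[:, j] ^= cols[:, low_of[low]]

    points = []
    for i, j in pairs:
        vi, di, (tag_i, _) = order[i]
        vj, dj, (tag_j, _) = order[j]
        if tag_i == "e" and tag_j == "ce":
            points.append((vi, vj))
    points.sort()
    return points


# ------------------------------------------------------------ matchings

def _linf(p, q):
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def brute_wasserstein(X, Y, q: float = 1.0) -> float:
    """Exhaustive minimal matching cost between two small diagrams.

    Points are (birth, death) tuples; unmatched points pay their diagonal
    projection cost. Pure recursion over all partial matchings.
    """
    X = [tuple(p) for p in X]
    Y = [tuple(p) for p in Y]

    def diag(p):
        return abs(p[1] - p[0]) / 2.0

    def rec(xs, ys):
        if not xs:
            return sum(diag(y) ** q for y in ys)
        x, rest = xs[0], xs[1:]
        best = diag(x) ** q + rec(rest, ys)
        for k, y in enumerate(ys):
            cost = _linf(x, y) ** q + rec(rest, ys[:k] + ys[k + 1:])
            best = min(best, cost)
        return best

    return rec(X, Y) ** (1.0 / q)


def brute_bottleneck(X, Y) -> float:
    """Exhaustive bottleneck (L-infinity) matching distance."""
    X = [tuple(p) for p in X]
    Y = [tuple(p) for p in Y]

    def diag(p):
        return abs(p[1] - p[0]) / 2.0

    def rec(xs, ys):
        if not xs:
            return max((diag(y) for y in ys), default=0.0)
        x, rest = xs[0], xs[1:]
        best = max(diag(x), rec(rest, ys))
        for k, y in enumerate(ys):
            cost = max(_linf(x, y), rec(rest, ys[:k] + ys[k + 1:]))
            best = min(best, cost)
        return best

    return rec(X, Y)


# ------------------------------------------------- partial correlation

def residual_partial_correlation(X: np.ndarray) -> np.ndarray:
    """Partial correlation by explicit regression residuals.

    For each pair (i, j), regress both series on all remaining series (plus
    an intercept) and correlate the residuals.
    """
    R, T = X.shape
    out = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            others = [k for k in range(R) if k not in (i, j)]
            Z = np.column_stack([np.ones(T), X[others].T])
            beta_i, *_ = np.linalg.lstsq(Z, X[i], rcond=None)
            beta_j, *_ = np.linalg.lstsq(Z, X[j], rcond=None)
            ri = X[i] - Z @ beta_i
            rj = X[j] - Z @ beta_j
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out
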