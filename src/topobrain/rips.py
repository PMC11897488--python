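"""Vietoris-Rips persistent homology of point clouds.

The Vietoris-Rips complex at scale eps contains a simplex whenever all
pairwise distances among its vertices are at most eps; sweeping eps yields a
filtration whose persistent homology is computed here over the two-element
field by boundary-matrix reduction. Columns are represented as Python
integers used as bit sets, reduced dimension by dimension; the filtration
order is (value, dimension, lexicographic vertex order), which makes the
reduction deterministic.

H0 deaths are the single-linkage merge scales; one essential H0 class remains
at full scale. By default the filtration is capped at the enclosing radius
(the smallest r such that some point is within r of all others), past which
the complex is a cone and no new homology appears; classes still alive at the
cap are reported as essential.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .diagram import ORDINARY, PersistenceDiagram
from .embedding import PointCloud


class SimplexBudgetError(RuntimeError):
    """Complex too large; lower max_points or max_scale."""


@dataclass
class RipsOptions:
    """Options for :func:`rips_diagrams`.

    max_scale "enclosing" caps the filtration at the enclosing radius.
    max_points defaults to 60 when max_dim == 2 (3-simplex enumeration is the
    budget-limiting step) and is unlimited otherwise; larger clouds are
    reduced by deterministic farthest-point subsampling.
    """

    max_dim: int = 1
    max_scale: float | str = "enclosing"
    metric: str = "euclidean"
    max_points: int | None = None
    subsample_seed: int = 0
    simplex_budget: int = 2_000_000

    def validate(self) -> None:
        if self.max_dim not in (0, 1, 2):
            raise ValueError("max_dim must be 0, 1, or 2")
        if self.max_scale != "enclosing" and not float(self.max_scale) > 0:
            raise ValueError("max_scale must be positive or 'enclosing'")

    def effective_max_points(self) -> int | None:
        if self.max_points is not None:
            return self.max_points
        return 60 if self.max_dim == 2 else None


def subsample(cloud: PointCloud, max_points: int, seed: int = 0) -> PointCloud:
    """Deterministic farthest-point subsample after a seeded random start.

    Identity when the cloud already has at most ``max_points`` points. The
    selected points keep their original order.
    """
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    pts = cloud.points
    n = pts.shape[0]
    if n <= max_points:
        return cloud
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = [start]
    mindist = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(max_points - 1):
        nxt = int(np.argmax(mindist))  # ties -> lowest index
        chosen.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(pts - pts[nxt], axis=1))
    chosen.sort()
    return PointCloud(points=pts[chosen].copy(), M=cloud.M, tau=cloud.tau,
                      source=cloud.source)


def enclosing_radius(dist: np.ndarray) -> float:
    """Smallest r with some point within distance r of every other point."""
    return float(np.min(np.max(dist, axis=1)))


def _enumerate_simplices(dist: np.ndarray, max_scale: float, top_dim: int,
                         budget: int):
    """Simplices per dimension with diameter filtration values.

    Returns a list ``simp[d] = (filt_values, vertex_tuples)`` for
    d = 0..top_dim, each sorted by (value, lexicographic vertices).
    """
    n = dist.shape[0]
    verts0 = [(i,) for i in range(n)]
    out = [(np.zeros(n), verts0)]
    total = n
    for d in range(1, top_dim + 1):
        combos = np.array(list(combinations(range(n), d + 1)), dtype=np.intp)
        if combos.size == 0:
            out.append((np.empty(0), []))
            continue
        vals = np.zeros(len(combos))
        for a, b in combinations(range(d + 1), 2):
            np.maximum(vals, dist[combos[:, a], combos[:, b]], out=vals)
        keep = vals <= max_scale
        combos, vals = combos[keep], vals[keep]
        total += len(combos)
        if total > budget:
            raise SimplexBudgetError(
                f"complex exceeds simplex budget ({budget}); "
                "reduce max_points or max_scale"
            )
        order = np.lexsort((*combos.T[::-1], vals))
        combos, vals = combos[order], vals[order]
        out.append((vals, [tuple(row) for row in combos.tolist()]))
    return out


def _reduce_block(face_index: dict, faces_destroyed: np.ndarray,
                  face_filt: np.ndarray, simps: list, filt: np.ndarray,
                  dim: int):
    """Reduce the dim-d boundary block; returns (pairs, creator flags).

    Columns are bit sets over the positions of the (d-1)-simplices; the
    standard left-to-right reduction pairs each nonzero reduced column's
    lowest one (the dying face) with the current simplex.
    """
    pivot_owner: dict[int, int] = {}
    creators = np.zeros(len(simps), dtype=bool)
    pairs = []
    for j, verts in enumerate(simps):
        col = 0
        for face in combinations(verts, dim):
            col |= 1 << face_index[face]
        while col:
            low = col.bit_length() - 1
            other = pivot_owner.get(low)
            if other is None:
                break
            col ^= other
        if col:
            pivot_owner[low] = col
            faces_destroyed[low] = True
            pairs.append((face_filt[low], filt[j]))
        else:
            creators[j] = True
    return pairs, creators


def rips_diagrams(cloud: PointCloud, opts: RipsOptions | None = None
                  ) -> list[PersistenceDiagram]:
    """Persistence diagrams H0..H_max_dim of a point cloud.

    Zero-persistence pairs (birth == death) are dropped. Classes alive at
    max_scale are reported with death = +inf; with the default enclosing-
    radius cap, H0 has exactly one essential class.
    """
    opts = opts or RipsOptions()
    opts.validate()
    if len(cloud) == 0:
        raise ValueError("point cloud is empty")
    mp = opts.effective_max_points()
    if mp is not None:
        cloud = subsample(cloud, mp, opts.subsample_seed)
    dist = squareform(pdist(cloud.points, metric=opts.metric))
    if opts.max_scale == "enclosing":
        max_scale = enclosing_radius(dist) if len(cloud) > 1 else 0.0
    else:
        max_scale = float(opts.max_scale)

    top_dim = min(opts.max_dim + 1, len(cloud) - 1)
    blocks = _enumerate_simplices(dist, max_scale, top_dim, opts.simplex_budget)

    creators = [np.ones(len(blocks[0][1]), dtype=bool)]
    destroyed = [np.zeros(len(b[1]), dtype=bool) for b in blocks]
    pairs_per_dim: dict[int, list] = {d: [] for d in range(opts.max_dim + 1)}
    for d in range(1, len(blocks)):
        face_filt, face_simps = blocks[d - 1]
        face_index = {v: i for i, v in enumerate(face_simps)}
        filt, simps = blocks[d]
        pairs, created = _reduce_block(
            face_index, destroyed[d - 1], face_filt, simps, filt, d
        )
        creators.append(created)
        pairs_per_dim[d - 1].extend(pairs)

    diagrams = []
    for d in range(opts.max_dim + 1):
        finite = [(b, dth) for b, dth in pairs_per_dim[d] if dth > b]
        if d < len(blocks):
            filt = blocks[d][0]
            essential = creators[d] & ~destroyed[d]
            finite += [(float(filt[i]), np.inf) for i in np.flatnonzero(essential)]
        diagrams.append(PersistenceDiagram(d, finite, ORDINARY))
    return diagrams
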