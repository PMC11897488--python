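"""q-Wasserstein distances between persistence diagrams and distance matrices.

The q-Wasserstein distance matches points of diagram X to points of diagram Y
or to their orthogonal projections on the diagonal (the completion that makes
unequal cardinalities well-defined), with the L-infinity ground metric; the
distance is the q-th root of the minimal total q-th-power cost. The matching
is solved exactly as a linear assignment problem.

Two matrix constructions are provided: inter-subject (one diagram per
subject, a fixed network) and inter-ROI (one diagram per ROI, a fixed
subject).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .diagram import PersistenceDiagram

INF_POLICIES = ("truncate_to_max_finite", "drop_essential")


@dataclass
class WassersteinOptions:
    """Order q >= 1, essential-point policy, and matching backend.

    ``truncate_to_max_finite`` replaces infinite deaths by the largest finite
    death across the two diagrams being compared (falling back to the largest
    birth when neither has a finite death), keeping distances finite and
    comparable; ``drop_essential`` removes infinite-death points.
    """

    q: float = 1.0
    infinite_death_policy: str = "truncate_to_max_finite"
    matching: str = "exact_assignment"

    def validate(self) -> None:
        if not self.q >= 1:
            raise ValueError("q must be >= 1")
        if self.infinite_death_policy not in INF_POLICIES:
            raise ValueError(f"policy must be one of {INF_POLICIES}")
        if self.matching not in ("exact_assignment", "brute_force"):
            raise ValueError("matching must be exact_assignment or brute_force")


def _finite_pairs(X: PersistenceDiagram, Y: PersistenceDiagram,
                  policy: str) -> tuple[np.ndarray, np.ndarray]:
    px, py = X.pairs, Y.pairs
    if policy == "drop_essential":
        return px[np.isfinite(px[:, 1])], py[np.isfinite(py[:, 1])]
    deaths = np.concatenate([px[:, 1], py[:, 1]])
    finite = deaths[np.isfinite(deaths)]
    if finite.size:
        cap = finite.max()
    else:
        births = np.concatenate([px[:, 0], py[:, 0]])
        cap = births.max() if births.size else 0.0
    px, py = px.copy(), py.copy()
    px[np.isinf(px[:, 1]), 1] = cap
    py[np.isinf(py[:, 1]), 1] = cap
    return px, py


def _diag_cost(p: np.ndarray) -> np.ndarray:
    """L-infinity distance of each point to its diagonal projection."""
    return np.abs(p[:, 1] - p[:, 0]) / 2.0


def _assignment_cost(px: np.ndarray, py: np.ndarray, q: float) -> float:
    n, m = len(px), len(py)
    if n == 0 and m == 0:
        return 0.0
    big = np.inf
    C = np.zeros((n + m, n + m))
    if n and m:
        dx = np.abs(px[:, None, :] - py[None, :, :]).max(axis=2)
        C[:n, :m] = dx ** q
    C[:n, m:] = big
    C[:n, m:][np.arange(n), np.arange(n)] = _diag_cost(px) ** q
    C[n:, :m] = big
    C[n:, :m][np.arange(m), np.arange(m)] = _diag_cost(py) ** q
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum())


def _brute_force_cost(px: np.ndarray, py: np.ndarray, q: float) -> float:
    n, m = len(px), len(py)
    dgx, dgy = _diag_cost(px) ** q, _diag_cost(py) ** q
    best = np.inf
    for k in range(0, min(n, m) + 1):
        for xs in itertools.combinations(range(n), k):
            rest_x = dgx.sum() - dgx[list(xs)].sum() if k else dgx.sum()
            for ys in itertools.permutations(range(m), k):
                cost = rest_x + dgy.sum() - (dgy[list(ys)].sum() if k else 0.0)
                for xi, yi in zip(xs, ys):
                    cost += np.abs(px[xi] - py[yi]).max() ** q
                best = min(best, cost)
    return float(best)


def wasserstein(X: PersistenceDiagram, Y: PersistenceDiagram,
                opts: WassersteinOptions | None = None) -> float:
    """q-Wasserstein distance between two diagrams of equal dimension/kind."""
    opts = opts or WassersteinOptions()
    opts.validate()
    if X.dimension != Y.dimension:
        raise ValueError(
            f"dimension mismatch: {X.dimension} vs {Y.dimension}"
        )
    if X.kind != Y.kind:
        raise ValueError(f"kind mismatch: {X.kind!r} vs {Y.kind!r}")
    px, py = _finite_pairs(X, Y, opts.infinite_death_policy)
    if opts.matching == "brute_force":
        total = _brute_force_cost(px, py, opts.q)
    else:
        total = _assignment_cost(px, py, opts.q)
    return total ** (1.0 / opts.q)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over subjects or ROIs."""

    values: np.ndarray
    axis: str  # "subjects" or "rois"
    labels: list
    context: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-9) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if np.max(np.abs(v - v.T), initial=0.0) > tol:
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def submatrix(self, labels) -> np.ndarray:
        idx = [self.labels.index(x) for x in labels]
        return self.values[np.ix_(idx, idx)]


def _pairwise_matrix(diagrams: dict, opts: WassersteinOptions,
                     axis: str, expected=None, context=None) -> DistanceMatrix:
    opts = opts or WassersteinOptions()
    if expected is not None:
        missing = [x for x in expected if x not in diagrams]
        if missing:
            raise KeyError(f"missing {axis} diagrams: {missing}")
        labels = list(expected)
    else:
        labels = list(diagrams)
    if labels:
        first = diagrams[labels[0]]
        for lab in labels[1:]:
            d = diagrams[lab]
            if d.dimension != first.dimension or d.kind != first.kind:
                raise ValueError(
                    f"diagram for {lab!r} has (dim, kind) "
                    f"({d.dimension}, {d.kind}), expected "
                    f"({first.dimension}, {first.kind})"
                )
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = wasserstein(diagrams[labels[i]], diagrams[labels[j]], opts)
            values[i, j] = values[j, i] = w
    mat = DistanceMatrix(values, axis, labels, dict(context or {}))
    mat.validate()
    return mat


def inter_subject_matrix(diagrams: dict, opts: WassersteinOptions | None = None,
                         subjects=None, context=None) -> DistanceMatrix:
    """Subjects x subjects Wasserstein matrix for one (network, dim, kind)."""
    return _pairwise_matrix(diagrams, opts or WassersteinOptions(),
                            "subjects", subjects, context)


def inter_roi_matrix(diagrams: dict, opts: WassersteinOptions | None = None,
                     rois=None, context=None) -> DistanceMatrix:
    """ROIs x ROIs Wasserstein matrix for one subject."""
    return _pairwise_matrix(diagrams, opts or WassersteinOptions(),
                            "rois", rois, context)


def write_distance_matrix(mat: DistanceMatrix, path) -> None:
    """TSV with a label header row/column plus a JSON context sidecar."""
    mat.validate()
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(map(str, mat.labels)) + "\n")
        for lab, row in zip(mat.labels, mat.values):
            fh.write(str(lab) + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")
    sidecar = {"axis": mat.axis, "context": mat.context}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t")[1:] for line in fh]
    values = np.array(rows, dtype=float)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    mat = DistanceMatrix(values, sidecar["axis"], labels, sidecar["context"])
    mat.validate()
    return mat
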