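"""Positively correlated connectivity graphs from ROI time series.

Edges of the functional-connectivity graph are kept only where both the
marginal (Pearson) and the partial correlation between two ROIs are strictly
positive: the marginal correlation can be inflated by shared drivers, while a
positive partial correlation — the off-diagonal of the normalized precision
matrix — indicates a direct association after controlling for all other ROIs.
A zero partial correlation indicates absence of direct connectivity, hence
the strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.covariance import LedoitWolf, shrunk_covariance


class ZeroVarianceError(ValueError):
    """An ROI series has zero variance."""


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with unit diagonal over an ROI order."""

    values: np.ndarray
    roi_order: list
    flavor: str  # "marginal" or "partial"

    def validate(self, tol: float = 1e-10) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.roi_order):
            raise ValueError("matrix shape does not match roi_order")
        if np.max(np.abs(v - v.T)) > tol:
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=tol):
            raise ValueError("correlation matrix diagonal must be 1")


@dataclass
class WeightedGraph:
    """Undirected graph with strictly positive edge weights.

    Edges are keyed by canonical (i, j) node-label pairs with i preceding j
    in ``nodes`` order.
    """

    nodes: list
    edges: dict = field(default_factory=dict)

    def validate(self) -> None:
        pos = {n: i for i, n in enumerate(self.nodes)}
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if pos[a] >= pos[b]:
                raise ValueError(f"edge ({a!r}, {b!r}) not in canonical order")
            if not w > 0:
                raise ValueError(f"edge ({a!r}, {b!r}) weight must be > 0")

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g

    def __len__(self) -> int:
        return len(self.nodes)


def _check_input(X: np.ndarray, roi_order) -> tuple[np.ndarray, list]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an ROIs x time matrix")
    if roi_order is None:
        roi_order = [f"roi{i}" for i in range(X.shape[0])]
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = roi_order[int(np.argmax(sd == 0))]
        raise ZeroVarianceError(f"zero-variance ROI: {bad!r}")
    return X, list(roi_order)


def marginal_correlation(X, roi_order=None) -> CorrelationMatrix:
    """Pairwise Pearson (marginal) correlation of an ROIs x time matrix."""
    X, roi_order = _check_input(X, roi_order)
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    out = CorrelationMatrix(r, roi_order, "marginal")
    out.validate()
    return out


def partial_correlation(X, roi_order=None, shrinkage="auto") -> CorrelationMatrix:
    """Partial correlation via the (shrinkage-regularized) precision matrix.

    rho_ij = -P_ij / sqrt(P_ii * P_jj) with P the inverse covariance.
    ``shrinkage`` is "auto" (Ledoit-Wolf), or a value in [0, 1); 0 uses the
    raw empirical covariance, which must then be invertible.
    """
    X, roi_order = _check_input(X, roi_order)
    data = X.T  # samples x variables
    if shrinkage == "auto":
        cov = LedoitWolf(assume_centered=False).fit(data).covariance_
    else:
        s = float(shrinkage)
        if not 0.0 <= s < 1.0:
            raise ValueError("shrinkage must be 'auto' or in [0, 1)")
        emp = np.cov(X, bias=True)
        cov = shrunk_covariance(emp, shrinkage=s) if s > 0 else emp
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular; increase shrinkage"
        ) from exc
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    out = CorrelationMatrix(rho, roi_order, "partial")
    out.validate()
    return out


def positive_graph(marginal: CorrelationMatrix, partial: CorrelationMatrix,
                   weight_source: str = "partial") -> WeightedGraph:
    """Graph with an edge wherever both correlations are strictly positive.

    The edge weight is taken from ``weight_source`` ("partial" by default,
    since the partial correlation is the direct-connectivity estimate;
    "marginal" selectable).
    """
    if marginal.roi_order != partial.roi_order:
        raise ValueError("marginal and partial roi_order differ")
    if weight_source not in ("partial", "marginal"):
        raise ValueError("weight_source must be 'partial' or 'marginal'")
    source = partial if weight_source == "partial" else marginal
    rois = marginal.roi_order
    edges = {}
    n = len(rois)
    for i in range(n):
        for j in range(i + 1, n):
            if marginal.values[i, j] > 0 and partial.values[i, j] > 0:
                edges[(rois[i], rois[j])] = float(source.values[i, j])
    g = WeightedGraph(nodes=list(rois), edges=edges)
    g.validate()
    return g
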