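"""Sliding-window (delay) embedding of scalar time series.

The embedding maps t -> (f(t), f(t+tau), ..., f(t+M*tau)), turning a scalar
series into an (M+1)-dimensional point cloud whose geometry reflects the
series' temporal structure. With the defaults M=2, tau=1 each point is three
consecutive samples, so a length-N series yields N-2 points in R^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class SeriesTooShortError(ValueError):
    """Series length must exceed M * tau."""


@dataclass
class PointCloud:
    """Ordered delay-embedding point cloud.

    ``points`` has shape (N - M*tau, M+1); row k (0-based) is the window
    starting at sample k, i.e. the 1-based point
    (f(k+1), f(k+1+tau), ..., f(k+1+M*tau)).
    """

    points: np.ndarray
    M: int
    tau: int
    source: tuple | None = None

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def embed(series, M: int = 2, tau: int = 1, z_normalize: bool = False,
          source: tuple | None = None) -> PointCloud:
    """Delay-embed a scalar series into an (M+1)-dimensional point cloud.

    Parameters
    ----------
    series : sequence of float, length N > M*tau
    M : int
        Embedding dimension parameter; points live in R^(M+1).
    tau : int
        Time lag in samples.
    z_normalize : bool
        If True, z-score the series before embedding (off by default).
    """
    x = np.asarray(series, dtype=float).ravel()
    if M < 1:
        raise ValueError("M must be >= 1")
    if tau < 1:
        raise ValueError("tau must be >= 1")
    N = x.size
    if N <= M * tau:
        raise SeriesTooShortError(
            f"series length {N} must exceed M*tau = {M * tau}"
        )
    if z_normalize:
        sd = x.std()
        if sd == 0:
            raise ValueError("cannot z-normalize a constant series")
        x = (x - x.mean()) / sd
    window = M * tau + 1
    points = sliding_window_view(x, window)[:, ::tau].copy()
    return PointCloud(points=points, M=M, tau=tau, source=source)
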