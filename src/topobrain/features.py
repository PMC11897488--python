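"""Lifespan feature vectors from persistence diagrams.

The classification input from graph filtration is the vector of the k most
persistent features: lifespans |death - birth| sorted in descending order,
zero-padded to fixed length. Essential (infinite-death) classes have
undefined lifespan and are dropped by default; they may instead be truncated
to the largest finite death in the diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagram import PersistenceDiagram


@dataclass
class LifespanFeatures:
    """Fixed-length descending lifespan vector for one subject."""

    vector: np.ndarray
    subject: str | None = None
    source: tuple | None = None  # (network, dimension)

    def validate(self) -> None:
        v = self.vector
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise ValueError("lifespans must be finite and non-negative")
        if np.any(np.diff(v) > 0):
            raise ValueError("lifespans must be sorted descending")


def top_k_lifespans(diagram: PersistenceDiagram, k: int = 10,
                    essential: str = "drop", subject=None,
                    source=None) -> LifespanFeatures:
    """Top-k lifespans of a diagram, descending, zero-padded to length k.

    ``essential`` is "drop" (default) or "truncate" (replace infinite deaths
    by the largest finite death before computing lifespans).
    """
    if essential not in ("drop", "truncate"):
        raise ValueError("essential must be 'drop' or 'truncate'")
    pairs = diagram.pairs
    if essential == "truncate" and len(pairs):
        deaths = pairs[:, 1]
        finite = deaths[np.isfinite(deaths)]
        cap = finite.max() if finite.size else pairs[:, 0].max()
        pairs = pairs.copy()
        pairs[np.isinf(pairs[:, 1]), 1] = cap
    spans = np.abs(pairs[:, 1] - pairs[:, 0]) if len(pairs) else np.empty(0)
    spans = spans[np.isfinite(spans)]
    spans = np.sort(spans)[::-1][:k]
    vector = np.zeros(k)
    vector[:spans.size] = spans
    feats = LifespanFeatures(vector=vector, subject=subject, source=source)
    feats.validate()
    return feats
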