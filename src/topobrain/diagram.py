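"""Persistence diagrams and their plain-text serialization.

A persistence diagram is a multiset of (birth, death) pairs for one homology
dimension. Ordinary diagrams (sublevel filtrations) satisfy birth <= death,
with death = +inf for essential classes that never die. Extended diagrams
(the loop pairing on graphs) record each independent cycle as
(max filter value on the cycle, min filter value on the cycle), so
birth >= death by convention.
"""

from __future__ import annotations

import numpy as np

ORDINARY = "ordinary"
EXTENDED = "extended"


class PersistenceDiagram:
    """Multiset of (birth, death) pairs in a single homology dimension.

    Parameters
    ----------
    dimension : int
        Homology dimension (0: components, 1: loops, 2: voids).
    pairs : array-like of shape (n, 2)
        Birth/death coordinates; death may be ``np.inf`` for essential
        classes of ordinary diagrams.
    kind : {"ordinary", "extended"}
        Filtration convention. Ordinary pairs satisfy birth <= death,
        extended pairs birth >= death.
    """

    __slots__ = ("dimension", "pairs", "kind")

    def __init__(self, dimension: int, pairs, kind: str = ORDINARY):
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
        if kind not in (ORDINARY, EXTENDED):
            raise ValueError(f"unknown diagram kind: {kind!r}")
        if arr.size and kind == ORDINARY and np.any(arr[:, 0] > arr[:, 1]):
            raise ValueError("ordinary diagram requires birth <= death")
        if arr.size and kind == EXTENDED:
            if np.any(~np.isfinite(arr)):
                raise ValueError("extended diagram pairs must be finite")
            if np.any(arr[:, 0] < arr[:, 1]):
                raise ValueError("extended diagram requires birth >= death")
        order = np.lexsort((arr[:, 1], arr[:, 0]))
        self.pairs = arr[order]
        self.dimension = int(dimension)
        self.kind = kind

    @property
    def births(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.pairs[:, 1]

    @property
    def lifespans(self) -> np.ndarray:
        """|death - birth| per pair; +inf for essential pairs."""
        return np.abs(self.deaths - self.births)

    @property
    def essential_count(self) -> int:
        return int(np.sum(np.isinf(self.deaths)))

    def finite(self) -> "PersistenceDiagram":
        """Copy with essential (infinite-death) pairs removed."""
        keep = np.isfinite(self.deaths)
        return PersistenceDiagram(self.dimension, self.pairs[keep], self.kind)

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PersistenceDiagram):
            return NotImplemented
        return (
            self.dimension == other.dimension
            and self.kind == other.kind
            and self.pairs.shape == other.pairs.shape
            and np.array_equal(self.pairs, other.pairs)
        )

    def __hash__(self):  # pragma: no cover - diagrams are not dict keys
        return NotImplemented

    def isclose(self, other: "PersistenceDiagram", atol: float = 1e-9) -> bool:
        """Multiset equality up to ``atol`` on the sorted pair arrays."""
        if self.dimension != other.dimension or self.kind != other.kind:
            return False
        if self.pairs.shape != other.pairs.shape:
            return False
        with np.errstate(invalid="ignore"):
            a, b = self.pairs, other.pairs
            inf_match = np.isinf(a) == np.isinf(b)
            fin = np.isfinite(a) & np.isfinite(b)
            close = np.abs(np.where(fin, a - b, 0.0)) <= atol
        return bool(np.all(inf_match) and np.all(close | ~fin))

    def __repr__(self) -> str:
        return (
            f"PersistenceDiagram(dim={self.dimension}, kind={self.kind!r}, "
            f"n={len(self)}, essential={self.essential_count})"
        )


def write_diagrams(path, diagrams) -> None:
    """Write diagrams to a TSV with columns dimension, birth, death, kind.

    Infinite deaths are written as the string ``inf``.
    """
    with open(path, "w") as fh:
        fh.write("dimension\tbirth\tdeath\tkind\n")
        for dgm in diagrams:
            for b, d in dgm.pairs:
                death = "inf" if np.isinf(d) else f"{d:.17g}"
                fh.write(f"{dgm.dimension}\t{b:.17g}\t{death}\t{dgm.kind}\n")


def read_diagrams(path) -> list[PersistenceDiagram]:
    """Read a diagram TSV written by :func:`write_diagrams`.

    Returns one diagram per (dimension, kind) present, ordered by dimension.
    """
    groups: dict[tuple[int, str], list[tuple[float, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["dimension", "birth", "death", "kind"]:
            raise ValueError(f"unrecognized diagram header in {path}")
        for line in fh:
            dim_s, b_s, d_s, kind = line.rstrip("\n").split("\t")
            key = (int(dim_s), kind)
            groups.setdefault(key, []).append((float(b_s), float(d_s)))
    return [
        PersistenceDiagram(dim, pts, kind)
        for (dim, kind), pts in sorted(groups.items())
    ]
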