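"""Synthetic multi-subject ROI time-series cohorts.

The generator emulates resting-state fMRI panels at the statistical level the
downstream topology assumes: per brain network, each ROI series is a mixture
of a small number of shared autoregressive drivers plus independent AR(1)
noise. Group membership enters through the coupling (variance share of the
shared drivers), so planted group effects are connectivity effects, not mean
shifts — matching how the filtrations read the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Dosenbach 160-ROI parcellation: node counts of the six classical networks.
DOSENBACH_NETWORKS = {"CB": 18, "CO": 32, "DMN": 34, "FP": 21, "OP": 22, "SM": 33}


class CohortSpecError(ValueError):
    """Raised when a :class:`CohortSpec` violates its invariants."""


class PanelFormatError(ValueError):
    """Raised when a panel file or its sidecar is malformed."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Attributes
    ----------
    n_subjects_per_group : int
        Subjects per group; groups are balanced by construction.
    groups : tuple of str
        Ordered group labels.
    networks : dict
        Network name -> ROI count. Defaults to the six-network Dosenbach
        partition (18, 32, 34, 21, 22, 33 nodes).
    n_timepoints : int
        Series length. Default 150 samples, consistent with ~7-10 minute
        resting-state scans at TR ~ 3 s after discarding initial volumes.
    latent_rank : int
        Number of shared AR(1) drivers per network.
    coupling_base : float
        Baseline variance share of the shared drivers, in [0, 1].
    coupling_shift_per_group : dict
        Group label -> additive coupling shift (the planted effect).
    noise_sd : float
        Marginal standard deviation of every emitted series.
    ar_coefficient : float
        AR(1) coefficient of the ROI-specific noise, |phi| < 1.
    driver_ar_coefficient : float
        AR(1) coefficient of the shared network drivers. Defaults to 0.8,
        slower than the ROI noise: resting-state network fluctuations are
        band-limited and smoother than region-local noise, which also makes
        the coupling share visible in each series' spectrum.
    seed : int
        Global seed; spawns one child seed per subject so any subject is
        individually reproducible.
    """

    n_subjects_per_group: int = 20
    groups: tuple = ("HC", "MCI")
    networks: dict = field(default_factory=lambda: dict(DOSENBACH_NETWORKS))
    n_timepoints: int = 150
    latent_rank: int = 2
    coupling_base: float = 0.3
    coupling_shift_per_group: dict = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 0.3}
    )
    noise_sd: float = 1.0
    ar_coefficient: float = 0.4
    driver_ar_coefficient: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise CohortSpecError("n_subjects_per_group must be >= 1")
        if len(self.groups) < 1:
            raise CohortSpecError("groups must be non-empty")
        if len(set(self.groups)) != len(self.groups):
            raise CohortSpecError("groups contains duplicate labels")
        if not self.networks:
            raise CohortSpecError("networks must be non-empty")
        for name, count in self.networks.items():
            if int(count) < 1:
                raise CohortSpecError(f"networks[{name!r}] must be >= 1")
        if self.n_timepoints < 1:
            raise CohortSpecError("n_timepoints must be >= 1")
        if self.latent_rank < 1:
            raise CohortSpecError("latent_rank must be >= 1")
        if not abs(self.ar_coefficient) < 1:
            raise CohortSpecError("ar_coefficient must satisfy |phi| < 1")
        if not abs(self.driver_ar_coefficient) < 1:
            raise CohortSpecError(
                "driver_ar_coefficient must satisfy |phi| < 1")
        if self.noise_sd <= 0:
            raise CohortSpecError("noise_sd must be > 0")
        for g in self.groups:
            if g not in self.coupling_shift_per_group:
                raise CohortSpecError(
                    f"coupling_shift_per_group missing group {g!r}"
                )
            c = self.coupling_base + self.coupling_shift_per_group[g]
            if not 0.0 <= c <= 1.0:
                raise CohortSpecError(
                    f"coupling_base + shift for group {g!r} is {c}, "
                    "outside [0, 1]"
                )


@dataclass
class TimeSeriesPanel:
    """Subjects x ROIs x time panel with network partition and group labels."""

    values: np.ndarray  # (n_subjects, n_rois, n_timepoints)
    subject_ids: list
    roi_ids: list
    roi_network: dict
    subject_group: dict

    def validate(self) -> None:
        s, r, t = self.values.shape
        if len(self.subject_ids) != s or len(self.roi_ids) != r:
            raise PanelFormatError("label lists do not match value dimensions")
        if np.any(~np.isfinite(self.values)):
            raise PanelFormatError("panel contains missing/non-finite values")
        if t >= 2 and np.any(self.values.std(axis=2) == 0):
            flat = np.argwhere(self.values.std(axis=2) == 0)[0]
            raise PanelFormatError(
                f"zero-variance series: subject {self.subject_ids[flat[0]]!r},"
                f" roi {self.roi_ids[flat[1]]!r}"
            )
        for roi in self.roi_ids:
            if roi not in self.roi_network:
                raise PanelFormatError(f"roi {roi!r} missing from roi_network")
        for sub in self.subject_ids:
            if sub not in self.subject_group:
                raise PanelFormatError(
                    f"subject {sub!r} missing from subject_group"
                )

    @property
    def networks(self) -> list:
        seen = []
        for roi in self.roi_ids:
            net = self.roi_network[roi]
            if net not in seen:
                seen.append(net)
        return seen

    @property
    def groups(self) -> list:
        seen = []
        for sub in self.subject_ids:
            g = self.subject_group[sub]
            if g not in seen:
                seen.append(g)
        return seen

    def network_rois(self, network: str) -> list:
        return [r for r in self.roi_ids if self.roi_network[r] == network]

    def subjects_in_group(self, group: str) -> list:
        return [s for s in self.subject_ids if self.subject_group[s] == group]

    def subject_matrix(self, subject, network: str | None = None) -> np.ndarray:
        """ROIs x time matrix for one subject, optionally one network."""
        si = self.subject_ids.index(subject)
        if network is None:
            return self.values[si]
        idx = [i for i, r in enumerate(self.roi_ids)
               if self.roi_network[r] == network]
        return self.values[si, idx, :]

    def series(self, subject, roi) -> np.ndarray:
        si = self.subject_ids.index(subject)
        ri = self.roi_ids.index(roi)
        return self.values[si, ri, :]


def _ar1_unit(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """Stationary AR(1) rows with unit marginal variance, shape (..., T)."""
    *lead, T = shape
    out = np.empty(shape)
    out[..., 0] = rng.standard_normal(lead)
    innov_sd = np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(shape)
    for t in range(1, T):
        out[..., t] = phi * out[..., t - 1] + innov_sd * eps[..., t]
    return out


def generate_cohort(spec: CohortSpec) -> TimeSeriesPanel:
    """Generate a deterministic cohort panel from a :class:`CohortSpec`.

    Per network, ``latent_rank`` unit-variance AR(1) drivers are drawn per
    subject; ROI i gets series
    ``noise_sd * (sqrt(c) * w_i . drivers + sqrt(1 - c) * eps_i)`` with
    nonnegative unit-norm mixing weights ``w_i``, independent unit-variance
    AR(1) noise ``eps_i``, and coupling
    ``c = coupling_base + coupling_shift_per_group[group]``. Nonnegative
    mixing makes within-network correlations positive, the regime the
    positive-graph construction assumes.
    """
    spec.validate()
    n_total = spec.n_subjects_per_group * len(spec.groups)
    subject_ids = []
    subject_group = {}
    for g in spec.groups:
        for k in range(spec.n_subjects_per_group):
            sid = f"{g}_{k:03d}"
            subject_ids.append(sid)
            subject_group[sid] = g

    roi_ids = []
    roi_network = {}
    for net, count in spec.networks.items():
        for i in range(int(count)):
            rid = f"{net}_{i + 1:03d}"
            roi_ids.append(rid)
            roi_network[rid] = net

    T = spec.n_timepoints
    phi = spec.ar_coefficient
    values = np.empty((n_total, len(roi_ids), T))
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    for si, sid in enumerate(subject_ids):
        rng = np.random.default_rng(children[si])
        c = spec.coupling_base + spec.coupling_shift_per_group[subject_group[sid]]
        row = 0
        for net, count in spec.networks.items():
            count = int(count)
            drivers = _ar1_unit(rng, (spec.latent_rank, T),
                                spec.driver_ar_coefficient)
            weights = np.abs(rng.standard_normal((count, spec.latent_rank)))
            weights /= np.linalg.norm(weights, axis=1, keepdims=True)
            noise = _ar1_unit(rng, (count, T), phi)
            series = np.sqrt(c) * weights @ drivers + np.sqrt(1.0 - c) * noise
            values[si, row:row + count, :] = spec.noise_sd * series
            row += count

    panel = TimeSeriesPanel(values, subject_ids, roi_ids, roi_network,
                            subject_group)
    panel.validate()
    return panel


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_panel(panel: TimeSeriesPanel, path) -> None:
    """Write a panel as TSV (subject_id, roi_id, t0001..tNNNN) + JSON sidecar."""
    panel.validate()
    T = panel.values.shape[2]
    cols = [f"t{t + 1:04d}" for t in range(T)]
    rows = []
    for si, sid in enumerate(panel.subject_ids):
        for ri, rid in enumerate(panel.roi_ids):
            rows.append((sid, rid, *panel.values[si, ri, :]))
    df = pd.DataFrame(rows, columns=["subject_id", "roi_id", *cols])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "roi_network": panel.roi_network,
        "subject_group": panel.subject_group,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_panel(path) -> TimeSeriesPanel:
    """Read a panel written by :func:`write_panel`, validating the sidecar."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject_id" or df.columns[1] != "roi_id":
        raise PanelFormatError("panel must start with subject_id, roi_id")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise PanelFormatError(f"missing sidecar {sidecar_file}")
    with open(sidecar_file) as fh:
        sidecar = json.load(fh)
    for key in ("roi_network", "subject_group"):
        if key not in sidecar:
            raise PanelFormatError(f"sidecar missing key {key!r}")

    if df.duplicated(subset=["subject_id", "roi_id"]).any():
        dup = df[df.duplicated(subset=["subject_id", "roi_id"])].iloc[0]
        raise PanelFormatError(
            f"duplicate row for subject {dup['subject_id']!r}, "
            f"roi {dup['roi_id']!r}"
        )
    subject_ids = list(dict.fromkeys(df["subject_id"]))
    roi_ids = list(dict.fromkeys(df["roi_id"]))
    for roi in roi_ids:
        if roi not in sidecar["roi_network"]:
            raise PanelFormatError(f"roi {roi!r} missing from roi_network")
    for sub in subject_ids:
        if sub not in sidecar["subject_group"]:
            raise PanelFormatError(f"subject {sub!r} missing from subject_group")
    if len(df) != len(subject_ids) * len(roi_ids):
        raise PanelFormatError(
            f"expected {len(subject_ids) * len(roi_ids)} rows "
            f"({len(subject_ids)} subjects x {len(roi_ids)} ROIs), "
            f"found {len(df)}"
        )

    T = df.shape[1] - 2
    values = np.empty((len(subject_ids), len(roi_ids), T))
    sub_pos = {s: i for i, s in enumerate(subject_ids)}
    roi_pos = {r: i for i, r in enumerate(roi_ids)}
    data = df.iloc[:, 2:].to_numpy(dtype=float)
    for k in range(len(df)):
        values[sub_pos[df.iat[k, 0]], roi_pos[df.iat[k, 1]], :] = data[k]
    panel = TimeSeriesPanel(
        values, subject_ids, roi_ids,
        dict(sidecar["roi_network"]), dict(sidecar["subject_group"]),
    )
    panel.validate()
    return panel
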