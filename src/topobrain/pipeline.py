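"""End-to-end orchestration of the two analysis arms.

The Vietoris-Rips arm turns every subject x ROI series into a delay-embedded
point cloud, computes Rips persistence diagrams, and collapses them into one
inter-ROI Wasserstein matrix per subject, network and homology dimension —
optionally feeding the hybrid classifier. The graph arm builds the positively
correlated graph per subject and network, computes the 0-th ordinary and 1-st
extended diagrams, the inter-subject Wasserstein matrix per network and
dimension, rank-sum group statistics, and optionally the stacked ensemble on
top-10 lifespan features.

Every stage writes its outputs plus a JSON manifest carrying the stage
parameters and a content hash of its inputs; a rerun with unchanged inputs
and parameters skips completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import TimeSeriesPanel, read_panel
from .connectivity import marginal_correlation, partial_correlation, positive_graph
from .diagram import write_diagrams
from .embedding import embed
from .ensemble import EnsembleConfig, fit_stacked_ensemble
from .features import top_k_lifespans
from .graph_ph import build_filter, extended_persistence_1, ordinary_persistence_0
from .hybridnet import HybridNetConfig, fit_hybrid_net
from .rips import RipsOptions, rips_diagrams
from .stats import wilcoxon_contrast
from .wasserstein import (
    WassersteinOptions,
    inter_roi_matrix,
    inter_subject_matrix,
    write_distance_matrix,
)

logger = logging.getLogger("topobrain")


@dataclass
class RunConfig:
    """Configuration of a full run; seeds propagate to every stochastic stage."""

    panel_path: str
    output_dir: str
    arm: str = "both"  # "vr", "graph", or "both"
    networks: list | None = None
    embedding_M: int = 2
    embedding_tau: int = 1
    rips: RipsOptions = field(default_factory=lambda: RipsOptions(max_dim=1))
    filter_transform: str = "identity"
    weight_source: str = "partial"
    shrinkage: str | float = "auto"
    wasserstein: WassersteinOptions = field(default_factory=WassersteinOptions)
    stats_policy: str = "within_block_upper_triangle"
    run_classifiers: bool = False
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    hybrid: HybridNetConfig = field(default_factory=HybridNetConfig)
    seed: int = 0
    force: bool = False

    def validate(self) -> None:
        if self.arm not in ("vr", "graph", "both"):
            raise ValueError("arm must be 'vr', 'graph' or 'both'")
        if not Path(self.panel_path).exists():
            raise FileNotFoundError(self.panel_path)


def _hash_obj(obj) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return hashlib.sha256(np.ascontiguousarray(o).tobytes()).hexdigest()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    payload = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Content-hash keyed stage cache with a JSON manifest per stage."""

    def __init__(self, outdir: Path, name: str, inputs_hash: str, force: bool):
        self.manifest_path = outdir / f"{name}.manifest.json"
        self.name = name
        self.inputs_hash = inputs_hash
        self.force = force
        self.outputs: list[str] = []
        self.t0 = time.monotonic()

    def completed(self) -> bool:
        if self.force or not self.manifest_path.exists():
            return False
        with open(self.manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("inputs_hash") != self.inputs_hash:
            return False
        return all(Path(p).exists() for p in manifest.get("outputs", []))

    def record(self, *paths) -> None:
        self.outputs.extend(str(p) for p in paths)

    def finish(self, extra: dict | None = None) -> None:
        manifest = {
            "stage": self.name,
            "inputs_hash": self.inputs_hash,
            "outputs": self.outputs,
            "seconds": round(time.monotonic() - self.t0, 3),
        }
        if extra:
            manifest.update(extra)
        with open(self.manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        logger.info("stage %s finished in %.2fs", self.name,
                    manifest["seconds"])


def _contrasts(panel: TimeSeriesPanel) -> list[tuple]:
    groups = panel.groups
    return [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]


def run_vr_arm(config: RunConfig, panel: TimeSeriesPanel | None = None) -> dict:
    """Vietoris-Rips arm: clouds -> diagrams -> WD_ROI (-> hybrid reports)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = panel or read_panel(config.panel_path)
    networks = config.networks or panel.networks
    params = {
        "M": config.embedding_M, "tau": config.embedding_tau,
        "rips": dataclasses.asdict(config.rips),
        "wasserstein": dataclasses.asdict(config.wasserstein),
        "networks": networks, "seed": config.seed,
    }
    inputs_hash = _hash_obj({"panel": _hash_file(config.panel_path),
                             "params": params})
    artifacts: dict = {"wd_roi": {}, "hybrid_reports": {}}

    stage = _Stage(outdir, "vr_arm", inputs_hash, config.force)
    recompute = not stage.completed()
    dims = range(config.rips.max_dim + 1)
    wd_dir = outdir / "wd_roi"
    wd_dir.mkdir(exist_ok=True)
    matrices: dict = {}
    for net in networks:
        rois = panel.network_rois(net)
        for subject in panel.subject_ids:
            per_roi = {}
            if recompute:
                for roi in rois:
                    cloud = embed(panel.series(subject, roi),
                                  config.embedding_M, config.embedding_tau,
                                  source=(subject, roi))
                    per_roi[roi] = rips_diagrams(cloud, config.rips)
            for dim in dims:
                path = wd_dir / f"{net}_H{dim}_{subject}.tsv"
                if recompute:
                    mat = inter_roi_matrix(
                        {r: per_roi[r][dim] for r in rois},
                        config.wasserstein, rois,
                        context={"network": net, "dimension": dim,
                                 "kind": "ordinary", "subject": subject},
                    )
                    write_distance_matrix(mat, path)
                    matrices[(net, dim, subject)] = mat
                stage.record(path, str(path) + ".json")
                artifacts["wd_roi"][(net, dim, subject)] = str(path)
    if recompute:
        stage.finish({"n_matrices": len(artifacts["wd_roi"])})

    if config.run_classifiers:
        from .wasserstein import read_distance_matrix
        for net in networks:
            for dim in dims:
                for ga, gb in _contrasts(panel):
                    subs = (panel.subjects_in_group(ga)
                            + panel.subjects_in_group(gb))
                    mats = {}
                    for s in subs:
                        key = (net, dim, s)
                        mats[s] = (matrices.get(key)
                                   or read_distance_matrix(artifacts["wd_roi"][key]))
                    labels = {s: panel.subject_group[s] for s in subs}
                    cfg = dataclasses.replace(config.hybrid, seed=config.seed)
                    _, report = fit_hybrid_net(mats, labels, cfg)
                    rpath = outdir / f"hybrid_{net}_H{dim}_{ga}_vs_{gb}.json"
                    with open(rpath, "w") as fh:
                        json.dump(report, fh, indent=1)
                    artifacts["hybrid_reports"][(net, dim, ga, gb)] = report
    return artifacts


def run_graph_arm(config: RunConfig, panel: TimeSeriesPanel | None = None) -> dict:
    """Graph arm: graphs -> Dg0/ExDg1 -> WD_S -> stats (-> ensemble reports)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = panel or read_panel(config.panel_path)
    networks = config.networks or panel.networks
    params = {
        "transform": config.filter_transform,
        "weight_source": config.weight_source,
        "shrinkage": config.shrinkage,
        "wasserstein": dataclasses.asdict(config.wasserstein),
        "stats_policy": config.stats_policy,
        "networks": networks, "seed": config.seed,
    }
    inputs_hash = _hash_obj({"panel": _hash_file(config.panel_path),
                             "params": params})
    stage = _Stage(outdir, "graph_arm", inputs_hash, config.force)
    recompute = not stage.completed()

    diagrams: dict = {}
    dgm_dir = outdir / "diagrams_graph"
    dgm_dir.mkdir(exist_ok=True)
    for net in networks:
        rois = panel.network_rois(net)
        for subject in panel.subject_ids:
            X = panel.subject_matrix(subject, net)
            marg = marginal_correlation(X, rois)
            part = partial_correlation(X, rois, config.shrinkage)
            graph = positive_graph(marg, part, config.weight_source)
            filt = build_filter(graph, config.filter_transform)
            dg0 = ordinary_persistence_0(filt)
            ex1 = extended_persistence_1(filt)
            diagrams[(net, 0, subject)] = dg0
            diagrams[(net, 1, subject)] = ex1
            path = dgm_dir / f"{net}_{subject}.tsv"
            if recompute:
                write_diagrams(path, [dg0, ex1])
            stage.record(path)

    artifacts: dict = {"wd_s": {}, "stats": [], "ensemble_reports": {},
                       "diagrams": diagrams}
    wd_dir = outdir / "wd_subjects"
    wd_dir.mkdir(exist_ok=True)
    stats_rows = []
    for net in networks:
        for dim, kind in ((0, "ordinary"), (1, "extended")):
            mat = inter_subject_matrix(
                {s: diagrams[(net, dim, s)] for s in panel.subject_ids},
                config.wasserstein, panel.subject_ids,
                context={"network": net, "dimension": dim, "kind": kind},
            )
            path = wd_dir / f"{net}_H{dim}.tsv"
            if recompute:
                write_distance_matrix(mat, path)
            stage.record(path, str(path) + ".json")
            artifacts["wd_s"][(net, dim)] = mat
            for contrast in _contrasts(panel):
                res = wilcoxon_contrast(mat, panel.subject_group, contrast,
                                        config.stats_policy)
                artifacts["stats"].append(res)
                stats_rows.append(
                    f"{net}\tH{dim}\t{contrast[0]} vs {contrast[1]}\t"
                    f"{res.statistic:.6g}\t{res.p_value:.6g}\t"
                    f"{res.significance_label}"
                )
    stats_path = outdir / "group_stats.tsv"
    if recompute:
        with open(stats_path, "w") as fh:
            fh.write("network\tdimension\tcontrast\tstatistic\tp_value\t"
                     "significance\n")
            fh.write("\n".join(stats_rows) + "\n")
    stage.record(stats_path)
    if recompute:
        stage.finish({"n_stats": len(stats_rows)})

    if config.run_classifiers:
        for net in networks:
            for dim in (0, 1):
                for ga, gb in _contrasts(panel):
                    subs = (panel.subjects_in_group(ga)
                            + panel.subjects_in_group(gb))
                    feats = np.stack([
                        top_k_lifespans(diagrams[(net, dim, s)]).vector
                        for s in subs
                    ])
                    labels = np.array([panel.subject_group[s] for s in subs])
                    cfg = dataclasses.replace(config.ensemble, seed=config.seed)
                    _, report = fit_stacked_ensemble(feats, labels, cfg)
                    rpath = outdir / f"ensemble_{net}_H{dim}_{ga}_vs_{gb}.json"
                    with open(rpath, "w") as fh:
                        json.dump(report, fh, indent=1)
                    artifacts["ensemble_reports"][(net, dim, ga, gb)] = report
    return artifacts


def run(config: RunConfig) -> dict:
    """Run the configured arm(s); returns the union of their artifacts."""
    config.validate()
    panel = read_panel(config.panel_path)
    artifacts = {}
    if config.arm in ("vr", "both"):
        artifacts["vr"] = run_vr_arm(config, panel)
    if config.arm in ("graph", "both"):
        artifacts["graph"] = run_graph_arm(config, panel)
    return artifacts
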