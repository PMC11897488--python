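"""Rank-sum group comparisons of inter-subject Wasserstein distances.

For a contrast (group A, group B), samples are assembled from the
subjects x subjects Wasserstein matrix — by default the upper-triangle
entries of each group's within-group block — and compared with the two-sided
Wilcoxon rank-sum test: exact enumeration when the smaller sample has at most
10 values and there are no ties, the tie-corrected normal approximation
otherwise.

Distance samples drawn from a matrix are not independent (entries share
subjects), which makes the classical rank-sum p-value anti-conservative at
the cohort level. The ``label_permutation`` inference mode therefore
recomputes the same rank-sum statistic under subject-level group-label
permutations, giving a p-value that is calibrated under exchangeability of
subjects; the classical p-value remains the default for comparability with
the usual reporting of such tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .wasserstein import DistanceMatrix

POLICIES = ("within_block_upper_triangle", "mean_distance_per_subject")
INFERENCES = ("rank_sum", "label_permutation")


@dataclass
class GroupTestResult:
    network: str
    dimension: int
    contrast: tuple
    statistic: float  # rank sum of the first contrast group's sample
    p_value: float
    n_A: int
    n_B: int
    sample_policy: str
    inference: str = "rank_sum"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def significance_label(self) -> str:
        return f"p = {self.p_value:.3g}" if self.significant else "NS"


def rank_sum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of A, p).

    Uses exact enumeration when min(n) <= 10 and there are no ties across
    the pooled sample, else the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):  # degenerate: every value tied
        return a.size * (a.size + b.size + 1) / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def _assemble_idx(values: np.ndarray, idx: np.ndarray, label: str,
                  policy: str) -> np.ndarray:
    if len(idx) < 2:
        raise ValueError(
            f"group {label!r} needs >= 2 subjects for policy {policy!r}"
        )
    block = values[np.ix_(idx, idx)]
    if policy == "within_block_upper_triangle":
        return block[np.triu_indices(len(idx), k=1)]
    # mean distance of each subject to the other subjects of its group
    return block.sum(axis=1) / (len(idx) - 1)


def _centered_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:a.size].sum() - a.size * (a.size + b.size + 1) / 2.0)


def wilcoxon_contrast(matrix: DistanceMatrix, groups: dict, contrast: tuple,
                      policy: str = "within_block_upper_triangle",
                      inference: str = "rank_sum",
                      n_permutations: int = 200,
                      permutation_seed: int = 0,
                      alpha: float = 0.05) -> GroupTestResult:
    """Test whether Wasserstein distances differ between two groups.

    Parameters
    ----------
    matrix : DistanceMatrix with axis "subjects".
    groups : subject -> group label.
    contrast : (groupA, groupB).
    policy : sample-assembly policy; the default compares the within-group
        upper-triangle distance samples, the alternative compares per-subject
        mean within-group distances.
    inference : "rank_sum" for the classical exact/asymptotic p-value, or
        "label_permutation" for the same statistic referred to its
        subject-level permutation null (calibrated for dependent distance
        samples; seeded, ``n_permutations`` draws).
    """
    if matrix.axis != "subjects":
        raise ValueError("matrix axis must be 'subjects'")
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if inference not in INFERENCES:
        raise ValueError(f"inference must be one of {INFERENCES}")
    ga, gb = contrast
    idx_a = np.array([i for i, s in enumerate(matrix.labels)
                      if groups.get(s) == ga])
    idx_b = np.array([i for i, s in enumerate(matrix.labels)
                      if groups.get(s) == gb])
    for g, idx in ((ga, idx_a), (gb, idx_b)):
        if idx.size == 0:
            raise ValueError(f"contrast group {g!r} absent from matrix")
    values = matrix.values
    sample_a = _assemble_idx(values, idx_a, ga, policy)
    sample_b = _assemble_idx(values, idx_b, gb, policy)
    stat, p = rank_sum_test(sample_a, sample_b)
    if inference == "label_permutation":
        obs = abs(_centered_rank_sum(sample_a, sample_b))
        pooled = np.concatenate([idx_a, idx_b])
        rng = np.random.default_rng(permutation_seed)
        hits = 1
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            pa = _assemble_idx(values, perm[:idx_a.size], ga, policy)
            pb = _assemble_idx(values, perm[idx_a.size:], gb, policy)
            if abs(_centered_rank_sum(pa, pb)) >= obs - 1e-9:
                hits += 1
        p = hits / (n_permutations + 1)
    return GroupTestResult(
        network=str(matrix.context.get("network", "")),
        dimension=int(matrix.context.get("dimension", -1)),
        contrast=(ga, gb),
        statistic=stat,
        p_value=p,
        n_A=sample_a.size,
        n_B=sample_b.size,
        sample_policy=policy,
        inference=inference,
        alpha=alpha,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p by default)."""
    return multipletests(np.asarray(p_values, dtype=float),
                         method="fdr_bh")[1]
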