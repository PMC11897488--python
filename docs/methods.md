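# Methods

This note records the models, conventions, numerical choices and known
limitations behind `topobrain`, in the order data flows through the package.

## Synthetic cohorts

`generate_cohort` emulates multi-subject ROI panels at the statistical level
the downstream topology consumes. Per subject and network, `latent_rank`
(default 2) shared drivers are stationary unit-variance AR(1) processes with
coefficient `driver_ar_coefficient` (default 0.8); each ROI receives

    x_i(t) = noise_sd * ( sqrt(c) * w_i · d(t) + sqrt(1 − c) * e_i(t) ),

with nonnegative unit-norm mixing weights w_i, independent unit-variance
AR(1) noise e_i (coefficient `ar_coefficient`, default 0.4), and coupling
c = `coupling_base` + `coupling_shift_per_group[group]` (defaults 0.3 and
+0.3 for the impaired group). Design notes:

* **Group effects are coupling shifts, not mean shifts.** All analyses in
  the package are connectivity-topological; a planted mean shift would be
  invisible to them by construction.
* **Drivers are slower than ROI noise.** Shared resting-state network
  fluctuations are band-limited and smooth relative to region-local noise.
  This matters doubly here: it is what makes the coupling share visible in
  each series' spectrum, so the Vietoris–Rips arm (which only ever sees
  per-ROI delay embeddings) can sense connectivity at all. With equal driver
  and noise coefficients every ROI has an identical marginal law at any
  coupling, and inter-ROI Wasserstein matrices carry essentially no group
  information — a degenerate design we measured and rejected.
* **Nonnegative mixing weights** make within-network correlations positive,
  the regime the positive-graph construction expects.
* T defaults to 150 samples, consistent with ~7–10-minute resting scans at a
  repetition time near 3 s after discarding initial volumes; the six-network
  160-ROI Dosenbach partition is the default parcellation.
* One global seed spawns a per-subject seed sequence, so panels are
  bit-reproducible and any subject can be regenerated alone.

What the generator deliberately omits: hemodynamics, scanner drift and
motion, spatial structure, inter-subject variance heterogeneity, and any
regional heterogeneity of dynamics beyond random driver loadings. Tests that
pass on these cohorts therefore certify the *machinery* (filtrations,
distances, statistics, classifiers) and the identifiability of a planted
coupling effect — not performance on real fMRI.

## Sliding-window embedding

`embed` maps a series to points (f(t), f(t+τ), …, f(t+Mτ)), t = 1 … N−Mτ
(1-based in documentation; storage is natural t order). Defaults M = 2,
τ = 1 — a window of three consecutive samples giving 3-D clouds. No
normalization is applied by default; z-scoring is a flag. Automatic selection
of M or τ is out of scope.

## Vietoris–Rips persistence

Simplices up to dimension `max_dim`+1 are enumerated with the diameter
filtration and non-strict inclusion (diam σ ≤ ε); for finite point sets the
strict and non-strict conventions differ only on a measure-zero set of
scales, and ≤ matches standard practice. The filtration order is
(value, dimension, lexicographic vertices), making the GF(2) column
reduction deterministic. Columns are Python integers used as bit sets over
the positions of the facets' dimension block.

* Default `max_scale` is the enclosing radius — min over points of the max
  distance to the rest — past which the complex is a cone and no new
  homology appears; exactly one essential H0 class survives. Classes alive
  at the cap are reported with death = +inf.
* Zero-persistence pairs are dropped.
* Default `max_points` is 60 when `max_dim` = 2 (the 3-simplex enumeration
  budget) and unlimited otherwise; larger clouds are reduced by
  deterministic farthest-point subsampling after a seeded random start. A
  configurable simplex budget (default 2·10⁶) refuses oversized complexes
  with actionable advice rather than thrashing.
* Field coefficients are fixed to GF(2).

A δ-perturbation of every point moves each pairwise distance by at most 2δ,
so diagrams move by at most 2δ in bottleneck distance; the test suite checks
this bound (the tighter δ sometimes quoted for function filtrations does not
hold for the diameter filtration).

## Connectivity graphs

Marginal correlation is plain Pearson; partial correlation is
ρ_ij = −P_ij/√(P_ii P_jj) with P the inverse of a Ledoit–Wolf-shrunk
covariance by default (`shrinkage=0` uses the raw empirical covariance for
oracle comparisons and errors if singular). The positive graph keeps edge
(i, j) iff both correlations are strictly greater than zero — a zero partial
correlation indicates absence of direct connectivity. The numeric edge
weight is configurable (`partial` default, `marginal` selectable): which
correlation should weight the surviving edges is genuinely ambiguous, and
the two choices answer different questions. Note for synthetic studies: a
latent-factor coupling effect appears in *marginal* weights and is largely
removed by partialling (the shared driver is exactly what partial
correlation controls away), so planted-effect calibration experiments in the
test suite use marginal weights; the partial-weight default is kept for the
package because on real data it is the better-motivated notion of direct
connectivity.

## Graph persistence

The filter sets f(e) = w(e) (identity transform by default; `one_minus_w`
available for users who want strong correlations to enter the sublevel
filtration first) and f(v) = min incident f(e); isolated vertices take
f(v) = 0 and contribute essential (0, ∞) components.

* **Dg₀**: Kruskal-style sweep with union-find and the elder rule (the
  component with the larger birth dies at the merging edge value; equal
  births are broken by the lexicographically larger minimum vertex dying).
  One essential (min birth, ∞) pair per connected component.
  Zero-persistence merges are dropped unless requested.
* **ExDg₁**: computed exactly by reducing the boundary matrix of the coned
  extended filtration — ascending vertices and edges, then a cone over every
  simplex in decreasing superlevel value (vertices at max incident edge
  value). Each independent cycle yields one point with birth ≥ death; for a
  lone cycle this is (max, min) edge value along the loop. The often-quoted
  shortcut "pair each non-forest edge with the minimum edge value on the
  cycle it closes with the minimum spanning forest" is *not* extended
  persistence once cycles share edges — the true death can come from a
  homologous representative — so the reduction is authoritative; the test
  suite checks it against an independent dense-matrix implementation of the
  same construction on hundreds of random graphs. |ExDg₁| always equals the
  first Betti number |E| − |V| + #components.
* Ties in filter values are broken by canonical node order; relabelling
  nodes permutes tie-breaks but leaves the diagram multisets unchanged
  (tested).

Extended persistence in dimension ≥ 2 does not exist on graphs and is out of
scope.

## Wasserstein distances

The classical bijection formulation is undefined for diagrams of unequal
cardinality, so each diagram is augmented with the diagonal projections of
the other's points — the standard partial-matching completion. Costs are
L∞ per matched pair raised to the power q (default q = 1, configurable);
the assignment is solved exactly with a rectangular assignment solver, and a
brute-force matching backend exists for small inputs. Essential points
default to `truncate_to_max_finite` (replace ∞ by the largest finite death
across the two diagrams being compared, falling back to the largest birth),
keeping distances finite and comparable; `drop_essential` is available.
Bottleneck distance exists only as a test utility — its insensitivity to all
but the worst pair makes it a poor production metric here.

Matrix builders compute each unordered pair once; permuting the label order
conjugates the matrix (tested).

## Group statistics

For a contrast (A, B), samples are assembled from WD_S per the
`sample_policy`: within-group upper-triangle blocks (default) or per-subject
mean within-group distance. The Wilcoxon rank-sum statistic is computed with
exact enumeration when the smaller sample has ≤ 10 values and no ties, and
the tie-corrected normal approximation otherwise; p < 0.05 is labelled
significant and raw p-values are reported (Benjamini–Hochberg adjustment is
an optional helper, not a default).

**Calibration caveat, and the permutation mode.** Entries of a distance
matrix share subjects, so neither sample policy yields independent
observations, and the classical rank-sum p-value is strongly
anti-conservative at the cohort level: on null synthetic cohorts we measure
rejection rates of 0.3–0.45 at α = 0.05. This is a property of the testing
procedure on distance samples, not of the generator. `wilcoxon_contrast`
therefore offers `inference="label_permutation"`: the same rank-sum
statistic referred to its null distribution under subject-level group-label
permutations (seeded, 200 permutations by default). The permutation p is
calibrated under subject exchangeability (measured 0.045–0.065 rejection on
200 null cohorts) and retains high power at the default planted effect
(≈ 0.96–1.0 with marginal edge weights, n = 20/group). The classical
p-value remains the default output for comparability with common practice;
cohort-level conclusions should use the permutation mode.

## Classification

**Lifespan features.** Top-k (default 10) lifespans |death − birth| per
diagram, descending, zero-padded. Essential points are dropped by default
(infinite lifespan is undefined); truncation to the largest finite death is
a flag.

**Stacked ensemble.** Stratified 80/20 train/test split; RFE with a random
forest down to 5 features on the training set; ten base classifiers (SVC,
random forest, gradient boosting, XGBoost, AdaBoost, extra trees, logistic
regression, k-NN, LightGBM, and sklearn's histogram gradient boosting
standing in for CatBoost — recorded in every report) ranked by stratified
5-fold CV accuracy; the top five stacked under a random-forest meta-model;
held-out accuracy reported on the untouched test split. All estimators are
seeded; reports are bit-reproducible.

**Hybrid net.** Implemented directly on numpy with explicit forward and
backward passes (im2col convolutions), which is entirely adequate at
brain-network matrix sizes (n ≤ 34) on one CPU. Architecture: flat branch
n² → 256; conv branch 3×3 "same"-padded convolutions with 16, 32, 64
filters, one 2×2 max pool (pool size is the conventional default; only its
placement is fixed by the design), then 128 and 256 filters and global
average pooling; concatenation to 512; dense 128/64/32 with dropout 0.2;
softmax head; cross-entropy loss. "Same" padding keeps block-1 maps at n×n
so the architecture survives small networks. Hyperparameters — learning rate
log-uniform on [1e−4, 1e−1], batch size ∈ {4, 8, 16, 32}, validation split
∈ {0.2, 0.25, 0.3}, optimizer ∈ {SGD, Adam} — are drawn by a seeded random
search (20 trials by default) with early stopping at patience 10 within at
most 100 epochs; splits are stratified by class and keyed to subject
identifiers (each subject contributes exactly one matrix, so grouping is
automatic). A stratified test fraction (default 0.2) is held out before the
search; the best trial's trained weights are evaluated on it once. Inputs
are standardized by the training split's global mean and standard
deviation. Gradients are verified against finite differences in the test
suite, and the parameter count is checked against the closed-form layer
arithmetic to guard architecture drift.

## Pipeline

`run_vr_arm` and `run_graph_arm` materialize every stage to TSV/JSON with a
manifest per stage (parameter echo, input content hash, output list,
timing); an unchanged rerun skips completed stages, and a forced rerun
reproduces byte-identical outputs. Pairwise-distance loops are written so
results are independent of evaluation order. The CLI is a thin `click`
wrapper over the library.

## Problem sizes in the shipped experiments

The statistical experiments in the test suite run at deliberately modest
sizes chosen once as realistic-but-small study conditions: null calibration
on 200 cohorts of 10 subjects/group over an 8-ROI network (T = 100); power
on 100 cohorts at the default +0.3 coupling shift, 20 subjects/group, one
10-ROI network (T = 150); end-to-end recovery over 10 cohorts per arm, with
Rips clouds subsampled to 40 points and the hybrid search reduced to 3
trials × 30 epochs. Larger networks mainly increase cost, not information,
under the homogeneous generator: the 160-ROI default exists so structural
constants and formats are exercised at full scale.

## Known limitations

* The Rips reduction is pure Python; it is comfortable to ~60-point clouds
  at max_dim 2 and ~150 points at max_dim 1, not beyond.
* The generator's homogeneity means per-ROI dynamics differ across ROIs only
  through random driver loadings; regional heterogeneity of real brains is
  not modelled, so absolute classifier accuracies here say nothing about
  accuracies on clinical data.
* With partial-correlation edge weights, a purely latent-factor group effect
  is (correctly) attenuated by the partialling itself; studies planting
  effects through shared drivers should analyse marginal-weight graphs or
  plant direct-edge effects instead.
* The classical rank-sum p-values on distance samples are anti-conservative
  (see above); they are reported for comparability, not for inference.
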