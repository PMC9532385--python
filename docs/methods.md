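# Methods

This document records the statistical model, the algorithmic conventions and
the numerical choices the package makes, including where tests use reduced
("scaled") problem sizes.

## Voxel grids and data model

Analyses run on a `VoxelGrid`: an isotropic voxel lattice (default 3 mm) with
an affine mapping voxel indices to millimetre coordinates, a gray-matter mask
and an integer network parcellation. Maps are stored as flat vectors over the
gray voxels in C order (`VoxelMap`). NIfTI volumes (float32) round-trip
through nibabel; subject covariates round-trip through TSV. An
`AnalysisConfig` records every threshold (correlation threshold, distance
cutoff, α, cluster extent, peak separation, permutation count, seed) and
emits a JSON manifest with a SHA-256 of its contents so a run's thresholds
are auditable.

## Functional connectivity strength (FCS)

For each voxel, FCS is the sum of Pearson correlations r ≥ 0.1 (threshold
kept at equality) to all voxels strictly more than 20 mm away; negative
correlations are excluded. The computation accepts either a time-series
matrix or a precomputed correlation matrix (detected by symmetry and unit
diagonal) and evaluates in row blocks so the full correlation matrix is never
materialized for time-series input. Zero-variance voxels get FCS 0 with a
warning. Raw FCS maps are z-normalized across voxels (population SD); a
constant map raises rather than silently dividing by zero.

## Per-cohort GLM

Subject maps are modeled as FCS = β₀ + β_age(Age − mean Age) + β_sex·Sex + ε
with sex coded ±0.5 and centered. The cohort summary is the intercept map β₀
(the covariate-adjusted cohort mean, since covariates are centered) and the
unbiased residual variance with df = N − p. Constant covariate columns are
dropped automatically (e.g. single-sex cohorts), which adjusts p. Cohorts
need at least 2 subjects.

## Random-effects meta-analysis

DerSimonian–Laird, per voxel over k cohorts:
W = N/SD², Q = ΣWM² − (ΣWM)²/ΣW, df = k−1,
T² = max(0, (Q−df)/(ΣW − ΣW²/ΣW)), I² = max(0, (Q−df)/Q)·100 (0 when
Q = 0), W* = 1/(SD²/N + T²), M* = ΣW*M/ΣW*, SE = (ΣW*)^(−1/2), Z = M*/SE,
d = Z/√k. T² and I² are floored at zero (standard truncation). Voxels where
any cohort has non-positive variance are flagged NaN rather than dropped
silently. Note that under a true global null Q ~ χ²(k−1), so the truncated
estimator returns exact zeros at roughly half the voxels and small positive
I² elsewhere; "no heterogeneity" manifests as I² rarely exceeding the
substantial-heterogeneity bound (50%), which is what the acceptance test
asserts.

## Hub inference

Family-wise error control uses the permutation distribution of the map-wide
maximum Z: per iteration each cohort's (mean, variance) map pair is jointly
permuted over voxels with an independent permutation per cohort, the
meta-analytic Z map is recomputed, and its maximum recorded. Voxelwise
p = (1 + #{null max ≥ Z}) / (n_permutations + 1) (add-one estimator), so the
smallest achievable p is 1/(n+1) — with the default α = 0.001 at least 1000
permutations are required for any voxel to survive; the package default is
10,000. Significant voxels (p < α) are clustered with 26-connectivity and
clusters of volume > 200 mm³ survive. Peaks are strict 26-neighborhood local
maxima, retained greedily per cluster in descending Z (ties by lowest voxel
index) subject to a 15-mm minimum separation; a cluster that is an exact
plateau (no strict maximum) falls back to its maximum-Z voxel. Peak rows
carry Z, d, M* and SE.

## Reproducibility

Dice = 2|A∩B|/(|A|+|B|), defined as 1.0 when both masks are empty (two
analyses that both find nothing agree). Leave-one-cohort-out reruns the full
inference chain on each k−1 subset (k ≥ 3) and reports per-fold Dice plus,
for each full-analysis peak, the distance to the nearest reduced-analysis
peak. Hub occurrence probability is the fraction of units whose top-N set
contains each voxel; exact ties at the top-N boundary are broken by voxel
index with a warning. Subsample stability draws random unit subsets per
size, takes the top-N occurrence mask (N = reference mask size) and reports
mean ± SD Dice against the reference; the full-size subset is evaluated once
(SD exactly 0).

## Seed profiles

A seed is a 6-mm-radius sphere (inclusive boundary); its mean time series is
correlated with every voxel and Fisher z-transformed with |r| capped at
1 − 1e-7 so z stays finite. Cohort-level seed maps run through the same GLM →
meta-analysis → FWER chain. A significant map is summarized as the percentage
of each network's voxels it covers; empty networks give NaN with a warning.
Profiles (networks × seeds) are clustered with single-linkage agglomerative
clustering on Euclidean column distances (scipy `linkage`; the same default
pairing as MATLAB's `linkage`), cut by `fcluster` at a requested cluster
count.

## Surrogate maps

The generator follows the permute → smooth → variogram-match → rank-reassign
scheme: the source map is permuted; the permutation is smoothed with
Gaussian-kernel k-nearest-neighbor weights over a grid of bandwidths
(fractions 0.05–0.6 of the variogram distance cutoff, the 70th percentile of
pairwise distances); for each bandwidth an affine fit γ_surr ≈ α + β·γ_smooth
to the source variogram is solved in closed form with weights 1/γ_src²
(relative error) and α, β constrained non-negative; the best bandwidth's
field √β·smoothed + √α·noise is then re-assigned the exact source value
multiset by rank. Variograms use 25 equal-width bins up to the cutoff with
pair subsampling (50,000 pairs) for large inputs.

Numerical choice: the smoothing neighborhood defaults to
knn = min(500, n−1), not a small fixed neighborhood. With ~500 locations and
smooth fields at 15-mm scale, a 100-neighbor cap leaves the surrogate
variogram error at ~26–33% while the full neighborhood reaches ~20–22%;
the wider support is what lets the affine fit match long-range structure.
Map-level tests: a rank-sum statistic of hub vs non-hub values against the
null of top-|hub| relabelings from each surrogate (add-one p, optional
Bonferroni factor), and a Pearson correlation against the surrogate null
(two-sided or one-sided).

## Transcriptomic association

Expression samples are labeled hub/non-hub by nearest-voxel lookup through
the grid affine (outside-grid or non-gray samples are excluded). The
classification protocol draws 300 training samples per class per repetition,
picks the boosting length by stratified cross-validated early stopping
(binary logistic XGBoost, η = 0.05, validation-loss curves averaged across
folds and truncated to their common length), tests on all held-out samples,
and accumulates gain importances and per-sample correctness over
repetitions. Defaults mirror the full protocol (1000 repetitions, 30-fold
CV, ≤1500 rounds, 50-round patience); the cross-validation is implemented as
an explicit fold loop rather than `xgb.cv` for speed. The SVM sweep pairs
all hub samples with the equally many easiest or hardest non-hub samples
(by correct-classification rate, ties broken by sample id) and scores a
standardized RBF SVM (C = 1) on the top-n genes by contribution via
stratified cross-validation. Gene sets are summarized by their PC1
(sign-aligned to mean expression, min-max scaled to [0, 1]); developmental
trajectories are lowess fits against log2 post-conceptional days,
interpolated onto a common grid, with a median-absolute-deviation band
across regions; parcels are called hubs when strictly more than 50% of their
locations fall in the hub mask.

## Synthetic generators: scope and limits

Cohort maps are mean + cohort random effect u_c ~ N(0, τ²) + covariate
effects + i.i.d. Gaussian noise — spatially white within the planted
structure, so they exercise the estimators, not realistic spatial spectra.
Time series come from a Cholesky factor of a block correlation matrix.
Expression matrices place samples at (jittered) voxel coordinates;
informative genes are Gaussian-kernel-smoothed spatial fields (15-mm scale)
with a mean shift in hub samples, remaining genes are white noise. Two
consequences worth knowing:

- With exchangeable planted values, a max-statistic permutation null can
  re-align the planted values at a common voxel; if the planted fraction f
  and cohort count k satisfy V·f^k·n_perm ≳ 1 the null saturates at the
  observed maximum. Tests keep planted fractions ~1%.
- Because informative genes are themselves smooth spatial maps, any smooth
  relabeling of samples is genuinely separable from signal-bearing synthetic
  expression; the "surrogate labels at chance" property is therefore tested
  on label-free expression.

## Scaled problem sizes

Package defaults match the full protocol; tests and `scripts/acceptance.py`
use reduced counts chosen for a 1-CPU budget, as package-level choices:
classification tests use 3-fold CV, ≤30 boosting rounds, 5-round patience
and 8–100 repetitions; FWER calibration uses 12 cohorts × 20 subjects,
2000 voxels, 500 permutations and 200 replicates; surrogate calibration uses
150 locations, 99 surrogates and 120 replicates. The acceptance target
(chance-level accuracy) uses the full 382 + 776 × 500 matrix with 100 scaled
repetitions (~3 min).
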