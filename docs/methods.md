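# Methods

This note documents the models, estimators and design choices behind
`neurocascade`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic validation does and does not show.

## The analysis in one paragraph

Three-class identification of Alzheimer's disease (AD), mild cognitive
impairment (MCI) and healthy controls (HC) from four ROI-level imaging
metrics: the Hurst exponent (HE) of the resting-state BOLD signal, left and
right hippocampus seed connectivity (L.Hip / R.Hip), and gray-matter volume
(GMV). Per region of a 170-label parcellation (164 usable), these give a
654-column feature table (163 + 163 + 164 + 164; each hippocampus seed is
excluded from its own connectivity metric because the self-correlation is
degenerate). Features are ranked by minimum-redundancy-maximum-relevance
(MRMR), pruned by a sequential-feature-collection (SFC) window search, and
classified by a two-stage cascade — patients (AD∪MCI) vs HC, then AD vs
MCI — using RBF-SVMs or a single-hidden-layer neural network, all inside
nested stratified 10-fold cross-validation.

## Signal cleaning

Cleaning order is fixed: confound regression → band-pass → metrics.
Confound regression is OLS of every unit on an intercept plus the nuisance
set (six motion parameters, global/WM/CSF means); residuals are exactly
orthogonal to the regressors and the operation is idempotent. The band-pass
(default 0.01–0.10 Hz at TR = 2 s) is an ideal rectangular filter in the
DFT domain: coefficients outside the band are zeroed on both conjugate
halves. This matches the convention of the resting-state preprocessing
toolchains this pipeline mirrors; the sharp cut-off costs some edge
ringing on short (~230-point) series, which we accept for comparability.

## Hurst exponent by rescaled-range analysis

For window size n the series is split into non-overlapping blocks; per
block R is the range of the cumulative sum of mean-centred values and S the
sample standard deviation (ddof = 1, zero-S blocks dropped). H is the
least-squares slope of log mean(R/S) against log n.

**Small-sample correction.** Raw R/S is biased upward for i.i.d. data
(white noise at n ≈ 1000 reads ≈ 0.55). By default the Anis–Lloyd expected
R/S of i.i.d. data — with the (n − ½)/n finite-sample factor, exact
Gamma-ratio front factor for n ≤ 340 and its Stirling limit beyond — is
subtracted and the asymptote √(nπ/2) added back before fitting, so the
white-noise expectation is unbiased at 0.5.

**Window ladder.** The default ladder is powers of two spanning
[length/16, length/2] (floored at 8). Calibration against exact-covariance
fractional Gaussian noise showed that ladders starting at 8 drag the fitted
slope toward 0.5 for strongly dependent series (bias ≈ −0.15 at H = 0.9,
length 4096), because the R/S statistic approaches its asymptotic power law
slowly; the top five octaves keep the transient small (measured biases at
length 4096, 200 replicates: +0.010 / −0.008 / −0.012 / −0.044 for
H = 0.3 / 0.5 / 0.7 / 0.9). A residual negative bias of up to ≈ 0.05 at
H = 0.9 is intrinsic to R/S at this length and no window choice removes it.
Callers may pass any explicit ladder (short fMRI series typically use
8–64).

## fGn oracle

The validation oracle is fractional Gaussian noise synthesised by
circulant (Davies–Harte) embedding of the closed-form autocovariance
γ(k) = σ²/2(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}). The embedding eigenvalues
are nonnegative for fGn, so the target H is the exact population value, not
an ARFIMA-style approximation. Tests verify the lag-1 autocorrelation
2^{2H−1} − 1 and the full autocovariance curve empirically.

## Seed connectivity and regional aggregation

The seed reference is the unweighted mean series over the seed's voxels;
left and right hippocampus (labels 41/42) are processed independently.
Features are raw Pearson r by default — a Fisher-z flag exists but is off,
since the downstream classifiers are invariant to the monotone transform in
practice and the raw coefficient is the conventional feature. Regional
reduction is the unweighted voxel mean for functional maps; GMV is the sum
of Jacobian-modulated GM probability × voxel volume / 1000 (millilitres) —
modulation preserves tissue amounts, so the sum is a true regional volume.
Negative GM voxels (interpolation artefacts) are clamped to zero with a
warning. Label volumes are resampled by nearest-neighbour sampling at
target-voxel centres; labels that vanish (e.g. the two single-voxel regions
lost going from 1 mm to 3 mm) are recorded as empty rather than silently
dropped.

## MRMR and the SFC search

The MRMR criterion for a set S is mean feature–class mutual information
minus (1/|S|²) Σ_{i≠j} I(f_i, f_j). Mutual information is the plug-in
estimate on equal-frequency bins (default 4 bins for continuous features;
class labels used as-is), a robust choice at cohort sizes of ~50–200
subjects. The self-information term is excluded from the redundancy sum so
that the size-1 criterion reduces to pure relevance — the first ranked
feature is always the max-relevance feature. The criterion is maximised by
the classic greedy incremental scheme; exhaustive enumeration is used only
as a test oracle on small instances. Ties break toward the lower column
index, making the ranking deterministic.

The SFC search evaluates every contiguous window order[ℓ..ℓ+k−1] of the
ranked top-m list (k ≥ 2), i.e. m(m−1)/2 candidates — 1225 at the default
m = 50. The evaluator during the search is the inner-CV accuracy of an
RBF-SVM at fixed mid-grid hyperparameters (C = 1, gamma = 1/n_features on
z-scored data); the full grid search runs once on the winning subset.
Re-optimising the full 33 × 33 grid inside each of the 1225 windows would
multiply the cost by three orders of magnitude for no documented benefit;
the search structure (which windows are compared) is unchanged. Ties prefer
fewer features, then the smaller loop index.

## Classification

**SVM cascade.** Stage 1 relabels AD∪MCI as "patient" and fits patient vs
HC; stage 2 fits AD vs MCI on the patients stage 1 classifies correctly on
its own training data (the literal study procedure; a flag trains on all
patients instead, and training falls back to all patients automatically if
the filtering removes a class). Each stage runs its own feature selection
and its own grid search (C, gamma ∈ {2^p : p = −8, −7.5, …, 8}) by inner
stratified CV, with ties resolved to the smaller C then smaller gamma.
Features are z-scored with training statistics before every fit — RBF
kernels need comparable scales. At prediction time a subject labelled HC by
stage 1 keeps that label; predicted patients flow to stage 2.

**ANN.** f(x) = g(Σ_j w_kj · g(Σ_i w_ji x_i + b_j) + b_k), logistic g, one
output per class, one-hot targets, batch gradient descent on the mean
squared error, stopping at RMSE < 0.01 or 500 epochs. Because the gradient
of the *mean* squared error scales as 1/n, the default step size is 5.0,
chosen so the classic XOR problem trains well inside the epoch budget.
Divergence triggers up to three halved-learning-rate retries. The hidden
width is tuned on 2..20 nodes by inner CV. The ANN runs either as the
cascade's stage classifier or as a direct 3-class network.

**Nested CV and leakage.** Outer and inner folds are stratified by class
with seeds derived deterministically from the master seed. All
training-side data access goes through a row guard that knows the outer
test fold and raises immediately on any test-row access; the guard is
exercised positively (it fires on deliberate violations) and negatively
(100 randomized nested-CV runs without a single violation) in the tests.
Reports carry the pooled 3×3 confusion matrix, per-class correct rates,
stage-1 and stage-2 ROC AUCs (trapezoidal, pooled decision values across
outer folds), and per-fold selected features. Because the set of test
patients reaching stage 2 is itself a stage-1 outcome, stage-2 accuracy
and AUC are reported under both accountings: stage-1-correct patients only,
and all true patients.

**Baselines and PCA.** Gaussian naive Bayes and random forest are thin
adapters around standard implementations, for direct 3-class comparison. A
PCA reducer (components fitted on training rows; smallest count whose
cumulative explained variance reaches the CVCR threshold, default grid
0.60–0.90) is available as an alternative to MRMR + SFC.

## Synthetic cohort

The generator emulates the study's data structures, not its physics: no
k-space/EPI simulation, no head motion, no anatomy. Defaults follow the
study conditions — group sizes 44/66/58 (AD/MCI/HC), 164 usable regions,
654 feature columns, demographics drawn from the printed per-group
means/SDs (clinical scores as independent Gaussians; between-score
covariances are not published and are not modelled), sex assigned at the
printed male fractions, CDR as the diagnostic constant (1 / 0.5 / 0).
Feature columns are Gaussian noise (sd 1) plus user-specified per-class
mean offsets in designated (metric, region) columns. A "separable" oracle
cohort plants ≥ 5·sd offsets in a handful of columns, giving a known
ceiling (≈100% cascade accuracy) and a permutation floor (≈33%).

Passing tests on this cohort demonstrate the *mechanics* — selection
finds planted signal, the cascade converts separation into accuracy, no
leakage — not real-data performance: real imaging features have spatial
correlation, site effects and far lower effect sizes.

## Problem sizes in the test suite

Library defaults match the full study design (33×33 grid, top-50 MRMR,
1225-window SFC, 10×10 nested CV). The test suite and example runs use
reduced sizes chosen for quick iteration — coarse 5×5 grids, top_m ≤ 6,
3–5 fold CV, cohorts of 18–60 subjects, 100–500 Monte-Carlo replicates for
estimator calibration — which keep the full suite under half a minute
while exercising every code path at full fidelity.

## Known limitations

- R/S retains an intrinsic ≈ −0.04..−0.05 bias at H = 0.9 for 4096-point
  series; longer series or other estimator families (DFA, wavelet) would be
  needed beyond that, and are out of scope here by design.
- The ideal DFT band-pass assumes approximate stationarity and rings at
  series edges.
- The plug-in MI estimator is biased upward at very small n; MRMR rankings
  are comparative, so this mostly cancels, but absolute MI values should
  not be over-interpreted.
- The ANN is deliberately minimal (batch GD, squared error); it reproduces
  the reference design rather than modern practice.
- The spectral-exponent route to H (via the 1/f power-spectrum slope) is
  not implemented; only the R/S estimator is provided.
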