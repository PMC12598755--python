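# Methods

This package implements a brain-age analysis for obesity cohorts as a tested,
reusable pipeline over ROI-level feature tables. This note documents the model
and procedure, what the synthetic-data generator does and does not emulate,
the numerical choices, and the known limitations.

## The brain-age framework

Chronological age is predicted from brain features by a penalized linear
model; the discrepancy between predicted and chronological age (the *brain
age delta*) indexes deviation from typical brain-ageing trajectories. The
study design the pipeline reproduces is: divide a cohort by BMI class
(normal 18.5–24.9, overweight 25–29.9, obese ≥ 30 kg/m²); build a matched
obese (O) / normal-weight-control (NWc) pair of held-out groups; train
brain-age models per imaging modality on everyone else (normal-weight and
overweight participants, which widens training variability and, if anything,
biases *against* finding a group difference); predict the held-out groups;
and compare bias-corrected deltas between groups over the lifespan and
within age strata (18–40, 40–60, 60+, half-open intervals).

### Matching

Greedy 1:1 nearest-age matching without replacement: candidate controls must
be within 5 years of age, same sex, and within one ordinal education level;
an obese case with no admissible control is excluded. Cases are processed in
descending age order (older cases face the scarcest pools), ties between
equally close candidates go to the smaller education difference, then the
lexicographically smaller id. The processing order and tie-breaks are
conventions chosen for determinism — with them the result is invariant to
shuffling the candidate list. Optimal (global cost-minimizing) and
propensity-score matching are out of scope.

### Elastic-net brain-age model

Features are standardized with training-set statistics, then regressed on
age with an elastic-net penalty. Hyperparameters follow the glmnet naming:
α ∈ {0.001, 0.25, 0.5, 0.75, 0.99} is the L1/L2 mixing ratio and λ, the
penalty strength, takes 100 log-spaced values in [1e−5, 1e5]
(scikit-learn's `l1_ratio` and `alpha` respectively). Selection is by
10-fold cross-validation stratified by age: ages are cut at training-set
deciles and each bin's members are dealt round-robin to folds, so fold age
composition differs from the global composition by at most one member per
bin. The (α, λ) pair (plus, for connectivity, the retained PC count) with
the lowest mean validation MSE is selected and the model refitted on the
full training set. Coordinate-descent tolerance is 1e-4 with a 10 000
iteration cap. Zero-variance feature columns are dropped with a logged
warning rather than raising, so degenerate synthetic inputs do not abort
runs.

For connectivity features, PCA is part of the model: within cross-validation
the reducer is refitted on each fold's training part (components are nested,
so one fit at the largest candidate count serves every smaller one), and the
candidate PC counts are linearly spaced with step 5. The final reducer is
refitted on the whole training set at the selected count.

### Bias correction

Brain-age predictions overestimate young and underestimate old participants
(regression dilution), so an OLS line `predicted = a·chronological + b` is
fitted and predictions corrected as `corrected = (predicted − b)/a`;
corrected delta = corrected predicted age − chronological age. The line is
fitted on **out-of-fold training predictions** at the selected
hyperparameters: fitting it on in-sample training predictions would
understate the dilution, and fitting it on the held-out groups would leak
group structure into the correction. An algebraic consequence — the OLS
slope of corrected delta on age is exactly zero on the bias-fit sample — is
asserted numerically (±1e-8) in the tests. Performance (R², MAE) is
reported on corrected predictions.

### Permutation testing

The null distribution for model performance refits the elastic net on
age-shuffled training data at the *originally selected* hyperparameters
(a full grid re-search per permutation would multiply the cost a
thousand-fold for no change in the null's meaning) and records held-out
MAE; p = (1 + #{null MAE ≤ observed}) / (n_perm + 1). One subtlety found
during development and documented in the test suite: when the selected
penalty fully shrinks all coefficients (as it tends to under a true null),
every permuted refit predicts the same training mean, all null MAEs tie
with the observed one and p degenerates to a conservative 1. The uniformity
check therefore uses penalties small enough to keep coefficients nonzero;
under genuine signal the issue does not arise.

### Group inference

Two-sample comparisons use the pooled-variance (Student's) t with a
two-tailed p, the default of the SPSS workflow such studies typically use;
for the equal-n groups produced by 1:1 matching it coincides with Welch's t,
which is available behind a flag. A summary-statistics entry point reruns
the identical formula from published mean (±SD) and N, so printed
comparison tables can be recomputed; the raw-data path delegates to it,
making the two paths agree exactly by construction. Zero-variance
comparisons return a documented sentinel (t = ±inf, p = 0; t = 0, p = 1
for identical means) instead of raising. Pearson chi-square (no continuity
correction) covers categorical demographics. No multiple-testing correction
is applied across modalities or strata — deliberately mirroring the
analysis design this package reproduces; treat per-stratum p-values as
exploratory.

### Obesity classification and stability

A ridge logistic regression classifies O vs NWc from MRI features plus age
and sex. Tolerance (from {3, 2, 1, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001,
0.0001}) and C (30 log-spaced values in [1e−4, 1e4]) are tuned by inner
cross-validation on the training folds only, inside a repeated (default
10×) stratified 10-fold scheme; folds are stratified jointly by class and
age decile so both classes appear in every fold while age balance is kept.
AUC uses the rank statistic with ties averaged; sensitivity and specificity
use a 0.5 probability threshold (a convention — the threshold is not
tuned). Metrics are averaged over repeats.

Feature stability refits the classifier at fixed hyperparameters (the
modally selected combination) on bootstrap resamples (default 1000 for a
full run, 200 in the demo config); degenerate single-class resamples are
redrawn and counted. Per-coefficient CIs are the 2.5th/97.5th percentiles;
the z-score standardizes the feature-wise mean coefficients *across
features* (inputs are z-scored, so coefficients are scale-comparable), and
|z| > 1.5 flags influential features. Sign convention: a negative weight
means a larger feature value favours the normal-weight class.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not
realistic images:

- **Demographics.** Ages uniform on [18, 89] (the empirical age
  distribution of the reference cohort is not published; uniform is the
  neutral choice and is configurable); sex Bernoulli(0.5), education
  uniform on the five ordinal levels, MMSE uniform on 25–30, all
  independent of group. BMI is sampled uniformly within the class range;
  the obese count is exact by construction (`round(n · obese_fraction)`).
- **Acceleration as an effective-age shift.** The obesity effect adds
  `accel_years` to the *effective age* at which obese participants' features
  are generated (optionally only within an age window), rather than offsetting
  features directly — an obese brain looks like an older normal-weight brain,
  which is the construct under test. Setting `accel_years=0` gives the null.
- **Grey matter.** 48 ROI volumes, `baseline + slope·effective_age + noise`;
  a majority of slopes negative (atrophy, −0.004 to −0.001 per year on
  baselines of 0.9–1.6 volume-fraction units) with a small positive
  minority (occipital-like). The default residual SD of 0.1 was chosen so
  the fitted model's held-out MAE lands in the 4–6-year range typical of
  published brain-age models, making recovery tests honest about realistic
  prediction error. Optional per-ROI group offsets plant region-specific
  signatures for classifier-recovery studies.
- **White matter.** FA declines with age; MD/AD/RD rise (diffusivities in
  1e−3 mm²/s units). The obesity acceleration defaults to zero here,
  encoding the white-matter null finding; it is configurable.
- **Connectivity.** A 167-node, 10-network parcellation whose default
  per-network sizes (30, 26, 20, 18, 15, 15, 15, 11, 10, 7) are a
  convention chosen to reproduce the canonical 1539 within-network /
  12 322 between-network pair counts — the true atlas's per-network sizes
  are not published, so only the pair counts are guaranteed. Node
  time-series follow a two-factor model (network factor + global factor +
  unique noise) with within-network coupling 0.50 − 0.003·(eff.age − 18)
  and between-network coupling 0.05 + 0.0015·(eff.age − 18): intra-network
  connectivity falls and inter-network connectivity rises with age, the
  dominant linear trends reported across the adult lifespan (the quadratic
  curvature of those trajectories is not modelled). Matrices are Pearson
  correlations of 261-sample series; sampling noise comes from the finite
  run length, and any length ≥ 100 is accepted.

All generators are pure functions of (configuration, seed).

What passing tests on these data do **not** show: robustness to scanner or
preprocessing artefacts, non-linear age trajectories, heteroscedastic or
spatially correlated ROI noise, realistic education/BMI confounding, or
non-uniform age distributions. They do show that the estimation machinery
is unbiased and calibrated when its assumptions hold: the +3-year injected
acceleration is recovered within 1 year (averaged over 20 replicates), the
null rejection rate sits at the nominal 5%, permutation p-values are
uniform under the null, and label-permuted classification is at chance.

## Problem sizes and defaults

The demo pipeline uses a 600-participant pool, held-out groups capped at
83 pairs, 200 permutations and 200 bootstrap iterations; a full run
(`--full`) uses 1000/1000. Calibration suites in the tests run at reduced
scale (260-participant pools, 24 ROIs, a coarser λ grid, 5 folds) — the
calibration properties they check are scale-invariant, and the reduced
sizes keep replicate counts high (100–200) where the binomial/KS assertions
need them. The acceptance script reports which size each number was
computed at.

## Known limitations

- Greedy matching is order-dependent by design and can exclude cases a
  globally optimal matching would keep.
- The permutation test reuses the selected hyperparameters; under a true
  null with heavy shrinkage its p is conservative (see above).
- The bootstrap z-threshold (|z| > 1.5) is a screening convention, not an
  error-rate-controlled test.
- Corrected deltas for the two held-out groups share one fitted model and
  one bias line, so their errors are not strictly independent; the t-test
  treats them as such (as does the design it reproduces).
- CSV round-trips store floats at full precision but connectivity tables
  for large cohorts are bulky; use the long format only when files must be
  inspected.
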