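# Methods

## The prediction problem

The 250-µg short Synacthen (ACTH stimulation) test diagnoses adrenal
insufficiency: serum cortisol is measured at baseline and 30 minutes after
synthetic-ACTH injection, and a 30-minute cortisol at or above a pass
threshold (430 nmol/L on the assay this package parameterizes) classifies the
patient as adrenally sufficient. Patients monitored for adrenal recovery are
retested repeatedly. This package predicts the 30-minute cortisol of a *new*
test from the patient's *previous* test results plus the new early-morning
baseline cortisol, so that a confident prediction can replace the dynamic
test entirely.

The unit of analysis is a within-patient pair of tests. Two fixed
fractional-polynomial (FP1) linear models are shipped:

    morning-only:  ŷ = −54.476 + 325.134·√(new baseline / 100)
    previous-AST:  ŷ = −116.5 + 251.5·√(new baseline / 100)
                        − 49.4·(previous baseline / 100)
                        + 714.3·(previous 30-minute / 1000)

with development residual SDs (RMSE) of 110.3 and 73.4 nmol/L. The residual
SD converts a point prediction into a probability of passing a repeat test,
`P(pass) = 1 − Φ((430 − ŷ)/σ)`, and into normal-theory prediction intervals
`ŷ ± z·σ` (coefficient-estimation uncertainty is ignored: only the residual
SD is available for the published models, and it dominates at these sample
sizes). Point predictions are left unclipped internally — flooring at zero
would bias calibration statistics — and floored/rounded only in user-facing
calculator output.

A documented inconsistency: solving the morning-only formula for a predicted
430 nmol/L gives a baseline of 222.0 nmol/L, although the value 133 nmol/L
circulates as the 50%-pass baseline for this model. The package follows the
printed coefficients; `invert_single_covariate` reproduces 222.0 and the
worked-example inversion of the previous-AST model reproduces 133 only in
the context of a previous test at (100, 200).

## Synthetic cohorts

Patient-level data are not shareable, so a generator (`astpredict.cohort`)
emulates the published summary statistics; every test in this repository
runs on its output. Design:

- **Marginals.** Each continuous variable (previous/new baseline cortisol,
  previous 30-minute cortisol, previous/new baseline ACTH, days between
  tests) is truncated log-normal: hormone concentrations are right-skewed
  and strictly positive, and the published ranges are treated as hard
  truncation bounds. The (µ, σ) of each marginal are solved numerically so
  that the *truncated* mean and SD equal the published ones (a Monte-Carlo
  test checks the generator reproduces its configured means within 2%).
- **Dependence.** The three cortisol variables share a Gaussian copula with
  pairwise latent correlation 0.7 (configurable). No covariances were
  published; 0.7 was chosen once because it reproduces the qualitative fact
  that the previous-AST model explains substantially more variance than the
  new baseline alone, and it was not revisited. ACTH and days between tests
  are drawn independently.
- **Outcome.** The new 30-minute cortisol is the previous-AST model's linear
  predictor plus N(0, σ) noise with σ = 73.4 nmol/L (the development RMSE),
  clipped at zero. With σ = 0 the outcome is exactly the linear predictor,
  which gives the pipeline-recovery tests an exact target.
- **Missingness.** Baseline ACTH is set missing completely at random at rate
  21/258 ≈ 0.081 (the development datasets' missing-value fraction); the
  validation preset has no missing ACTH. MCAR matches the absence of any
  reported mechanism. Cortisol/ACTH ratios are deterministic children of
  ACTH: they are blanked and recomputed, never imputed directly.
- **Strata.** Sex, AI type and steroid route/formulation are sampled from
  the published subgroup proportions, independent of the hormone values.
  They exist to exercise grouped cross-validation plumbing; the generator
  deliberately encodes no stratum-specific hormone differences, so passing
  grouped-CV tests shows the machinery works, not that the model is robust
  in real subgroups.

What the generator does *not* emulate: assay changes, time-of-day effects,
within-patient series longer than one pair, informative missingness, and any
real covariance structure beyond the single copula parameter. Results on
synthetic cohorts therefore validate the *procedures*, not the published
real-data performance values, which are unreachable without the patient data.

## Model development pipeline

`develop_model` reproduces the development procedure on any paired-test
table. Per bootstrap replicate (resampled with replacement at the input
size): random-forest imputation of missing ACTH, FP1 power choice per
candidate, backwards elimination at α = 0.05, and parameter-wise shrinkage.
Aggregation keeps variables whose bootstrap inclusion fraction (selected
with p ≤ α) reaches 0.9, averages the shrunken coefficients, and reports the
RMSE of the aggregated model on the input table as the residual SD. The
default replicate count is 5000; tests and the analysis drivers pass 200 (or
fewer), which this package treats as its standard desk-scale setting — the
retention pattern stabilizes far earlier.

Decisions taken where the procedure was underdetermined:

- **FP1 search.** Powers come from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 = log),
  degree 1 only. Each candidate's power is first chosen univariably (least
  RSS), then refined by cycling through the candidates and re-choosing each
  power within the joint multivariable fit, ties toward linearity, until a
  full cycle changes nothing (≤3 cycles). The refinement matters: with
  correlated candidates the univariable optimum is systematically distorted
  by the co-predictors — on zero-noise cohorts the univariable search picks
  log where the generating transform is linear — whereas the joint
  refinement recovers the generating powers exactly. Under realistic noise
  the sqrt/log distinction for the baseline-cortisol terms remains weakly
  identified and can flip between replicates; the final model uses each
  retained variable's modal power.
- **Backwards elimination** removes one variable at a time (the largest
  p-value above α), refitting after each removal.
- **Parameter-wise shrinkage** is estimated by K-fold (K = 10)
  cross-validation calibration: fit the selected model per training fold,
  collect out-of-fold per-term contributions `b_j·x_j`, then regress the
  outcome jointly on those contributions with a free intercept. The slope on
  contribution j is term j's multiplicative shrinkage factor; the
  calibration intercept is the shrunken intercept. On noise-free data all
  factors are exactly 1; on deliberately overfit fits (n = 30, five noise
  terms) the mean factor drops below 1, as it should.
- **Aggregation across replicates.** Coefficients estimated under different
  transforms are not commensurable, so a retained variable's final
  coefficient averages shrunken coefficients only over replicates that chose
  its modal power, and the final intercept averages over replicates whose
  retained-variable transforms all match the modal configuration. Averaging
  intercepts across transform families would mix values on different scales
  and was measurably biased when tried.
- **Random-forest imputation** is iterative (median start, 3 sweeps, 50
  trees): each imputable variable is regressed on the other continuous
  variables including the outcome, on originally observed rows only.
  Observed values are never modified.
- **Determinism.** Replicate r's random stream derives from
  `SeedSequence(master_seed, spawn_key=(r,))`, so replicates are
  order-independent and the whole report is bit-identical under a fixed
  seed.

Backwards selection with α = 1 degenerates to no elimination (inclusion
fraction 1 for every candidate), which tests use as a boundary case. The
"no-ACTH" candidate set contains the four candidates that survive removing
plasma ACTH and both derived ratios from the eight.

## Performance statistics

- `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` for the predictions as given (may be negative
  on external data); RMSE likewise.
- Calibration slope/intercept: least squares of observed on predicted
  (slope < 1 ⇒ overfitted predictions).
- AUC at the pass threshold: Mann-Whitney concordance for detecting an
  observed pass from the continuous prediction, ties counted ½, computed
  from average ranks and verified against O(n²) enumeration in tests.
- Confidence intervals: percentile bootstrap, 2000 resamples by default (the
  CI construction used for the published tables is unstated; percentile is
  the package's choice). Resamples on which a statistic is undefined (e.g.
  single-class AUC) are dropped; more than 5% failures aborts.
- Nested models are compared by the Gaussian likelihood-ratio statistic
  `n·ln(SSE_a/SSE_b)` and the gain in R².

## Benefit policy

The equivocal-range policy uses two thresholds on the *predicted* value: a
prediction strictly below the low threshold is accepted as adrenal
insufficiency, strictly above the high threshold as adequate function, and
only the equivocal range proceeds to an actual stimulation test. Ties on a
threshold stay equivocal (conservative: ties go to testing). The low
threshold is the largest cut point whose ROC sensitivity for detecting an
observed pass, `P(pred > t | pass)`, still meets the target (0.95 by
default) — the largest such cut maximizes the specificity of the
insufficiency call. The high threshold is symmetric: the smallest cut point
with `P(pred ≤ t | fail)` at the target. Candidate cut points are midpoints
between consecutive sorted unique predictions plus ±∞ sentinels, so
thresholds never depend on the observed outcome values directly. If the two
thresholds cross (a model accurate enough that both targets are met with
room to spare), they collapse to their midpoint: the equivocal range is
empty and every test is saved. `proportion_saved` + proportion equivocal = 1
by construction, and both searches are tested against exhaustive
enumeration.

## Numerical notes and limitations

- Zero-noise fits have residual variance at round-off scale; p-values of
  genuinely contributing variables are then ~0 while noise variables get
  noisy O(1) t-statistics, which is sufficient for the elimination step but
  means zero-noise inclusion fractions of null variables are not
  interpretable as error rates.
- `select_fp_power` requires ≥3 distinct predictor values and restricts the
  power set to ≥0.5 when the scaled predictor contains nonpositive values.
- Rank deficiency in a design matrix raises a named error identifying the
  collinear candidates (pivoted-QR diagnostic).
- Plausibility windows (cortisol ≤ 2000 nmol/L, ACTH ≤ 500 ng/L) warn
  rather than error: published sample ranges are not physiological limits.
- The bootstrap failure budget in `develop_model` is 1% of replicates;
  beyond that the run aborts with the first failure's replicate index.
- Scale divisors default to 100 (baseline cortisol), 1000 (30-minute
  cortisol) — matching the shipped formulas — and order-of-magnitude values
  for the remaining candidates (10 for ACTH and ratios, 100 for days);
  they are configurable per variable.
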