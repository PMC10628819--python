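# astpredict

Predicting repeat short-Synacthen-test results from previous test results
and a new early-morning cortisol.

The 250-µg short Synacthen test (ACTH stimulation test, AST) is the standard
diagnostic for adrenal insufficiency: serum cortisol is measured at baseline
and 30 minutes after synthetic-ACTH injection, and a 30-minute cortisol
≥ 430 nmol/L (assay-dependent) is a pass. Patients weaning from
glucocorticoids are retested repeatedly while their
hypothalamo–pituitary–adrenal axis recovers, which is burdensome for
patients and services. This package is for biostatisticians and
endocrinology researchers who want to study — and stress-test — the
alternative: *predict* the new 30-minute cortisol from data already in hand
and only test the patients whose prediction is equivocal.

At its core are two fractional-polynomial linear models with fixed published
coefficients,

    morning-only:  ŷ = −54.476 + 325.134·√(x_new/100)
    previous-AST:  ŷ = −116.5 + 251.5·√(x_new/100) − 49.4·(x_prev/100) + 714.3·(y_prev/1000)

where `x_new` is the new baseline cortisol, `x_prev`/`y_prev` the previous
test's baseline and 30-minute cortisol (all nmol/L), with residual SDs 110.3
and 73.4 nmol/L. Around them the package implements the full development and
evaluation methodology:

- `astpredict.cohort` — synthetic paired-test cohorts (truncated log-normal
  marginals, Gaussian copula, MCAR missing ACTH, outcome generated from the
  previous-AST mechanism), since the patient data cannot be shared;
- `astpredict.models` — FP1 terms, point predictions, prediction intervals,
  pass probabilities `1 − Φ((430 − ŷ)/σ)`, single-covariate inversion;
- `astpredict.development` — bootstrap model development: random-forest
  imputation, FP1 power selection, backwards elimination (α = 0.05),
  parameter-wise shrinkage, retention by bootstrap inclusion fraction > 0.9;
- `astpredict.validation` — R², RMSE, calibration slope/intercept,
  Mann-Whitney AUC at the pass threshold, percentile-bootstrap CIs,
  leave-one-group-out cross-validation, likelihood-ratio model comparison;
- `astpredict.benefit` — equivocal-range policies: thresholds attaining
  target sensitivity/specificity and the proportion of tests saved.

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

```python
from astpredict import published_models, predict

model = published_models()["previous_ast"]
pred = predict(model, {
    "new_baseline_cortisol": 133,   # nmol/L, this morning
    "prev_baseline_cortisol": 100,  # nmol/L, previous test
    "prev_cortisol_30": 200,        # nmol/L, previous test
})
print(round(pred.point), round(pred.pass_probability, 3))
```

prints `267 0.013`: in the context of a weak previous test (baseline 100,
30-minute 200), a new morning cortisol of 133 nmol/L predicts a 30-minute
cortisol of 267 nmol/L — far below the 430 nmol/L pass threshold, with only
a 1.3% probability of passing, so a repeat stimulation test would add little.
With a stronger previous test (baseline 200, 30-minute 400) the same morning
cortisol predicts 360 nmol/L and a 17% pass probability — equivocal, so this
patient *should* be tested. The same calculation is available from a shell:

```
$ astpredict predict --model previous_ast --new-baseline 133 --prev-baseline 100 --prev-30 200
predicted 30-minute cortisol: 267 nmol/L
95% interval: 123 to 411 nmol/L
probability of passing (>= 430 nmol/L): 0.013
```

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts: `01` simulates development (n = 258) and validation (n = 111)
cohorts, `02` applies the published models, `03` re-develops a model by the
bootstrap pipeline (the three generating variables are retained with
inclusion fraction 1.0; days-between-tests is dropped), `04` computes
performance statistics (on the synthetic validation cohort the previous-AST
model reaches R² ≈ 0.87 / AUC ≈ 0.97 versus R² ≈ 0.59 / AUC ≈ 0.86 for the
morning-only model), and `05` evaluates the 95%/95% equivocal-range policy
(previous-AST saves ~89% of tests versus ~60% for morning-only on that
cohort). Outputs land in `results/`.

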