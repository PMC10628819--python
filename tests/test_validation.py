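"""Calibration, discrimination, bootstrap CIs, grouped cross-validation, model comparison."""

import numpy as np
import pandas as pd
import pytest

from astpredict import (
    CANDIDATES_NO_ACTH,
    DevelopmentConfig,
    auc_at_threshold,
    bootstrap_ci,
    calibration_stats,
    compare_models,
    cross_validate_groups,
    development_config,
    generate_cohort,
    performance_report,
    predict_frame,
    prepare_analysis_frame,
    published_models,
)
from astpredict.errors import (
    CalibrationError,
    ConfigurationError,
    DiscriminationError,
    GroupingError,
)


# -- calibration ----------------------------------------------------------

def test_calibration_identity():
    y = np.linspace(10, 800, 50)
    cs = calibration_stats(y, y)
    assert cs.r2 == pytest.approx(1.0)
    assert cs.rmse == pytest.approx(0.0, abs=1e-12)
    assert cs.slope == pytest.approx(1.0)
    assert cs.intercept == pytest.approx(0.0, abs=1e-9)


def test_calibration_constant_shift():
    rng = np.random.default_rng(0)
    p = rng.uniform(100, 700, 100)
    y = p + 40.0
    cs = calibration_stats(y, p)
    assert cs.slope == pytest.approx(1.0)
    assert cs.intercept == pytest.approx(40.0)
    assert cs.r2 < 1.0
    assert cs.rmse == pytest.approx(40.0)


def test_calibration_matches_closed_form_oracle():
    """Slope and intercept agree with the normal-equation solution to 1e-10."""
    rng = np.random.default_rng(1)
    for _ in range(5):
        p = rng.uniform(0, 900, 200)
        y = 30 + 0.9 * p + rng.normal(0, 50, 200)
        cs = calibration_stats(y, p)
        sxx = np.sum((p - p.mean()) ** 2)
        sxy = np.sum((p - p.mean()) * (y - y.mean()))
        slope = sxy / sxx
        intercept = y.mean() - slope * p.mean()
        assert cs.slope == pytest.approx(slope, abs=1e-10)
        assert cs.intercept == pytest.approx(intercept, abs=1e-10)


def test_calibration_errors():
    with pytest.raises(CalibrationError):
        calibration_stats([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(CalibrationError, match="constant"):
        calibration_stats([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


# -- discrimination -------------------------------------------------------

def test_auc_perfect_and_null():
    y = np.array([100.0] * 20 + [600.0] * 20)
    p = np.array([50.0] * 20 + [500.0] * 20)
    assert auc_at_threshold(y, p, 430.0) == 1.0
    rng = np.random.default_rng(2)
    y = rng.uniform(0, 900, 5000)
    p = rng.uniform(0, 900, 5000)  # independent of outcome
    assert auc_at_threshold(y, p, 430.0) == pytest.approx(0.5, abs=0.03)


def _auc_bruteforce(y, p, threshold):
    passes = p[y >= threshold]
    fails = p[y < threshold]
    total = 0.0
    for a in passes:
        for b in fails:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(passes) * len(fails))


def test_auc_equals_pairwise_oracle_with_ties():
    rng = np.random.default_rng(3)
    for n in (10, 50, 120):
        y = rng.uniform(0, 900, n)
        p = np.round(rng.uniform(0, 900, n), -1)  # coarse rounding forces ties
        assert auc_at_threshold(y, p, 430.0) == pytest.approx(
            _auc_bruteforce(y, p, 430.0), abs=1e-12
        )


def test_auc_single_class_errors():
    with pytest.raises(DiscriminationError):
        auc_at_threshold([500.0, 600.0, 700.0], [1.0, 2.0, 3.0], 430.0)


# -- bootstrap CI ---------------------------------------------------------

def test_bootstrap_ci_constant_statistic():
    data = (np.arange(100, dtype=float),)
    lo, hi = bootstrap_ci(lambda x: 7.0, data, n_reps=200, seed=0)
    assert lo == hi == 7.0


def test_bootstrap_ci_width_matches_clt():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(1000)
    lo, hi = bootstrap_ci(lambda v: float(np.mean(v)), (x,), n_reps=2000, seed=1)
    expected_width = 2 * 1.96 / np.sqrt(1000)
    assert (hi - lo) == pytest.approx(expected_width, rel=0.2)


def test_bootstrap_ci_deterministic():
    x = np.random.default_rng(5).standard_normal(200)
    a = bootstrap_ci(lambda v: float(np.median(v)), (x,), n_reps=500, seed=9)
    b = bootstrap_ci(lambda v: float(np.median(v)), (x,), n_reps=500, seed=9)
    assert a == b


# -- performance report ---------------------------------------------------

def test_performance_report_brackets_points(dev_frame, models):
    frame = predict_frame(models["previous_ast"], dev_frame)
    rep = performance_report(
        frame["new_cortisol_30"], frame["pred_point"], n_boot=400, seed=0
    )
    assert rep.n == len(frame)
    for value, ci in [
        (rep.r2, rep.r2_ci),
        (rep.rmse, rep.rmse_ci),
        (rep.calibration_slope, rep.calibration_slope_ci),
        (rep.auc, rep.auc_ci),
    ]:
        assert ci[0] <= value <= ci[1]
    assert rep.r2 <= 1.0
    assert 0.0 <= rep.auc <= 1.0
    # generated at noise SD 73.4: RMSE should sit near it
    assert 55 < rep.rmse < 95


# -- grouped cross-validation ---------------------------------------------

def test_cross_validation_partitions_and_generalizes():
    cfg = development_config(n_pairs=240, seed=55).with_overrides(acth_missing_rate=0.0)
    frame = prepare_analysis_frame(generate_cohort(cfg))
    dev_config = DevelopmentConfig(
        n_bootstrap=10, seed=2, candidate_variables=CANDIDATES_NO_ACTH
    )
    cv = cross_validate_groups(frame, "sex", dev_config, n_boot=100)
    assert sum(cv.group_sizes.values()) == len(frame)
    assert set(cv.groups) == set(cv.models)
    pooled = predict_frame(published_models()["previous_ast"], frame)
    pooled_r2 = calibration_stats(pooled["new_cortisol_30"], pooled["pred_point"]).r2
    for g, rep in cv.groups.items():
        # both sexes come from one mechanism: held-out fit close to pooled fit
        assert rep.r2 == pytest.approx(pooled_r2, abs=0.15), g


def test_cross_validation_single_group_errors(dev_frame):
    mono = dev_frame.assign(sex="female")
    with pytest.raises(GroupingError):
        cross_validate_groups(
            mono, "sex", DevelopmentConfig(n_bootstrap=2, candidate_variables=CANDIDATES_NO_ACTH)
        )
    with pytest.raises(GroupingError):
        cross_validate_groups(
            dev_frame, "nonexistent", DevelopmentConfig(n_bootstrap=2)
        )


def test_cross_validation_merges_small_groups(dev_frame):
    n = len(dev_frame)
    labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    # a tiny stratum containing both outcome classes, to be merged into "other"
    y = dev_frame["new_cortisol_30"].to_numpy()
    tiny_idx = np.concatenate([np.where(y >= 430)[0][:4], np.where(y < 430)[0][:4]])
    labels[tiny_idx] = "tiny"
    frame = dev_frame.assign(ai_type=labels)
    with pytest.warns(UserWarning, match="merged"):
        cv = cross_validate_groups(
            frame,
            "ai_type",
            DevelopmentConfig(n_bootstrap=5, seed=1, candidate_variables=CANDIDATES_NO_ACTH),
            n_boot=50,
        )
    assert "other" in cv.groups


# -- model comparison -----------------------------------------------------

def test_compare_models_identity():
    y = np.random.default_rng(6).uniform(0, 900, 100)
    p = y + 10
    cmp = compare_models(y, p, p, params_a=2, params_b=4)
    assert cmp.statistic == 0.0
    assert cmp.delta_r2 == 0.0
    assert cmp.pvalue == 1.0


def test_compare_models_detects_richer_truth(dev_frame, models):
    """On cohorts generated by the richer mechanism the nested test is decisive."""
    frame = predict_frame(models["previous_ast"], dev_frame, prefix="rich_")
    frame = predict_frame(models["morning_only"], frame, prefix="poor_")
    y = frame["new_cortisol_30"]
    cmp = compare_models(
        y, frame["poor_point"], frame["rich_point"], params_a=2, params_b=4
    )
    assert cmp.pvalue < 0.001
    assert cmp.delta_r2 > 0
    # delta_r2 is exactly the difference of calibration r2 values
    direct = (
        calibration_stats(y, frame["rich_point"]).r2
        - calibration_stats(y, frame["poor_point"]).r2
    )
    assert cmp.delta_r2 == pytest.approx(direct, abs=1e-12)


def test_compare_models_requires_nesting():
    y = np.arange(10, dtype=float)
    with pytest.raises(ConfigurationError):
        compare_models(y, y, y, params_a=3, params_b=3)
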