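"""Calibration, discrimination and cross-validation statistics.

Calibration is summarized by R-squared (1 - SSE/SST around the observed
mean), root-mean-squared error, and the slope/intercept of regressing the
observed outcome on the prediction (ideal 1 and 0; slope below 1 indicates
overfitting).  Discrimination is the area under the ROC curve for detecting
a pass (observed 30-minute cortisol at or above the threshold) from the
continuous prediction, computed as the Mann-Whitney concordance probability
with ties counted one half.  Confidence intervals are percentile bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .development import DevelopmentConfig, develop_model
from .errors import (
    CalibrationError,
    CiError,
    ConfigurationError,
    DiscriminationError,
    GroupingError,
)
from .models import ModelSpec, predict_frame

__all__ = [
    "CalibrationStats",
    "PerformanceReport",
    "GroupedCvReport",
    "ModelComparison",
    "calibration_stats",
    "auc_at_threshold",
    "bootstrap_ci",
    "performance_report",
    "cross_validate_groups",
    "compare_models",
]


@dataclass(frozen=True)
class CalibrationStats:
    r2: float
    rmse: float
    slope: float
    intercept: float


def calibration_stats(observed, predicted) -> CalibrationStats:
    """Calibration of continuous predictions against observations.

    ``r2 = 1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)`` — this is the
    proportion of variance explained by the predictions as given and may be
    negative on external data.  Slope and intercept come from least-squares
    regression of observed on predicted.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise CalibrationError("observed and predicted must be equal-length 1-D sequences")
    if len(y) < 3:
        raise CalibrationError(f"need at least 3 observations, got {len(y)}")
    if np.ptp(p) == 0:
        raise CalibrationError("constant predictions: calibration slope undefined")
    sse = float(np.sum((y - p) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    design = np.column_stack([np.ones_like(p), p])
    (intercept, slope), *_ = np.linalg.lstsq(design, y, rcond=None)
    return CalibrationStats(
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(sse / len(y))),
        slope=float(slope),
        intercept=float(intercept),
    )


def auc_at_threshold(observed, predicted, threshold: float = 430.0) -> float:
    """ROC area for detecting a pass (observed >= threshold) from predictions.

    Mann-Whitney concordance probability with tied predictions counted 1/2,
    computed from average ranks.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    passes = y >= threshold
    n1 = int(passes.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DiscriminationError(
            f"both outcome classes required at threshold {threshold}; got {n1} passes / {n0} fails"
        )
    ranks = rankdata(p)
    u = ranks[passes].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    statistic: Callable,
    data,
    n_reps: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic``.

    ``data`` is a DataFrame or a tuple of aligned 1-D arrays; ``statistic``
    receives the resampled object(s) and returns a float.  Resamples on which
    the statistic raises are skipped; more than 5% failures aborts.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(data, pd.DataFrame):
        n = len(data)
        take = lambda idx: (data.iloc[idx],)
    else:
        arrays = tuple(np.asarray(a) for a in data)
        n = len(arrays[0])
        take = lambda idx: tuple(a[idx] for a in arrays)
    values = []
    failures = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(statistic(*take(idx))))
        except Exception:
            failures += 1
            if failures > 0.05 * n_reps:
                raise CiError(
                    f"statistic failed on more than 5% of {n_reps} resamples"
                ) from None
    lo, hi = np.percentile(values, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return float(lo), float(hi)


@dataclass(frozen=True)
class PerformanceReport:
    """Point estimates with 95% CI bounds for the five performance measures."""

    r2: float
    r2_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    calibration_slope: float
    calibration_slope_ci: tuple[float, float]
    calibration_intercept: float
    calibration_intercept_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    n: int
    pass_threshold: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pass_threshold": self.pass_threshold,
            "r2": {"value": self.r2, "ci": list(self.r2_ci)},
            "rmse": {"value": self.rmse, "ci": list(self.rmse_ci)},
            "calibration_slope": {"value": self.calibration_slope, "ci": list(self.calibration_slope_ci)},
            "calibration_intercept": {
                "value": self.calibration_intercept,
                "ci": list(self.calibration_intercept_ci),
            },
            "auc": {"value": self.auc, "ci": list(self.auc_ci)},
        }


def performance_report(
    observed,
    predicted,
    pass_threshold: float = 430.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> PerformanceReport:
    """Full performance summary with shared-resample percentile bootstrap CIs."""
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    point = calibration_stats(y, p)
    auc = auc_at_threshold(y, p, pass_threshold)

    rng = np.random.default_rng(seed)
    n = len(y)
    stats: dict[str, list[float]] = {k: [] for k in ("r2", "rmse", "slope", "intercept", "auc")}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            cs = calibration_stats(y[idx], p[idx])
        except CalibrationError:
            continue
        stats["r2"].append(cs.r2)
        stats["rmse"].append(cs.rmse)
        stats["slope"].append(cs.slope)
        stats["intercept"].append(cs.intercept)
        try:
            stats["auc"].append(auc_at_threshold(y[idx], p[idx], pass_threshold))
        except DiscriminationError:
            pass

    def ci(name: str) -> tuple[float, float]:
        vals = stats[name]
        if len(vals) < max(0.5 * n_boot, 2):
            raise CiError(f"too few valid bootstrap resamples for {name}")
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return float(lo), float(hi)

    return PerformanceReport(
        r2=point.r2,
        r2_ci=ci("r2"),
        rmse=point.rmse,
        rmse_ci=ci("rmse"),
        calibration_slope=point.slope,
        calibration_slope_ci=ci("slope"),
        calibration_intercept=point.intercept,
        calibration_intercept_ci=ci("intercept"),
        auc=auc,
        auc_ci=ci("auc"),
        n=n,
        pass_threshold=pass_threshold,
    )


_GROUPING_COLUMNS = {"sex": "sex", "ai_type": "ai_type", "steroid": "steroid_route"}


@dataclass(frozen=True)
class GroupedCvReport:
    """Leave-one-group-out cross-validation results."""

    grouping: str
    groups: Mapping[str, PerformanceReport]
    models: Mapping[str, ModelSpec]
    group_sizes: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "groups": {k: v.to_dict() for k, v in self.groups.items()},
            "group_sizes": dict(self.group_sizes),
            "models": {k: v.to_dict() for k, v in self.models.items()},
        }


def cross_validate_groups(
    frame: pd.DataFrame,
    grouping: str,
    dev_config: DevelopmentConfig,
    pass_threshold: float = 430.0,
    n_boot: int = 500,
    min_group: int = 10,
) -> GroupedCvReport:
    """Develop on the complement of each group, evaluate on the held-out group.

    ``grouping`` is one of ``sex``, ``ai_type``, ``steroid`` (steroid route)
    or any categorical column name.  Groups smaller than ``min_group`` are
    merged into ``other`` with a warning.
    """
    column = _GROUPING_COLUMNS.get(grouping, grouping)
    if column not in frame.columns:
        raise GroupingError(f"grouping variable {grouping!r} (column {column!r}) absent")
    labels = frame[column].astype(str)
    counts = labels.value_counts()
    small = [g for g, c in counts.items() if c < min_group]
    if small:
        warnings.warn(
            f"groups {small} have fewer than {min_group} pairs; merged into 'other'",
            UserWarning,
            stacklevel=2,
        )
        labels = labels.where(~labels.isin(small), "other")
        counts = labels.value_counts()
    if len(counts) < 2:
        raise GroupingError(f"grouping {grouping!r} yields fewer than 2 usable groups")

    groups: dict[str, PerformanceReport] = {}
    models: dict[str, ModelSpec] = {}
    sizes: dict[str, int] = {}
    for g in counts.index:
        held = labels == g
        dev = frame.loc[~held]
        report = develop_model(dev, dev_config)
        evaluated = predict_frame(report.final, frame.loc[held])
        groups[g] = performance_report(
            evaluated["new_cortisol_30"],
            evaluated["pred_point"],
            pass_threshold=pass_threshold,
            n_boot=n_boot,
            seed=dev_config.seed,
        )
        models[g] = report.final
        sizes[g] = int(held.sum())
    return GroupedCvReport(grouping=grouping, groups=groups, models=models, group_sizes=sizes)


@dataclass(frozen=True)
class ModelComparison:
    statistic: float
    df: int
    pvalue: float
    delta_r2: float


def compare_models(
    observed,
    predicted_a,
    predicted_b,
    params_a: int,
    params_b: int,
) -> ModelComparison:
    """Likelihood-ratio comparison of two nested Gaussian prediction models.

    Model b must nest model a (``params_b > params_a``).  The statistic is
    ``n * ln(SSE_a / SSE_b)`` on ``params_b - params_a`` degrees of freedom;
    ``delta_r2`` is the gain in proportion of variance explained.
    """
    if params_b <= params_a:
        raise ConfigurationError(
            f"models not nested: params_b ({params_b}) must exceed params_a ({params_a})"
        )
    y = np.asarray(observed, dtype=float)
    pa = np.asarray(predicted_a, dtype=float)
    pb = np.asarray(predicted_b, dtype=float)
    n = len(y)
    sse_a = float(np.sum((y - pa) ** 2))
    sse_b = float(np.sum((y - pb) ** 2))
    if sse_a == sse_b:
        stat = 0.0
    elif sse_b == 0:
        stat = float("inf")
    else:
        stat = n * float(np.log(sse_a / sse_b))
    stat = max(stat, 0.0)
    df = params_b - params_a
    pvalue = float(chi2.sf(stat, df))
    delta_r2 = calibration_stats(y, pb).r2 - calibration_stats(y, pa).r2
    return ModelComparison(statistic=stat, df=df, pvalue=pvalue, delta_r2=delta_r2)
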