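"""Equivocal-range decision policies: how many stimulation tests are saved.

The policy acts directly on a model's predicted 30-minute cortisol:
predictions strictly below a low threshold are accepted as adrenal
insufficiency, predictions strictly above a high threshold as adequate
adrenal function, and only the equivocal range in between proceeds to an
actual stimulation test.  The low threshold is tied to a target sensitivity
for detecting a pass (so that few patients who would pass are labelled
insufficient is controlled via the ROC operating point), the high threshold
to a target specificity (few patients who would fail are labelled
sufficient).  The proportion of predictions outside the equivocal range is
the proportion of tests saved.

Threshold searches use candidate cut points at midpoints between consecutive
sorted unique predictions, with -inf/+inf sentinels, so results do not depend
on the observed outcome values themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PolicyError

__all__ = [
    "BenefitPolicy",
    "threshold_for_sensitivity",
    "threshold_for_specificity",
    "two_threshold_policy",
    "proportion_saved",
    "benefit_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenefitPolicy:
    """An equivocal prediction range with its attained operating statistics.

    ``sensitivity`` is the attained ROC sensitivity for detecting a pass at
    the low threshold, P(prediction > low | observed pass); ``specificity``
    the attained specificity at the high threshold,
    P(prediction <= high | observed fail).  ``proportion_saved`` is the
    fraction of cases predicted outside the open equivocal interval (ties on
    a threshold stay equivocal and proceed to testing).
    """

    low_threshold: float
    high_threshold: float
    sensitivity: float
    specificity: float
    proportion_saved: float
    pass_threshold: float = 430.0

    def __post_init__(self):
        if self.low_threshold > self.high_threshold:
            raise PolicyError(
                f"low_threshold {self.low_threshold} exceeds high_threshold {self.high_threshold}"
            )

    def classify(self, prediction):
        """'insufficient' | 'equivocal' | 'sufficient' (vectorized over arrays)."""
        p = np.asarray(prediction, dtype=float)
        out = np.where(
            p < self.low_threshold,
            "insufficient",
            np.where(p > self.high_threshold, "sufficient", "equivocal"),
        )
        return out.item() if np.ndim(prediction) == 0 else out


def _candidate_thresholds(predicted: np.ndarray) -> np.ndarray:
    uniq = np.unique(predicted)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.empty(0)
    return np.concatenate([[-np.inf], mids, [np.inf]])


def _classes(observed: np.ndarray, pass_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    passes = observed >= pass_threshold
    if passes.all() or (~passes).all():
        raise PolicyError(
            f"both outcome classes required at pass threshold {pass_threshold}"
        )
    return passes, ~passes


def threshold_for_sensitivity(
    observed, predicted, target: float, pass_threshold: float = 430.0
) -> float:
    """Low threshold: the largest cut point t with pass-sensitivity >= target.

    Sensitivity here is the ROC sensitivity for detecting an observed pass
    from the prediction, P(prediction > t | observed pass).  Among cut points
    meeting the target, the largest is returned, which maximizes the attained
    specificity P(prediction <= t | observed fail): predictions below it are
    then safe to accept as insufficiency.
    """
    if not 0 < target <= 1:
        raise PolicyError(f"target sensitivity must be in (0, 1], got {target}")
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    passes, _ = _classes(y, pass_threshold)
    pass_preds = p[passes]
    best = None
    for t in _candidate_thresholds(p):
        sens = float(np.mean(pass_preds > t))
        if sens >= target:
            best = t  # candidates ascend; keep the largest qualifying
    if best is None:
        raise PolicyError(f"sensitivity target {target} unattainable")
    return float(best)


def threshold_for_specificity(
    observed, predicted, target: float, pass_threshold: float = 430.0
) -> float:
    """High threshold: the smallest cut point t with fail-specificity >= target.

    Specificity is P(prediction <= t | observed fail); predictions above the
    returned cut point are safe to accept as adequate adrenal function.  The
    smallest qualifying cut point maximizes the attained sensitivity
    P(prediction > t | observed pass).
    """
    if not 0 < target <= 1:
        raise PolicyError(f"target specificity must be in (0, 1], got {target}")
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    _, fails = _classes(y, pass_threshold)
    fail_preds = p[fails]
    for t in _candidate_thresholds(p):
        spec = float(np.mean(fail_preds <= t))
        if spec >= target:
            return float(t)
    raise PolicyError(f"specificity target {target} unattainable")


def two_threshold_policy(
    observed,
    predicted,
    sensitivity_target: float = 0.95,
    specificity_target: float = 0.95,
    pass_threshold: float = 430.0,
) -> BenefitPolicy:
    """The two-threshold equivocal-range policy at the given targets.

    If the low threshold exceeds the high one (a model good enough that the
    operating points cross), both collapse to their midpoint: the equivocal
    range is empty and every prediction is acted on.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    low = threshold_for_sensitivity(y, p, sensitivity_target, pass_threshold)
    high = threshold_for_specificity(y, p, specificity_target, pass_threshold)
    if low > high:
        low = high = (low + high) / 2.0
    passes, fails = _classes(y, pass_threshold)
    sens = float(np.mean(p[passes] > low))
    spec = float(np.mean(p[fails] <= high))
    saved = float(np.mean((p < low) | (p > high)))
    return BenefitPolicy(
        low_threshold=low,
        high_threshold=high,
        sensitivity=sens,
        specificity=spec,
        proportion_saved=saved,
        pass_threshold=pass_threshold,
    )


def proportion_saved(observed, predicted, policy: BenefitPolicy) -> float:
    """Fraction of cases whose prediction escapes the equivocal range.

    Strictly below the low threshold or strictly above the high one; values
    equal to a threshold remain equivocal and still go to testing.
    ``observed`` is accepted for signature symmetry but unused.
    """
    p = np.asarray(predicted, dtype=float)
    return float(np.mean((p < policy.low_threshold) | (p > policy.high_threshold)))


def benefit_curve(
    observed,
    predicted,
    sensitivity_grid: Sequence[float],
    specificity_grid: Sequence[float],
    pass_threshold: float = 430.0,
) -> pd.DataFrame:
    """One policy per (sensitivity, specificity) grid point.

    Returns a flat table with columns ``sensitivity_target``,
    ``specificity_target``, ``low``, ``high``, ``saved_low`` (fraction
    accepted as insufficient), ``saved_high`` (fraction accepted as
    sufficient) and ``saved_total``.  Grid points whose targets are
    unattainable are skipped with a logged warning.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    rows = []
    for s in sensitivity_grid:
        for sp in specificity_grid:
            try:
                policy = two_threshold_policy(y, p, s, sp, pass_threshold)
            except PolicyError as exc:
                log.warning("skipping grid point (sens=%s, spec=%s): %s", s, sp, exc)
                continue
            saved_low = float(np.mean(p < policy.low_threshold))
            saved_high = float(np.mean(p > policy.high_threshold))
            rows.append(
                {
                    "sensitivity_target": s,
                    "specificity_target": sp,
                    "low": policy.low_threshold,
                    "high": policy.high_threshold,
                    "attained_sensitivity": policy.sensitivity,
                    "attained_specificity": policy.specificity,
                    "saved_low": saved_low,
                    "saved_high": saved_high,
                    "saved_total": saved_low + saved_high,
                }
            )
    return pd.DataFrame(rows)
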