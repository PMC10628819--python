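"""Fractional-polynomial linear prediction models for the short Synacthen test.

The central object is :class:`ModelSpec`: an intercept plus a sum of FP1
(single-power fractional polynomial) terms, each acting on a scaled positive
covariate.  Two models with fixed published coefficients are shipped with the
package and returned by :func:`published_models`:

``morning_only``
    30-minute cortisol = -54.476 + 325.134 * sqrt(new baseline cortisol / 100)

``previous_ast``
    30-minute cortisol = -116.5 + 251.5 * sqrt(new baseline cortisol / 100)
    - 49.4 * (previous baseline cortisol / 100)
    + 714.3 * (previous 30-minute cortisol / 1000)

All cortisol values are in nmol/L.  A predicted 30-minute cortisol at or above
the pass threshold (430 nmol/L by default) classifies the patient as adrenally
sufficient; the residual standard deviation of each model converts a point
prediction into a probability of passing a repeat test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import DomainError, MissingCovariateError, RangeError

__all__ = [
    "FP_POWERS",
    "FpTerm",
    "ModelSpec",
    "Prediction",
    "fp_transform",
    "pass_probability",
    "predict",
    "predict_frame",
    "published_models",
    "invert_single_covariate",
]

#: Allowed FP1 powers; 0 denotes the natural logarithm of the scaled value.
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Plausibility windows (warnings only, not hard limits). Cortisol in nmol/L,
#: ACTH in ng/L. Sample ranges in real cohorts are narrower; these are sanity
#: bounds beyond which an input is most likely a unit or entry error.
PLAUSIBILITY_WINDOWS = {
    "cortisol": (0.0, 2000.0),
    "acth": (0.0, 500.0),
}


def _plausibility_window(variable: str) -> tuple[float, float] | None:
    if "acth" in variable and "ratio" not in variable:
        return PLAUSIBILITY_WINDOWS["acth"]
    if "cortisol" in variable:
        return PLAUSIBILITY_WINDOWS["cortisol"]
    return None


def fp_transform(value, scale_divisor: float, power: float):
    """Apply an FP1 transform: ``(value / scale_divisor) ** power``.

    Power 0 denotes the natural logarithm of the scaled value.  Zero values
    are admissible only for powers >= 0.5 (where the transform is finite).

    Parameters
    ----------
    value : float or array-like
        Covariate value(s), in original units; must be positive (nonnegative
        for powers >= 0.5).
    scale_divisor : float
        Positive scaling constant (100 for baseline cortisol, 1000 for
        30-minute cortisol in the published models).
    power : float
        One of :data:`FP_POWERS`.
    """
    if scale_divisor <= 0:
        raise DomainError(f"scale_divisor must be positive, got {scale_divisor}")
    if power not in FP_POWERS:
        raise DomainError(f"power {power} not in allowed set {FP_POWERS}")
    x = np.asarray(value, dtype=float) / scale_divisor
    if power >= 0.5:
        if np.any(x < 0):
            raise DomainError(f"negative value under power {power}")
    else:
        if np.any(x <= 0):
            raise DomainError(f"nonpositive value under power {power} (log/negative powers need value > 0)")
    if power == 0.0:
        out = np.log(x)
    else:
        out = np.power(x, power)
    if np.ndim(value) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class FpTerm:
    """One FP1 regression term.

    ``coefficient`` is the final (post-shrinkage) coefficient in outcome units
    per transformed unit; ``shrinkage_factor`` records the multiplicative
    optimism correction that produced it and is metadata, not re-applied at
    prediction time.
    """

    variable: str
    scale_divisor: float
    power: float
    coefficient: float
    shrinkage_factor: float = 1.0
    standard_error: float | None = None

    def __post_init__(self):
        if self.scale_divisor <= 0:
            raise DomainError(f"term {self.variable}: scale_divisor must be positive")
        if self.power not in FP_POWERS:
            raise DomainError(f"term {self.variable}: power {self.power} not in {FP_POWERS}")

    def transform(self, value):
        return fp_transform(value, self.scale_divisor, self.power)

    def contribution(self, value):
        """Coefficient times transformed value."""
        t = self.transform(value)
        return self.coefficient * t if np.ndim(t) == 0 else self.coefficient * np.asarray(t)


@dataclass(frozen=True)
class ModelSpec:
    """An intercept plus FP1 terms, with the residual SD and pass threshold.

    ``residual_sd`` is the development root-mean-squared error in nmol/L and
    drives prediction intervals and pass probabilities.
    """

    name: str
    intercept: float
    terms: tuple[FpTerm, ...]
    residual_sd: float
    pass_threshold: float = 430.0

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        names = [t.variable for t in self.terms]
        if len(set(names)) != len(names):
            raise DomainError(f"model {self.name}: duplicate term variables {names}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(t.variable for t in self.terms)

    @property
    def n_parameters(self) -> int:
        """Number of estimated parameters (intercept + terms)."""
        return 1 + len(self.terms)

    def linear_predictor(self, covariates: Mapping):
        """Point prediction (nmol/L). Accepts scalars or aligned arrays/Series."""
        total = None
        for term in self.terms:
            try:
                value = covariates[term.variable]
            except KeyError:
                raise MissingCovariateError(
                    f"model {self.name!r} requires covariate {term.variable!r}"
                ) from None
            window = _plausibility_window(term.variable)
            if window is not None:
                arr = np.asarray(value, dtype=float)
                if np.any((arr < window[0]) | (arr > window[1])):
                    warnings.warn(
                        f"{term.variable} outside plausibility window {window}; "
                        "prediction returned anyway",
                        UserWarning,
                        stacklevel=2,
                    )
            contrib = term.contribution(value)
            total = contrib if total is None else total + contrib
        if total is None:
            total = 0.0
        return self.intercept + total

    def predict(self, covariates: Mapping, coverage: float = 0.95, policy=None) -> "Prediction":
        return predict(self, covariates, coverage=coverage, policy=policy)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": float(self.intercept),
            "residual_sd": float(self.residual_sd),
            "pass_threshold": float(self.pass_threshold),
            "terms": [
                {
                    "variable": t.variable,
                    "scale_divisor": float(t.scale_divisor),
                    "power": float(t.power),
                    "coefficient": float(t.coefficient),
                    "shrinkage_factor": float(t.shrinkage_factor),
                    "standard_error": None if t.standard_error is None else float(t.standard_error),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelSpec":
        terms = tuple(
            FpTerm(
                variable=t["variable"],
                scale_divisor=float(t["scale_divisor"]),
                power=float(t["power"]),
                coefficient=float(t["coefficient"]),
                shrinkage_factor=float(t.get("shrinkage_factor", 1.0)),
                standard_error=(
                    None if t.get("standard_error") is None else float(t["standard_error"])
                ),
            )
            for t in data["terms"]
        )
        return cls(
            name=str(data["name"]),
            intercept=float(data["intercept"]),
            terms=terms,
            residual_sd=float(data["residual_sd"]),
            pass_threshold=float(data.get("pass_threshold", 430.0)),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Prediction:
    """A point prediction with interval, pass probability, and classification.

    ``classification`` is one of ``insufficient``/``equivocal``/``sufficient``
    when an equivocal-range policy is supplied, else ``None``.  The point is
    not clipped at zero: calibration work needs the raw linear predictor.
    """

    point: float
    interval_low: float
    interval_high: float
    pass_probability: float
    classification: str | None = None
    coverage: float = 0.95

    @property
    def point_display(self) -> float:
        """User-facing value: floored at 0 and rounded to the nearest 1 nmol/L."""
        return float(round(max(self.point, 0.0)))


def pass_probability(point: float, residual_sd: float, threshold: float) -> float:
    """Probability that the realized 30-minute cortisol reaches ``threshold``.

    Models the outcome as Gaussian with mean ``point`` and SD ``residual_sd``.
    """
    if residual_sd <= 0:
        raise DomainError("residual_sd must be positive for pass probabilities")
    return float(norm.sf((threshold - point) / residual_sd))


def predict(model: ModelSpec, covariates: Mapping, coverage: float = 0.95, policy=None) -> Prediction:
    """Evaluate ``model`` at ``covariates`` and package the result.

    The interval is normal-theory ``point +- z * residual_sd`` (coefficient
    estimation uncertainty ignored).  ``policy`` may be any object with
    ``low_threshold``/``high_threshold`` attributes (see the benefit module);
    classification uses strict inequalities, ties fall in the equivocal range.
    """
    point = float(model.linear_predictor(covariates))
    z = norm.ppf(0.5 + coverage / 2.0)
    prob = pass_probability(point, model.residual_sd, model.pass_threshold)
    classification = None
    if policy is not None:
        if point < policy.low_threshold:
            classification = "insufficient"
        elif point > policy.high_threshold:
            classification = "sufficient"
        else:
            classification = "equivocal"
    return Prediction(
        point=point,
        interval_low=point - z * model.residual_sd,
        interval_high=point + z * model.residual_sd,
        pass_probability=prob,
        classification=classification,
        coverage=coverage,
    )


def predict_frame(model: ModelSpec, frame, prefix: str = "pred_", coverage: float = 0.95):
    """Append prediction columns to a paired-test table.

    Adds ``{prefix}point``, ``{prefix}lower``, ``{prefix}upper`` and
    ``{prefix}pass_prob``. Returns a copy.
    """
    out = frame.copy()
    point = np.asarray(model.linear_predictor(out), dtype=float)
    z = norm.ppf(0.5 + coverage / 2.0)
    out[prefix + "point"] = point
    out[prefix + "lower"] = point - z * model.residual_sd
    out[prefix + "upper"] = point + z * model.residual_sd
    out[prefix + "pass_prob"] = norm.sf((model.pass_threshold - point) / model.residual_sd)
    return out


def _load_packaged_model(name: str) -> ModelSpec:
    ref = resources.files("astpredict").joinpath(f"data/models/{name}.yaml")
    with ref.open() as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


def published_models() -> dict[str, ModelSpec]:
    """The two fixed-coefficient models shipped with the package.

    Returns a mapping with keys ``morning_only`` and ``previous_ast``.  The
    coefficients are the parameter-wise shrunken estimates; the residual SD is
    the development RMSE of each model.
    """
    return {name: _load_packaged_model(name) for name in ("morning_only", "previous_ast")}


def invert_single_covariate(
    model: ModelSpec,
    target: float,
    free_variable: str,
    fixed: Mapping | None = None,
    window: tuple[float, float] = (0.0, 2000.0),
    tol: float = 1e-6,
) -> float:
    """Solve for the covariate value whose point prediction equals ``target``.

    Requires the model to be monotone in ``free_variable`` over ``window``
    (guaranteed for a single FP1 term).  Other covariates are held at the
    values given in ``fixed``.

    Raises
    ------
    RangeError
        If ``target`` is not attainable within ``window``.
    """
    fixed = dict(fixed or {})
    term = next((t for t in model.terms if t.variable == free_variable), None)
    if term is None:
        raise MissingCovariateError(f"{free_variable!r} is not a covariate of model {model.name!r}")

    lo, hi = window
    if term.power < 0.5 and lo <= 0:
        lo = 1e-9 * term.scale_divisor  # log/negative powers need a positive lower edge

    def f(v: float) -> float:
        cov = dict(fixed)
        cov[free_variable] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return float(model.linear_predictor(cov)) - target

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if f_lo * f_hi > 0:
        raise RangeError(
            f"target {target} nmol/L unattainable for {free_variable!r} in window [{lo}, {hi}]"
        )
    root = brentq(f, lo, hi, xtol=tol)
    return float(root)
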