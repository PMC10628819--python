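"""Synthetic paired-AST cohort generation.

Real paired short-Synacthen-test data cannot be shared at patient level, so
every downstream stage of this package is exercised on synthetic cohorts that
emulate the published marginal statistics of the development and validation
datasets: truncated log-normal marginals moment-matched to the reported
mean/SD and truncated to the reported ranges, a Gaussian copula linking the
cortisol variables, missing-completely-at-random baseline ACTH, and an
outcome (new 30-minute cortisol) generated from the published previous-AST
model's linear predictor plus Gaussian residual noise, clipped at zero.

One generated row is one pair of tests within one patient:

    previous test  (baseline cortisol, baseline ACTH, 30-minute cortisol)
    new test       (baseline cortisol, baseline ACTH, 30-minute cortisol)

plus the patient strata (sex, AI type, steroid route/formulation) used only
to exercise grouped cross-validation; hormone values are generated
independently of strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import root
from scipy.stats import norm

from .errors import ConfigurationError
from .models import published_models

__all__ = [
    "COHORT_COLUMNS",
    "MarginalSpec",
    "CohortConfig",
    "AstRecord",
    "PairedAst",
    "development_config",
    "validation_config",
    "generate_cohort",
    "inject_missingness",
    "prepare_analysis_frame",
    "read_cohort",
    "write_cohort",
    "frame_to_pairs",
]

#: Fixed column order of the cohort table (CSV schema).
COHORT_COLUMNS = [
    "patient_id",
    "prev_datetime",
    "prev_baseline_cortisol",
    "prev_baseline_acth",
    "prev_cortisol_30",
    "new_datetime",
    "new_baseline_cortisol",
    "new_baseline_acth",
    "new_cortisol_30",
    "sex",
    "ai_type",
    "steroid_route",
    "steroid_formulation",
]

_CONTINUOUS_VARS = (
    "prev_baseline_cortisol",
    "prev_cortisol_30",
    "new_baseline_cortisol",
    "prev_baseline_acth",
    "new_baseline_acth",
    "days_between",
)

# The three cortisol variables share a Gaussian copula; ACTH and days between
# tests are drawn independently.
_COPULA_VARS = ("prev_baseline_cortisol", "prev_cortisol_30", "new_baseline_cortisol")


@dataclass(frozen=True)
class MarginalSpec:
    """Mean/SD and truncation range of one truncated log-normal marginal."""

    mean: float
    sd: float
    lower: float
    upper: float

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"{name}.sd must be positive, got {self.sd}")
        if not (0 <= self.lower < self.upper):
            raise ConfigurationError(
                f"{name}: truncation bounds must satisfy 0 <= lower < upper, "
                f"got [{self.lower}, {self.upper}]"
            )
        if not (self.lower < self.mean < self.upper):
            raise ConfigurationError(f"{name}.mean {self.mean} outside [{self.lower}, {self.upper}]")


def _trunc_lognorm_moments(mu: float, sigma: float, lower: float, upper: float):
    """Mean and SD of a log-normal(mu, sigma) truncated to [lower, upper]."""
    a = (math.log(lower) - mu) / sigma if lower > 0 else -np.inf
    b = (math.log(upper) - mu) / sigma
    z = norm.cdf(b) - norm.cdf(a)
    m1 = math.exp(mu + sigma**2 / 2) * (norm.cdf(b - sigma) - norm.cdf(a - sigma)) / z
    m2 = math.exp(2 * mu + 2 * sigma**2) * (norm.cdf(b - 2 * sigma) - norm.cdf(a - 2 * sigma)) / z
    var = max(m2 - m1**2, 0.0)
    return m1, math.sqrt(var)


def _match_trunc_lognorm(spec: MarginalSpec) -> tuple[float, float]:
    """Solve for (mu, sigma) so the TRUNCATED moments match the target mean/SD."""
    cv2 = (spec.sd / spec.mean) ** 2
    sigma0 = math.sqrt(math.log1p(cv2))
    mu0 = math.log(spec.mean) - sigma0**2 / 2

    def eqs(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        m, s = _trunc_lognorm_moments(mu, sigma, spec.lower, spec.upper)
        return [m - spec.mean, s - spec.sd]

    sol = root(eqs, x0=[mu0, math.log(sigma0)], method="hybr")
    if not sol.success:
        # The untruncated moment match is an adequate fallback when truncation
        # removes almost no mass; otherwise refuse.
        m, s = _trunc_lognorm_moments(mu0, sigma0, spec.lower, spec.upper)
        if abs(m - spec.mean) < 0.02 * spec.mean and abs(s - spec.sd) < 0.05 * spec.sd:
            return mu0, sigma0
        raise ConfigurationError(
            f"cannot moment-match truncated log-normal to mean={spec.mean}, sd={spec.sd}, "
            f"range=[{spec.lower}, {spec.upper}]"
        )
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _trunc_lognorm_ppf(u, mu: float, sigma: float, lower: float, upper: float):
    """Quantile function of the truncated log-normal, u in (0, 1)."""
    a = norm.cdf((math.log(lower) - mu) / sigma) if lower > 0 else 0.0
    b = norm.cdf((math.log(upper) - mu) / sigma)
    p = a + np.asarray(u) * (b - a)
    x = np.exp(mu + sigma * norm.ppf(p))
    return np.clip(x, lower if lower > 0 else np.nextafter(0, 1), upper)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a paired-AST cohort deterministically."""

    n_pairs: int
    seed: int = 0
    marginals: Mapping[str, MarginalSpec] = field(default_factory=dict)
    #: Pairwise Gaussian-copula correlation among the three cortisol variables.
    correlation: float = 0.7
    #: Residual SD (nmol/L) of the outcome around the generating model.
    outcome_noise_sd: float = 73.4
    #: Probability that each baseline ACTH value is missing (MCAR).
    acth_missing_rate: float = 21.0 / 258.0
    group_proportions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    start_date: str = "2016-08-01"
    window_days: int = 1826

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise ConfigurationError(f"n_pairs must be positive, got {self.n_pairs}")
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError(f"correlation must be in [-1, 1], got {self.correlation}")
        if self.outcome_noise_sd < 0:
            raise ConfigurationError(f"outcome_noise_sd must be >= 0, got {self.outcome_noise_sd}")
        if not 0.0 <= self.acth_missing_rate <= 1.0:
            raise ConfigurationError(
                f"acth_missing_rate must be in [0, 1], got {self.acth_missing_rate}"
            )
        missing = [v for v in _CONTINUOUS_VARS if v not in self.marginals]
        if missing:
            raise ConfigurationError(f"marginals missing for: {missing}")
        for name, spec in self.marginals.items():
            spec.validate(f"marginals[{name}]")
        for stratum, props in self.group_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"group_proportions[{stratum}] must sum to 1, got {total}"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError(f"group_proportions[{stratum}] has negative entries")

    def with_overrides(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "correlation": self.correlation,
            "outcome_noise_sd": self.outcome_noise_sd,
            "acth_missing_rate": self.acth_missing_rate,
            "start_date": self.start_date,
            "window_days": self.window_days,
            "marginals": {
                k: {"mean": v.mean, "sd": v.sd, "lower": v.lower, "upper": v.upper}
                for k, v in self.marginals.items()
            },
            "group_proportions": {k: dict(v) for k, v in self.group_proportions.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        marginals = {
            k: MarginalSpec(float(v["mean"]), float(v["sd"]), float(v["lower"]), float(v["upper"]))
            for k, v in data.get("marginals", {}).items()
        }
        return cls(
            n_pairs=int(data["n_pairs"]),
            seed=int(data.get("seed", 0)),
            marginals=marginals,
            correlation=float(data.get("correlation", 0.7)),
            outcome_noise_sd=float(data.get("outcome_noise_sd", 73.4)),
            acth_missing_rate=float(data.get("acth_missing_rate", 21.0 / 258.0)),
            group_proportions={k: dict(v) for k, v in data.get("group_proportions", {}).items()},
            start_date=str(data.get("start_date", "2016-08-01")),
            window_days=int(data.get("window_days", 1826)),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _packaged_config(name: str) -> CohortConfig:
    ref = resources.files("astpredict").joinpath(f"data/{name}.yaml")
    with ref.open() as fh:
        return CohortConfig.from_dict(yaml.safe_load(fh))


def development_config(n_pairs: int = 258, seed: int = 0) -> CohortConfig:
    """Defaults emulating the development cohort (258 paired tests)."""
    return _packaged_config("cohort_development").with_overrides(n_pairs=n_pairs, seed=seed)


def validation_config(n_pairs: int = 111, seed: int = 0) -> CohortConfig:
    """Defaults emulating the prospective validation cohort (111 paired tests)."""
    return _packaged_config("cohort_validation").with_overrides(n_pairs=n_pairs, seed=seed)


# -- record-level types ---------------------------------------------------


@dataclass(frozen=True)
class AstRecord:
    """One stimulation test."""

    patient_id: str
    test_datetime: datetime
    baseline_cortisol: float
    baseline_acth: float | None = None
    cortisol_30: float | None = None
    sex: str = ""
    ai_type: str = ""
    steroid_route: str = ""
    steroid_formulation: str = ""

    def __post_init__(self):
        if not 0 <= self.baseline_cortisol <= 2000:
            raise ConfigurationError(
                f"baseline_cortisol {self.baseline_cortisol} outside [0, 2000] nmol/L"
            )
        if self.baseline_acth is not None and not 0 <= self.baseline_acth <= 500:
            raise ConfigurationError(
                f"baseline_acth {self.baseline_acth} outside [0, 500] ng/L"
            )

    @property
    def ratio(self) -> float | None:
        """Cortisol/ACTH ratio (nmol/ng), absent when ACTH is absent."""
        if self.baseline_acth is None or self.baseline_acth == 0:
            return None
        return self.baseline_cortisol / self.baseline_acth


@dataclass(frozen=True)
class PairedAst:
    """A (previous test, new test) pair within one patient: the unit of analysis."""

    previous: AstRecord
    new: AstRecord

    def __post_init__(self):
        if not self.previous.test_datetime < self.new.test_datetime:
            raise ConfigurationError("previous test must precede the new test")

    @property
    def days_between(self) -> int:
        """Calendar-date difference between the two tests, in days."""
        return (self.new.test_datetime.date() - self.previous.test_datetime.date()).days

    @property
    def prev_ratio(self) -> float | None:
        return self.previous.ratio

    @property
    def new_ratio(self) -> float | None:
        return self.new.ratio


def frame_to_pairs(frame: pd.DataFrame) -> list[PairedAst]:
    """Convert a cohort table into validated :class:`PairedAst` objects."""
    pairs = []
    for row in frame.itertuples(index=False):
        prev = AstRecord(
            patient_id=row.patient_id,
            test_datetime=pd.Timestamp(row.prev_datetime).to_pydatetime(),
            baseline_cortisol=float(row.prev_baseline_cortisol),
            baseline_acth=None if pd.isna(row.prev_baseline_acth) else float(row.prev_baseline_acth),
            cortisol_30=float(row.prev_cortisol_30),
            sex=row.sex,
            ai_type=row.ai_type,
            steroid_route=row.steroid_route,
            steroid_formulation=row.steroid_formulation,
        )
        new = AstRecord(
            patient_id=row.patient_id,
            test_datetime=pd.Timestamp(row.new_datetime).to_pydatetime(),
            baseline_cortisol=float(row.new_baseline_cortisol),
            baseline_acth=None if pd.isna(row.new_baseline_acth) else float(row.new_baseline_acth),
            cortisol_30=None if pd.isna(row.new_cortisol_30) else float(row.new_cortisol_30),
            sex=row.sex,
            ai_type=row.ai_type,
            steroid_route=row.steroid_route,
            steroid_formulation=row.steroid_formulation,
        )
        pairs.append(PairedAst(previous=prev, new=new))
    return pairs


# -- generation -----------------------------------------------------------


def _sample_time_of_day(rng: np.random.Generator, n: int) -> np.ndarray:
    """Minutes after midnight; roughly 09:52 +- 48 min, clipped to 08:15-13:50."""
    minutes = rng.normal(9 * 60 + 52, 48, size=n)
    return np.clip(minutes, 8 * 60 + 15, 13 * 60 + 50)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a paired-AST cohort table.

    The three cortisol covariates are drawn from truncated log-normal
    marginals linked by a Gaussian copula with pairwise correlation
    ``config.correlation``; ACTH and days between tests are independent.  The
    outcome ``new_cortisol_30`` is the published previous-AST model's linear
    predictor plus N(0, outcome_noise_sd) noise, clipped at zero.  Baseline
    ACTH values are then set missing completely at random at
    ``config.acth_missing_rate``.  Deterministic given the seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = config.n_pairs

    # Correlated latent normals for the cortisol variables.
    k = len(_COPULA_VARS)
    corr = np.full((k, k), config.correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, k)) @ chol.T
    u_cortisol = norm.cdf(z)

    values: dict[str, np.ndarray] = {}
    for j, var in enumerate(_COPULA_VARS):
        spec = config.marginals[var]
        mu, sigma = _match_trunc_lognorm(spec)
        values[var] = _trunc_lognorm_ppf(u_cortisol[:, j], mu, sigma, spec.lower, spec.upper)
    for var in ("prev_baseline_acth", "new_baseline_acth", "days_between"):
        spec = config.marginals[var]
        mu, sigma = _match_trunc_lognorm(spec)
        values[var] = _trunc_lognorm_ppf(rng.random(n), mu, sigma, spec.lower, spec.upper)

    days = np.maximum(np.round(values["days_between"]).astype(int), 1)

    # Outcome from the published previous-AST model plus residual noise.
    generator_model = published_models()["previous_ast"]
    lp = np.asarray(
        generator_model.linear_predictor(
            {
                "new_baseline_cortisol": values["new_baseline_cortisol"],
                "prev_baseline_cortisol": values["prev_baseline_cortisol"],
                "prev_cortisol_30": values["prev_cortisol_30"],
            }
        ),
        dtype=float,
    )
    noise = rng.normal(0.0, config.outcome_noise_sd, size=n) if config.outcome_noise_sd > 0 else 0.0
    outcome = np.maximum(lp + noise, 0.0)

    # Dates: previous test uniform in the study window, new test days later.
    offsets = rng.integers(0, config.window_days, size=n)
    start = pd.Timestamp(config.start_date)
    prev_minutes = _sample_time_of_day(rng, n)
    new_minutes = _sample_time_of_day(rng, n)
    prev_dt = start + pd.to_timedelta(offsets, unit="D") + pd.to_timedelta(prev_minutes, unit="m")
    new_dt = (
        start
        + pd.to_timedelta(offsets + days, unit="D")
        + pd.to_timedelta(new_minutes, unit="m")
    )

    # Strata, independent of hormone values.
    strata: dict[str, np.ndarray] = {}
    for stratum in ("sex", "ai_type", "steroid_route", "steroid_formulation"):
        props = config.group_proportions.get(stratum, {"unspecified": 1.0})
        labels = list(props.keys())
        p = np.array([props[l] for l in labels], dtype=float)
        p = p / p.sum()
        strata[stratum] = rng.choice(labels, size=n, p=p)

    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "prev_datetime": prev_dt.round("min"),
            "prev_baseline_cortisol": values["prev_baseline_cortisol"],
            "prev_baseline_acth": values["prev_baseline_acth"],
            "prev_cortisol_30": values["prev_cortisol_30"],
            "new_datetime": new_dt.round("min"),
            "new_baseline_cortisol": values["new_baseline_cortisol"],
            "new_baseline_acth": values["new_baseline_acth"],
            "new_cortisol_30": outcome,
            "sex": strata["sex"],
            "ai_type": strata["ai_type"],
            "steroid_route": strata["steroid_route"],
            "steroid_formulation": strata["steroid_formulation"],
        },
        columns=COHORT_COLUMNS,
    )

    if config.acth_missing_rate > 0:
        frame = inject_missingness(
            frame, "prev_baseline_acth", config.acth_missing_rate, seed=int(rng.integers(2**31))
        )
        frame = inject_missingness(
            frame, "new_baseline_acth", config.acth_missing_rate, seed=int(rng.integers(2**31))
        )
    return frame


_RATIO_PARENTS = {"prev_baseline_acth": "prev_ratio", "new_baseline_acth": "new_ratio"}


def inject_missingness(frame: pd.DataFrame, variable: str, rate: float, seed: int = 0) -> pd.DataFrame:
    """Set ``variable`` missing completely at random with probability ``rate``.

    If derived ratio columns are present and ``variable`` is a baseline ACTH,
    the corresponding ratio is set missing too (ratios are deterministic
    functions of their parents).  Returns a copy.
    """
    if variable not in frame.columns:
        raise ConfigurationError(f"unknown variable {variable!r}")
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"rate must be in [0, 1], got {rate}")
    out = frame.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(len(out)) < rate
    out.loc[mask, variable] = np.nan
    ratio_col = _RATIO_PARENTS.get(variable)
    if ratio_col is not None and ratio_col in out.columns:
        out.loc[mask, ratio_col] = np.nan
    return out


def prepare_analysis_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Add the derived candidate variables: days_between and the two ratios.

    ``days_between`` is the calendar-date difference between tests;
    ``prev_ratio``/``new_ratio`` are baseline cortisol (nmol/L) over baseline
    ACTH (ng/L), absent wherever the ACTH is absent.
    """
    out = frame.copy()
    prev_date = pd.to_datetime(out["prev_datetime"]).dt.normalize()
    new_date = pd.to_datetime(out["new_datetime"]).dt.normalize()
    out["days_between"] = (new_date - prev_date).dt.days
    out["prev_ratio"] = out["prev_baseline_cortisol"] / out["prev_baseline_acth"]
    out["new_ratio"] = out["new_baseline_cortisol"] / out["new_baseline_acth"]
    return out


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write the cohort as CSV: header row, ISO date-times, empty field = missing."""
    out = frame[COHORT_COLUMNS].copy()
    for col in ("prev_datetime", "new_datetime"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    frame = pd.read_csv(path, parse_dates=["prev_datetime", "new_datetime"])
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"cohort file {path} lacks columns: {missing}")
    return frame[COHORT_COLUMNS]
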