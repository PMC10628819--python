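"""Prediction-model development by bootstrap aggregation.

The development procedure, applied to a paired-AST table:

1. draw a bootstrap resample (with replacement, same size as the input);
2. impute missing baseline ACTH within the resample by random forest and
   recompute the cortisol/ACTH ratios;
3. choose each candidate's FP1 power univariably (least residual sum of
   squares over the allowed power set, ties broken toward linearity);
4. multiple linear regression with backwards elimination, removing the
   least significant variable while its p-value exceeds alpha;
5. estimate a parameter-wise shrinkage factor per surviving term by K-fold
   cross-validation calibration and shrink the coefficients.

Steps 1-5 are repeated ``n_bootstrap`` times.  A variable is retained in the
final model if its bootstrap inclusion fraction (share of replicates where it
survived elimination with p <= alpha) reaches ``bif_threshold``; final
coefficients are means of the shrunken per-replicate coefficients, the final
intercept the mean shrunken intercept over all replicates, and the residual
SD the RMSE of the aggregated model on the input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .cohort import prepare_analysis_frame
from .errors import (
    ConfigurationError,
    DevelopmentError,
    ImputationError,
    SelectionError,
    SingularFitError,
)
from .models import FP_POWERS, FpTerm, ModelSpec

__all__ = [
    "CANDIDATES_FULL",
    "CANDIDATES_NO_ACTH",
    "DEFAULT_SCALES",
    "ImputationSettings",
    "DevelopmentConfig",
    "ReplicateFit",
    "DevelopmentReport",
    "impute_random_forest",
    "select_fp_power",
    "refine_fp_powers",
    "fit_backwards",
    "parameterwise_shrinkage",
    "develop_model",
]

#: The eight candidate predictors.
CANDIDATES_FULL = (
    "prev_baseline_acth",
    "prev_baseline_cortisol",
    "prev_cortisol_30",
    "days_between",
    "new_baseline_acth",
    "new_baseline_cortisol",
    "prev_ratio",
    "new_ratio",
)

#: Candidates when baseline ACTH is not measured (drops ACTH and both ratios).
CANDIDATES_NO_ACTH = (
    "prev_baseline_cortisol",
    "prev_cortisol_30",
    "days_between",
    "new_baseline_cortisol",
)

#: Scale divisors applied before the FP transform. The cortisol scales match
#: the published formulas; the others keep transformed values near unit order.
DEFAULT_SCALES = {
    "prev_baseline_cortisol": 100.0,
    "new_baseline_cortisol": 100.0,
    "prev_cortisol_30": 1000.0,
    "prev_baseline_acth": 10.0,
    "new_baseline_acth": 10.0,
    "prev_ratio": 10.0,
    "new_ratio": 10.0,
    "days_between": 100.0,
}

#: Variables that may be imputed. Ratios are recomputed, never imputed.
IMPUTABLE = ("prev_baseline_acth", "new_baseline_acth")

OUTCOME = "new_cortisol_30"


@dataclass(frozen=True)
class ImputationSettings:
    """Random-forest imputation settings: forest size and sweep count."""

    n_trees: int = 50
    n_iterations: int = 3


@dataclass(frozen=True)
class DevelopmentConfig:
    n_bootstrap: int = 5000
    alpha: float = 0.05
    bif_threshold: float = 0.9
    fp_powers: tuple[float, ...] = FP_POWERS
    candidate_variables: tuple[str, ...] = CANDIDATES_FULL
    seed: int = 0
    imputation: ImputationSettings = field(default_factory=ImputationSettings)
    shrinkage_folds: int = 10
    scale_divisors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALES))
    model_name: str = "developed"

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigurationError(f"n_bootstrap must be >= 1, got {self.n_bootstrap}")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 < self.bif_threshold <= 1:
            raise ConfigurationError(f"bif_threshold must be in (0, 1], got {self.bif_threshold}")
        if not self.candidate_variables:
            raise ConfigurationError("candidate_variables must be non-empty")
        unknown = [v for v in self.candidate_variables if v not in DEFAULT_SCALES and v not in self.scale_divisors]
        if unknown:
            raise ConfigurationError(f"no scale divisor for candidates: {unknown}")

    def scale(self, variable: str) -> float:
        return float(self.scale_divisors.get(variable, DEFAULT_SCALES.get(variable, 1.0)))


# -- imputation -----------------------------------------------------------


def impute_random_forest(
    frame: pd.DataFrame,
    seed: int = 0,
    settings: ImputationSettings = ImputationSettings(),
    variables: Sequence[str] = IMPUTABLE,
) -> pd.DataFrame:
    """Impute missing values by iterative random-forest regression.

    Each imputable variable with missing entries is regressed (on originally
    observed rows) against the other continuous variables, including the
    outcome; missing entries start at the column median and are refined over
    ``settings.n_iterations`` sweeps.  Observed values are never modified and
    ratio columns are recomputed from the imputed ACTH afterwards.
    Deterministic given ``seed``.
    """
    out = frame.copy()
    targets = [v for v in variables if v in out.columns and out[v].isna().any()]
    if not targets:
        return out
    for v in targets:
        if out[v].isna().all():
            raise ImputationError(f"variable {v!r} is entirely missing; nothing to learn from")

    feature_pool = [
        c
        for c in (
            "prev_baseline_cortisol",
            "prev_cortisol_30",
            "new_baseline_cortisol",
            "days_between",
            OUTCOME,
        )
        + tuple(variables)
        if c in out.columns
    ]
    observed_masks = {v: out[v].notna().to_numpy() for v in targets}
    # Initial fill: column medians of the observed values.
    work = out[feature_pool].copy()
    for v in targets:
        work[v] = work[v].fillna(work[v].median())

    rng = np.random.default_rng(seed)
    for _ in range(max(settings.n_iterations, 1)):
        for v in targets:
            features = [c for c in feature_pool if c != v]
            obs = observed_masks[v]
            forest = RandomForestRegressor(
                n_estimators=settings.n_trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            forest.fit(work.loc[obs, features], out.loc[obs, v])
            work.loc[~obs, v] = forest.predict(work.loc[~obs, features])

    for v in targets:
        out[v] = work[v]
    if "prev_ratio" in out.columns:
        out["prev_ratio"] = out["prev_baseline_cortisol"] / out["prev_baseline_acth"]
    if "new_ratio" in out.columns:
        out["new_ratio"] = out["new_baseline_cortisol"] / out["new_baseline_acth"]
    return out


# -- FP power selection ---------------------------------------------------


def _design_column(x: np.ndarray, scale: float, power: float) -> np.ndarray:
    z = x / scale
    if power == 0.0:
        return np.log(z)
    return np.power(z, power)


def select_fp_power(
    outcome: np.ndarray,
    predictor: np.ndarray,
    scale_divisor: float,
    powers: Iterable[float] = FP_POWERS,
) -> float:
    """Choose the FP1 power minimizing univariable residual sum of squares.

    Ties (within floating tolerance) are broken toward power 1 (linearity).
    Powers below 0.5 are excluded when the scaled predictor contains
    nonpositive values.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(np.unique(x)) < 3:
        raise SelectionError("need at least 3 distinct predictor values to choose a power")
    powers = [p for p in powers if p in FP_POWERS]
    if np.any(x <= 0):
        powers = [p for p in powers if p >= 0.5]
    if not powers:
        raise SelectionError("no admissible powers for this predictor")

    sst = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-10 * max(sst, 1.0)
    rss = {}
    ones = np.ones_like(y)
    for p in powers:
        t = _design_column(x, scale_divisor, p)
        design = np.column_stack([ones, t])
        _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < 2:
            continue
        rss[p] = float(res[0]) if res.size else float(
            np.sum((y - design @ np.linalg.lstsq(design, y, rcond=None)[0]) ** 2)
        )
    if not rss:
        raise SelectionError("all candidate powers produced degenerate fits")
    best = min(rss.values())
    if 1.0 in rss and rss[1.0] <= best + tol:
        return 1.0
    return float(min((p for p, v in rss.items() if v <= best + tol), key=lambda p: abs(p - 1.0)))


def refine_fp_powers(
    frame: pd.DataFrame,
    candidates: Sequence[str],
    powers: Mapping[str, float],
    config: "DevelopmentConfig",
    outcome: str = OUTCOME,
    max_cycles: int = 3,
) -> dict[str, float]:
    """Refine per-variable FP1 powers within the multivariable model.

    Starting from the univariable choices, cycle through the candidates and
    re-choose each variable's power by the residual sum of squares of the
    joint OLS fit with the other variables held at their current transforms,
    ties broken toward linearity.  Stops when a full cycle changes nothing.
    The marginal (univariable) optimum can differ from the generative power
    when candidates are correlated; the joint refinement recovers it.
    """
    y = frame[outcome].to_numpy(dtype=float)
    current = dict(powers)
    sst = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-10 * max(sst, 1.0)
    for _ in range(max_cycles):
        changed = False
        for v in candidates:
            x_v = frame[v].to_numpy(dtype=float)
            admissible = [p for p in config.fp_powers if p in FP_POWERS]
            if np.any(x_v / config.scale(v) <= 0):
                admissible = [p for p in admissible if p >= 0.5]
            others = [
                _design_column(frame[w].to_numpy(dtype=float), config.scale(w), current[w])
                for w in candidates
                if w != v
            ]
            base = [np.ones_like(y)] + others
            rss = {}
            for p in admissible:
                design = np.column_stack(base + [_design_column(x_v, config.scale(v), p)])
                beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
                if rank < design.shape[1] and p != current[v]:
                    continue
                rss[p] = float(np.sum((y - design @ beta) ** 2))
            if not rss:
                continue
            best = min(rss.values())
            if 1.0 in rss and rss[1.0] <= best + tol:
                choice = 1.0
            else:
                choice = float(
                    min((p for p, r in rss.items() if r <= best + tol), key=lambda p: abs(p - 1.0))
                )
            if choice != current[v]:
                current[v] = choice
                changed = True
        if not changed:
            break
    return current


# -- backwards elimination ------------------------------------------------


@dataclass(frozen=True)
class TermFit:
    variable: str
    scale_divisor: float
    power: float
    coefficient: float
    standard_error: float
    pvalue: float


@dataclass(frozen=True)
class BackwardsFit:
    """Result of backwards elimination: surviving terms plus the intercept."""

    terms: tuple[TermFit, ...]
    intercept: float
    intercept_se: float
    n: int

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(t.variable for t in self.terms)


def _collinear_columns(design: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns involved in a rank deficiency via pivoted QR."""
    q, r, piv = scipy.linalg.qr(design, pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = diag.max() * max(design.shape) * np.finfo(float).eps
    dependent = [piv[i] for i in range(len(diag)) if diag[i] < thresh]
    return [names[j] for j in dependent if j < len(names)]


def fit_backwards(
    frame: pd.DataFrame,
    terms: Sequence[tuple[str, float, float]],
    alpha: float = 0.05,
    outcome: str = OUTCOME,
) -> BackwardsFit:
    """OLS with backwards elimination of ``(variable, scale, power)`` terms.

    Removes the variable with the largest p-value, one at a time, while that
    p-value exceeds ``alpha``; refits after each removal.  May return an
    intercept-only fit.
    """
    if not terms:
        raise ConfigurationError("terms must be non-empty")
    y = frame[outcome].to_numpy(dtype=float)
    current = list(terms)

    while True:
        cols = [_design_column(frame[v].to_numpy(dtype=float), s, p) for v, s, p in current]
        names = [v for v, _, _ in current]
        design = sm.add_constant(np.column_stack(cols), has_constant="add") if cols else np.ones((len(y), 1))
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(design[:, 1:], names)
            raise SingularFitError(f"collinear candidate variables: {bad or names}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(y, design).fit()
        if not current:
            return BackwardsFit(terms=(), intercept=float(fit.params[0]),
                                intercept_se=float(fit.bse[0]), n=len(y))
        pvals = np.nan_to_num(fit.pvalues[1:], nan=1.0)
        worst = int(np.argmax(pvals))
        if pvals[worst] > alpha:
            del current[worst]
            if not current:
                mean = float(y.mean())
                se = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else 0.0
                return BackwardsFit(terms=(), intercept=mean, intercept_se=se, n=len(y))
            continue
        fitted_terms = tuple(
            TermFit(
                variable=v,
                scale_divisor=s,
                power=p,
                coefficient=float(fit.params[i + 1]),
                standard_error=float(fit.bse[i + 1]),
                pvalue=float(pvals[i]),
            )
            for i, (v, s, p) in enumerate(current)
        )
        return BackwardsFit(
            terms=fitted_terms,
            intercept=float(fit.params[0]),
            intercept_se=float(fit.bse[0]),
            n=len(y),
        )


# -- parameter-wise shrinkage ---------------------------------------------


def parameterwise_shrinkage(
    frame: pd.DataFrame,
    terms: Sequence[tuple[str, float, float]],
    outcome: str = OUTCOME,
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Per-term multiplicative shrinkage factors by K-fold CV calibration.

    For each fold, the model is fitted on the training part and the
    out-of-fold per-term contributions ``b_j * x_j`` are collected; the
    outcome is then regressed jointly on those contributions (intercept
    re-estimated).  The slope on each contribution is the term's shrinkage
    factor; the calibration intercept is the shrunken intercept.

    Returns ``(factors, shrunken_intercept)``.
    """
    if not terms:
        raise ConfigurationError("shrinkage needs at least one term")
    n = len(frame)
    if folds > n:
        raise ConfigurationError(f"folds ({folds}) exceeds number of rows ({n})")
    y = frame[outcome].to_numpy(dtype=float)
    x = np.column_stack(
        [_design_column(frame[v].to_numpy(dtype=float), s, p) for v, s, p in terms]
    )

    contributions = np.empty_like(x)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32 - 1))
    for train_idx, test_idx in kf.split(x):
        design = np.column_stack([np.ones(len(train_idx)), x[train_idx]])
        beta, *_ = np.linalg.lstsq(design, y[train_idx], rcond=None)
        contributions[test_idx] = x[test_idx] * beta[1:]

    calib = np.column_stack([np.ones(n), contributions])
    gamma, *_ = np.linalg.lstsq(calib, y, rcond=None)
    factors = {terms[j][0]: float(gamma[j + 1]) for j in range(len(terms))}
    return factors, float(gamma[0])


# -- replicate bookkeeping and aggregation --------------------------------


@dataclass(frozen=True)
class ReplicateFit:
    """One bootstrap replicate's selected model, pre- and post-shrinkage."""

    replicate_index: int
    selected: tuple[str, ...]
    powers: Mapping[str, float]
    raw_coefficients: Mapping[str, float]
    shrinkage_factors: Mapping[str, float]
    shrunken_coefficients: Mapping[str, float]
    pvalues: Mapping[str, float]
    intercept_raw: float
    intercept_shrunken: float

    @property
    def intercept_factor(self) -> float:
        if abs(self.intercept_raw) < 1e-12:
            return 1.0
        return self.intercept_shrunken / self.intercept_raw


@dataclass(frozen=True)
class DevelopmentReport:
    """Aggregated development result."""

    final: ModelSpec
    bif: Mapping[str, float]
    shrinkage_summary: Mapping[str, tuple[float, float]]
    replicates: tuple[ReplicateFit, ...]
    n_failed: int
    config: DevelopmentConfig

    def replicate_frame(self) -> pd.DataFrame:
        """Flat per-replicate log: one row per (replicate, selected variable)."""
        rows = []
        for rep in self.replicates:
            if not rep.selected:
                rows.append(
                    {
                        "replicate": rep.replicate_index,
                        "variable": "(intercept only)",
                        "power": np.nan,
                        "raw_coefficient": np.nan,
                        "shrinkage_factor": np.nan,
                        "shrunken_coefficient": np.nan,
                        "pvalue": np.nan,
                        "intercept_raw": rep.intercept_raw,
                        "intercept_shrunken": rep.intercept_shrunken,
                    }
                )
            for v in rep.selected:
                rows.append(
                    {
                        "replicate": rep.replicate_index,
                        "variable": v,
                        "power": rep.powers[v],
                        "raw_coefficient": rep.raw_coefficients[v],
                        "shrinkage_factor": rep.shrinkage_factors[v],
                        "shrunken_coefficient": rep.shrunken_coefficients[v],
                        "pvalue": rep.pvalues[v],
                        "intercept_raw": rep.intercept_raw,
                        "intercept_shrunken": rep.intercept_shrunken,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "final_model": self.final.to_dict(),
            "bif": {k: float(v) for k, v in self.bif.items()},
            "shrinkage_summary": {
                k: {"mean": float(m), "sd": float(s)} for k, (m, s) in self.shrinkage_summary.items()
            },
            "n_bootstrap": self.config.n_bootstrap,
            "n_failed": self.n_failed,
            "alpha": self.config.alpha,
            "bif_threshold": self.config.bif_threshold,
            "seed": self.config.seed,
            "candidate_variables": list(self.config.candidate_variables),
        }


def _replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    """Splittable, order-independent per-replicate stream."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def _run_replicate(
    frame: pd.DataFrame, config: DevelopmentConfig, index: int
) -> ReplicateFit:
    rng = _replicate_rng(config.seed, index)
    n = len(frame)
    idx = rng.integers(0, n, size=n)
    rep = frame.iloc[idx].reset_index(drop=True)

    needs_imputation = any(
        v in rep.columns and rep[v].isna().any()
        for v in IMPUTABLE
        if v in config.candidate_variables
        or any(r in config.candidate_variables for r in ("prev_ratio", "new_ratio"))
    )
    if needs_imputation:
        rep = impute_random_forest(
            rep, seed=int(rng.integers(2**31)), settings=config.imputation
        )

    y = rep[OUTCOME].to_numpy(dtype=float)
    powers = {
        v: select_fp_power(y, rep[v].to_numpy(dtype=float), config.scale(v), config.fp_powers)
        for v in config.candidate_variables
    }
    powers = refine_fp_powers(rep, config.candidate_variables, powers, config)
    terms = [(v, config.scale(v), powers[v]) for v in config.candidate_variables]

    fit = fit_backwards(rep, terms, alpha=config.alpha)

    if fit.terms:
        factors, intercept_shrunken = parameterwise_shrinkage(
            rep,
            [(t.variable, t.scale_divisor, t.power) for t in fit.terms],
            folds=min(config.shrinkage_folds, len(rep)),
            seed=int(rng.integers(2**31)),
        )
    else:
        factors, intercept_shrunken = {}, fit.intercept

    return ReplicateFit(
        replicate_index=index,
        selected=fit.variables,
        powers={t.variable: t.power for t in fit.terms},
        raw_coefficients={t.variable: t.coefficient for t in fit.terms},
        shrinkage_factors=factors,
        shrunken_coefficients={
            t.variable: t.coefficient * factors[t.variable] for t in fit.terms
        },
        pvalues={t.variable: t.pvalue for t in fit.terms},
        intercept_raw=fit.intercept,
        intercept_shrunken=intercept_shrunken,
    )


def develop_model(frame: pd.DataFrame, config: DevelopmentConfig) -> DevelopmentReport:
    """Run the full bootstrap development procedure on a paired-AST table.

    ``frame`` may be a raw cohort table (derived columns are added) or an
    analysis frame.  Fully deterministic given ``config.seed``; replicate
    random streams are derived by a splittable counter scheme, so results do
    not depend on execution order.
    """
    config.validate()
    work = frame
    if "days_between" not in work.columns or "prev_ratio" not in work.columns:
        work = prepare_analysis_frame(work)
    missing_cols = [v for v in config.candidate_variables + (OUTCOME,) if v not in work.columns]
    if missing_cols:
        raise ConfigurationError(f"table lacks columns: {missing_cols}")
    if len(work) < 10 * len(config.candidate_variables):
        warnings.warn(
            f"only {len(work)} rows for {len(config.candidate_variables)} candidates; "
            "fewer than 10 rows per candidate",
            UserWarning,
            stacklevel=2,
        )

    replicates: list[ReplicateFit] = []
    failures: list[tuple[int, Exception]] = []
    for r in range(config.n_bootstrap):
        try:
            replicates.append(_run_replicate(work, config, r))
        except Exception as exc:  # collected; aborts only past the failure budget
            failures.append((r, exc))
            if len(failures) > max(1, 0.01 * config.n_bootstrap):
                raise DevelopmentError(
                    f"{len(failures)} of {r + 1} replicates failed; first failure at "
                    f"replicate {failures[0][0]}: {failures[0][1]!r}"
                ) from failures[0][1]
    if not replicates:
        raise DevelopmentError("all replicates failed")

    n_ok = len(replicates)
    bif = {
        v: sum(1 for rep in replicates if v in rep.selected and rep.pvalues[v] <= config.alpha)
        / n_ok
        for v in config.candidate_variables
    }
    retained = [v for v in config.candidate_variables if bif[v] >= config.bif_threshold]

    final_terms = []
    shrinkage_summary: dict[str, tuple[float, float]] = {}
    for v in retained:
        chosen = [rep for rep in replicates if v in rep.selected]
        powers = [rep.powers[v] for rep in chosen]
        vals, counts = np.unique(powers, return_counts=True)
        modal_power = float(vals[np.argmax(counts)])
        with_power = [rep for rep in chosen if rep.powers[v] == modal_power]
        coefs = np.array([rep.shrunken_coefficients[v] for rep in with_power])
        factors = np.array([rep.shrinkage_factors[v] for rep in with_power])
        final_terms.append(
            FpTerm(
                variable=v,
                scale_divisor=config.scale(v),
                power=modal_power,
                coefficient=float(coefs.mean()),
                shrinkage_factor=float(factors.mean()),
                standard_error=float(coefs.std(ddof=1)) if len(coefs) > 1 else None,
            )
        )
        shrinkage_summary[v] = (
            float(factors.mean()),
            float(factors.std(ddof=1)) if len(factors) > 1 else 0.0,
        )
    # Intercepts are only commensurable between replicates that used the same
    # transforms: average over the modal-transform family (fall back to all
    # replicates if none match, e.g. bif_threshold below every selection rate).
    modal_powers = {t.variable: t.power for t in final_terms}
    coherent = [
        rep
        for rep in replicates
        if set(retained) <= set(rep.selected)
        and all(rep.powers[v] == modal_powers[v] for v in retained)
    ]
    if not coherent:
        coherent = list(replicates)
    intercepts = np.array([rep.intercept_shrunken for rep in coherent])
    intercept = float(intercepts.mean())

    # Residual SD: RMSE of the aggregated model on the input table (imputing
    # once with a dedicated stream if a final-model variable has gaps).
    eval_frame = work
    if any(eval_frame[t.variable].isna().any() for t in final_terms):
        eval_frame = impute_random_forest(
            eval_frame,
            seed=int(_replicate_rng(config.seed, config.n_bootstrap).integers(2**31)),
            settings=config.imputation,
        )
    if final_terms:
        pred = intercept + sum(
            t.coefficient * _design_column(eval_frame[t.variable].to_numpy(dtype=float), t.scale_divisor, t.power)
            for t in final_terms
        )
    else:
        pred = np.full(len(eval_frame), intercept)
    resid = eval_frame[OUTCOME].to_numpy(dtype=float) - pred
    rmse = float(np.sqrt(np.mean(resid**2)))

    final = ModelSpec(
        name=config.model_name,
        intercept=intercept,
        terms=tuple(final_terms),
        residual_sd=max(rmse, 1e-9),
        pass_threshold=430.0,
    )
    return DevelopmentReport(
        final=final,
        bif=bif,
        shrinkage_summary=shrinkage_summary,
        replicates=tuple(replicates),
        n_failed=len(failures),
        config=config,
    )
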