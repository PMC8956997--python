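"""Covariate-adjusted effectiveness and two-part cost models.

Effectiveness: a gaussian-identity regression of each month-6 score on arm
indicators plus pre-specified confounders (baseline score, age, days since
baseline, ethnicity, employment, household-income band, prenatal-course
attendance, skin-to-skin contact).

Cost: a two-part (hurdle) model for zero-inflated, right-skewed totals —
part 1 is a probit for the probability of incurring any cost, part 2 a
gamma GLM with log link fitted to the positive totals only; the expected
cost per participant is the product P(positive) * E[cost | positive].

"Adjusted" per-arm means are obtained by marginal standardization
(recycled predictions): every participant is assigned to each arm in turn,
the fitted models predict their outcome/cost, and predictions are averaged
over the pooled covariate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .trial_data import DEFAULT_OUTCOMES, OutcomeSpec, TrialDataset

__all__ = [
    "EffectModelSpec",
    "CostModelSpec",
    "EffectFit",
    "TwoPartFit",
    "ArmEstimates",
    "fit_effect_model",
    "fit_two_part_cost",
    "adjusted_arm_means",
    "ModelFitError",
    "DEFAULT_EFFECT_COVARIATES",
    "DEFAULT_COST_COVARIATES",
]

#: The confounders the effectiveness model adjusts for; "baseline" expands
#: to the outcome's own baseline-score column.
DEFAULT_EFFECT_COVARIATES = (
    "baseline",
    "age",
    "days_since_baseline",
    "ethnicity",
    "employment",
    "income_band",
    "prenatal_course",
    "skin_to_skin",
)

#: Determinants of service utilization used in the cost model.
DEFAULT_COST_COVARIATES = ("employment", "income_band")

_CATEGORICAL = ("ethnicity", "income_band")
_BINARY = ("employment", "prenatal_course", "skin_to_skin")


class ModelFitError(RuntimeError):
    """A model could not be fitted (rank deficiency, separation, ...)."""


@dataclass(frozen=True)
class EffectModelSpec:
    outcome: OutcomeSpec
    covariates: tuple = DEFAULT_EFFECT_COVARIATES
    family: str = "gaussian-identity"
    min_cases_per_arm: int = 10

    def __post_init__(self) -> None:
        if self.family != "gaussian-identity":
            raise ValueError(f"unsupported family {self.family!r}")


@dataclass(frozen=True)
class CostModelSpec:
    covariates: tuple = DEFAULT_COST_COVARIATES
    part1_link: str = "probit"
    part2_family: str = "gamma-log"


@dataclass
class DesignInfo:
    """Column layout for a regression design matrix.

    The arm indicator is always included; categorical covariates are
    one-hot with the largest category as reference.
    """

    covariates: tuple
    arm_levels: list          # reference arm first
    cat_levels: dict          # covariate -> levels, reference first
    baseline_col: str | None = None

    @classmethod
    def from_data(cls, df: pd.DataFrame, covariates, baseline_col=None) -> "DesignInfo":
        counts = df["arm"].value_counts()
        arms = list(counts.index)
        if "control" in arms:  # control is the natural reference when present
            arms.remove("control")
            arms = ["control"] + arms
        cat_levels = {}
        for cov in covariates:
            if cov in _CATEGORICAL:
                vc = df[cov].value_counts()
                cat_levels[cov] = list(vc.index)  # largest first = reference
        return cls(tuple(covariates), arms, cat_levels, baseline_col)

    @property
    def column_names(self) -> list:
        names = ["const"] + [f"arm_{a}" for a in self.arm_levels[1:]]
        for cov in self.covariates:
            if cov == "baseline":
                names.append(self.baseline_col)
            elif cov in self.cat_levels:
                names += [f"{cov}_{lev}" for lev in self.cat_levels[cov][1:]]
            else:
                names.append(cov)
        return names

    def matrix(self, df: pd.DataFrame, arm_override: str | None = None) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        arm = (
            pd.Series([arm_override] * n, index=df.index)
            if arm_override is not None
            else df["arm"]
        )
        for a in self.arm_levels[1:]:
            cols.append((arm == a).to_numpy(dtype=float))
        for cov in self.covariates:
            if cov == "baseline":
                cols.append(df[self.baseline_col].to_numpy(dtype=float))
            elif cov in self.cat_levels:
                for lev in self.cat_levels[cov][1:]:
                    cols.append((df[cov] == lev).to_numpy(dtype=float))
            else:
                cols.append(df[cov].to_numpy(dtype=float))
        return np.column_stack(cols)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose removal restores full column rank
        bad = []
        for j in range(X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                bad.append(names[j])
        raise ModelFitError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class EffectFit:
    """Fitted gaussian-identity effectiveness model for one outcome."""

    spec: EffectModelSpec
    design: DesignInfo
    params: np.ndarray
    converged: bool = True

    def predict_mean_for_arm(self, df: pd.DataFrame, arm: str) -> float:
        """Recycled prediction: mean predicted score with everyone in ``arm``."""
        X = self.design.matrix(df, arm_override=arm)
        return float(np.mean(X @ self.params))


def fit_effect_model(ds: TrialDataset, spec: EffectModelSpec) -> EffectFit:
    """Fit the adjusted effectiveness regression for one outcome.

    Gaussian-identity, so the fit is ordinary least squares on the design
    of arm indicators plus confounders.
    """
    df = ds.participants
    sizes = df["arm"].value_counts()
    small = sizes[sizes < spec.min_cases_per_arm]
    if len(small):
        raise ModelFitError(
            f"arms below the {spec.min_cases_per_arm}-case guard: {small.to_dict()}"
        )
    design = DesignInfo.from_data(df, spec.covariates, spec.outcome.baseline_col)
    X = design.matrix(df)
    y = df[spec.outcome.month6_col].to_numpy(dtype=float)
    _check_rank(X, design.column_names)
    params, *_ = np.linalg.lstsq(X, y, rcond=None)
    return EffectFit(spec, design, params)


@dataclass
class TwoPartFit:
    """Fitted two-part (hurdle) cost model.

    ``part1_params`` parameterize a probit for P(total cost > 0) (``None``
    when every total is positive, i.e. P=1); ``part2_params`` a gamma GLM
    with log link fitted on positive-cost records only.  Arms with no
    positive costs are recorded in ``zero_cost_arms`` and predicted an
    expected cost of 0.
    """

    spec: CostModelSpec
    design: DesignInfo
    part1_params: np.ndarray | None
    part2_params: np.ndarray
    n_zero_by_arm: dict
    zero_cost_arms: tuple = ()
    converged: bool = True

    def prob_positive(self, X: np.ndarray) -> np.ndarray:
        if self.part1_params is None:
            return np.ones(X.shape[0])
        return norm.cdf(X @ self.part1_params)

    def mean_positive(self, X: np.ndarray) -> np.ndarray:
        return np.exp(X @ self.part2_params)

    def expected_cost_for_arm(self, df: pd.DataFrame, arm: str) -> float:
        """Recycled prediction of E[cost] with everyone assigned to ``arm``."""
        if arm in self.zero_cost_arms:
            return 0.0
        X = self.design.matrix(df, arm_override=arm)
        return float(np.mean(self.prob_positive(X) * self.mean_positive(X)))


def _fit_probit(y: np.ndarray, X: np.ndarray, names) -> tuple:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit())).fit(
                maxiter=100, tol=1e-8
            )
    except Exception as exc:  # statsmodels raises various separation errors
        raise ModelFitError(
            f"probit part of the two-part model failed ({exc}); "
            "consider reducing the cost-model covariates"
        ) from exc
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise ModelFitError(
            "probit part shows (quasi-)separation; consider reducing the "
            f"cost-model covariates (columns: {names})"
        )
    return np.asarray(res.params), bool(res.converged)


def _fit_gamma_log(y: np.ndarray, X: np.ndarray) -> tuple:
    # Pearson-based dispersion is the statsmodels default for gamma GLMs
    res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit(
        maxiter=100, tol=1e-8
    )
    return np.asarray(res.params), bool(res.converged)


def fit_two_part_cost(ds: TrialDataset, spec: CostModelSpec = CostModelSpec()) -> TwoPartFit:
    """Fit the two-part cost model on the analysis set.

    Part 1 (probit) is fitted on every participant; part 2 (gamma, log
    link) on positive-cost participants only.  Requires at least one
    positive-cost record; an arm containing only zero costs is dropped
    from both parts with a warning and later predicted cost 0.
    """
    df = ds.participants
    pos = df["total_cost"].to_numpy(dtype=float) > 0
    if not pos.any():
        raise ModelFitError("no positive-cost records; cannot fit part 2")

    zero_cost_arms = tuple(
        a for a in ds.arms if not pos[(df["arm"] == a).to_numpy()].any()
    )
    if zero_cost_arms:
        warnings.warn(
            f"arm(s) with no positive costs: {zero_cost_arms}; "
            "their expected cost is 0",
            stacklevel=2,
        )
        keep = ~df["arm"].isin(zero_cost_arms).to_numpy()
        df = df[keep]
        pos = pos[keep]

    design = DesignInfo.from_data(df, spec.covariates)
    X = design.matrix(df)
    names = design.column_names
    _check_rank(X, names)

    if pos.all():
        part1_params, conv1 = None, True  # P(positive) == 1
    else:
        part1_params, conv1 = _fit_probit(pos.astype(float), X, names)

    X2 = X[pos]
    y2 = df.loc[pos, "total_cost"].to_numpy(dtype=float)
    _check_rank(X2, names)
    part2_params, conv2 = _fit_gamma_log(y2, X2)

    n_zero = {
        a: int((~pos[(df["arm"] == a).to_numpy()]).sum()) for a in design.arm_levels
    }
    for a in zero_cost_arms:
        n_zero[a] = int((ds.participants["arm"] == a).sum())
    return TwoPartFit(
        spec, design, part1_params, part2_params, n_zero, zero_cost_arms, conv1 and conv2
    )


@dataclass
class ArmEstimates:
    """Adjusted per-arm summary: effects per outcome and costs (SGD)."""

    arm: str
    adjusted_effect: dict          # outcome name -> adjusted mean score
    adjusted_health_cost: float
    adjusted_total_cost: float     # health cost + per-participant program cost

    def __post_init__(self) -> None:
        if self.adjusted_total_cost < self.adjusted_health_cost - 1e-9:
            raise ValueError("total cost cannot be below health-care cost")


def adjusted_arm_means(
    effect_fits: dict,
    cost_fit: TwoPartFit,
    ds: TrialDataset,
    program_costs: dict | None = None,
) -> list:
    """Marginally standardized per-arm estimates.

    For each arm, every participant's arm assignment is recycled to that
    arm, the fitted models predict score and expected cost, and predictions
    are averaged over the pooled sample.  ``program_costs`` maps arm to the
    per-participant program cost added on top of the adjusted health-care
    cost (missing arms get 0).
    """
    program_costs = program_costs or {}
    df = ds.participants
    out = []
    for arm in ds.arms:
        effects = {
            name: fit.predict_mean_for_arm(df, arm) for name, fit in effect_fits.items()
        }
        health = cost_fit.expected_cost_for_arm(df, arm)
        prog = float(program_costs.get(arm, 0.0))
        out.append(ArmEstimates(arm, effects, health, health + prog))
    return out


def fit_all(
    ds: TrialDataset,
    outcomes=DEFAULT_OUTCOMES,
    effect_covariates=DEFAULT_EFFECT_COVARIATES,
    cost_spec: CostModelSpec = CostModelSpec(),
) -> tuple:
    """Convenience: fit every effectiveness model and the cost model."""
    effect_fits = {
        spec.name: fit_effect_model(ds, EffectModelSpec(spec, tuple(effect_covariates)))
        for spec in outcomes
    }
    cost_fit = fit_two_part_cost(ds, cost_spec)
    return effect_fits, cost_fit
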