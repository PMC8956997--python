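"""Synthetic three-arm trial generator.

Emulates the statistical structure the downstream analysis assumes:

* arm-specific month-6 outcome levels with baseline scores drawn jointly
  (bivariate normal with a configurable within-person correlation, clipped
  to the instrument range);
* zero-inflated, right-skewed health-care costs: a point mass at zero with
  arm-specific probability ``p0`` and a gamma distribution for positive
  totals, calibrated so the zero fraction and the overall mean/SD match the
  published arm summaries;
* a realistic covariate mix (age, ethnicity, employment, household-income
  band, prenatal-course attendance, skin-to-skin contact, days since
  baseline), with optional covariate effects on outcome and cost so that
  confounding-adjustment code paths can be exercised.

Positive totals are split into 1-3 itemized bills that preserve the total
to the cent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import published
from .trial_data import (
    ARMS,
    CONDITION_CLASSES,
    DEFAULT_OUTCOMES,
    PERIODS,
    PROVIDERS,
    OutcomeSpec,
    TrialDataset,
    validate_trial_data,
)

__all__ = [
    "CostMixture",
    "OutcomeModel",
    "CovariateModel",
    "GeneratorConfig",
    "mixture_from_summary",
    "default_config",
    "generate_trial",
]


@dataclass(frozen=True)
class CostMixture:
    """Zero-inflated gamma model of a participant's total health-care cost.

    With probability ``p0`` the total is exactly zero; otherwise it is drawn
    from a gamma with shape ``shape`` and mean ``mean_positive``.
    """

    p0: float
    mean_positive: float
    shape: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0={self.p0} outside [0, 1]")
        if self.p0 < 1.0 and (self.mean_positive <= 0 or self.shape <= 0):
            raise ValueError("mean_positive and shape must be > 0")

    @property
    def sd_positive(self) -> float:
        return self.mean_positive / np.sqrt(self.shape)

    @property
    def overall_mean(self) -> float:
        return (1.0 - self.p0) * self.mean_positive

    @property
    def overall_sd(self) -> float:
        # Var = (1-p0) * (sigma+^2 + p0 * mu+^2)
        v = (1.0 - self.p0) * (self.sd_positive**2 + self.p0 * self.mean_positive**2)
        return float(np.sqrt(v))


def mixture_from_summary(p0: float, mean: float, sd: float, arm: str = "?") -> CostMixture:
    """Solve the gamma mixture so its zero fraction, overall mean and SD match.

    Inverts the mixture moments: ``mu+ = mean / (1-p0)`` and
    ``sigma+^2 = sd^2/(1-p0) - p0*mu+^2``.  Raises if the printed SD is
    unattainable given ``p0`` and the mean (the implied positive-part
    variance would be non-positive).
    """
    if p0 >= 1.0:
        if mean != 0:
            raise ValueError(f"arm {arm}: p0=1 but nonzero mean {mean}")
        return CostMixture(1.0, 1.0, 1.0)
    mu_pos = mean / (1.0 - p0)
    s2_pos = sd**2 / (1.0 - p0) - p0 * mu_pos**2
    if s2_pos <= 0:
        raise ValueError(
            f"arm {arm}: infeasible cost mixture — SD {sd} unattainable with "
            f"p0={p0:.3f} and mean {mean} (implied positive-part variance {s2_pos:.1f})"
        )
    shape = mu_pos**2 / s2_pos
    return CostMixture(p0, mu_pos, shape)


@dataclass(frozen=True)
class OutcomeModel:
    """Per-arm, per-outcome score model: jointly normal baseline and month-6."""

    baseline_mean: float
    baseline_sd: float
    month6_mean: float
    month6_sd: float
    correlation: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must be in (-1, 1)")
        if self.baseline_sd < 0 or self.month6_sd < 0:
            raise ValueError("SDs must be >= 0")

    def true_month6_mean(self, spec: OutcomeSpec) -> float:
        """Population mean of the generated month-6 score, clipping included.

        Clipping a normal draw to the instrument range shifts its mean;
        this closed form (censored-normal mean) is the generator's actual
        truth, used as the oracle in parameter-recovery checks.
        """
        from scipy.stats import norm

        a, b = spec.scale_min, spec.scale_max
        mu, sd = self.month6_mean, self.month6_sd
        if sd == 0:
            return float(min(max(mu, a), b))
        alpha, beta = (a - mu) / sd, (b - mu) / sd
        return float(
            a * norm.cdf(alpha)
            + b * norm.sf(beta)
            + mu * (norm.cdf(beta) - norm.cdf(alpha))
            - sd * (norm.pdf(beta) - norm.pdf(alpha))
        )


@dataclass(frozen=True)
class CovariateModel:
    """Marginal covariate distributions (shared across arms — randomization)."""

    age_mean: float = 30.0
    age_sd: float = 4.0
    ethnicity_probs: dict = field(
        default_factory=lambda: {"chinese": 0.50, "malay": 0.25, "indian": 0.15, "other": 0.10}
    )
    employment_prob: float = 0.85
    income_band_probs: dict = field(
        default_factory=lambda: {"<=5000": 0.25, ">5000": 0.75}
    )
    prenatal_prob: float = 0.5
    skin_to_skin_prob: float = 0.8
    days_since_baseline_range: tuple = (168, 196)

    def __post_init__(self) -> None:
        for name, p in [
            ("employment_prob", self.employment_prob),
            ("prenatal_prob", self.prenatal_prob),
            ("skin_to_skin_prob", self.skin_to_skin_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name, probs in [
            ("ethnicity_probs", self.ethnicity_probs),
            ("income_band_probs", self.income_band_probs),
        ]:
            vals = np.array(list(probs.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic trial.

    ``covariate_model`` is normally a single :class:`CovariateModel` (the
    covariate mix is arm-invariant under randomization); passing a dict
    keyed by arm deliberately imbalances the arms, which together with
    nonzero ``covariate_effects`` creates true confounding for testing the
    adjustment machinery.

    ``covariate_effects`` optionally injects linear effects of covariates on
    every month-6 score (``outcome_shift``) and multiplicative effects on the
    positive-cost mean (``cost_log_shift``, on the log scale), keyed by
    covariate indicator name (e.g. ``"employment"``, ``"income_>5000"``).
    Defaults are zero: arm effects only.
    """

    arm_sizes: dict
    covariate_model: CovariateModel | dict  # shared, or arm -> CovariateModel
    outcome_model: dict          # arm -> outcome name -> OutcomeModel
    cost_model: dict             # arm -> CostMixture
    outcomes: tuple = DEFAULT_OUTCOMES
    covariate_effects: dict = field(
        default_factory=lambda: {"outcome_shift": {}, "cost_log_shift": {}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for arm, n in self.arm_sizes.items():
            if n < 1:
                raise ValueError(f"arm {arm}: size must be >= 1")
        for arm in self.arm_sizes:
            if arm not in self.outcome_model or arm not in self.cost_model:
                raise ValueError(f"arm {arm}: missing outcome or cost model")

    def scaled(self, factor: int) -> "GeneratorConfig":
        """Same data-generating process with every arm size multiplied."""
        sizes = {a: int(n * factor) for a, n in self.arm_sizes.items()}
        return replace(self, arm_sizes=sizes)


# SDs and baseline levels are not reported at arm level; chosen once as
# plausible instrument spreads (see the methods note).
_MONTH6_SD = {"pmpse": 6.0, "picss": 8.0, "epds": 3.5, "hadsa": 2.8}
_BASELINE = {
    "pmpse": (48.0, 6.0),
    "picss": (74.0, 8.0),
    "epds": (7.0, 3.5),
    "hadsa": (6.0, 2.8),
}


def default_config(seed: int = 0) -> GeneratorConfig:
    """Generator calibrated to the published arm summaries.

    Arm sizes 64/63/66; per-arm zero-cost probabilities 28/64, 20/63, 30/66;
    gamma positive-cost parameters solved so the mixture reproduces the
    printed overall cost mean and SD per arm; month-6 outcome means set to
    the adjusted-effectiveness values (raw means are calibrated to the
    adjusted ones — the only per-arm levels reported).
    """
    arm_sizes = dict(published.ARM_SIZES)
    cost_model = {
        arm: mixture_from_summary(
            published.ZERO_COST_COUNTS[arm] / arm_sizes[arm],
            published.HEALTH_COST_MEAN[arm],
            published.HEALTH_COST_SD[arm],
            arm=arm,
        )
        for arm in arm_sizes
    }
    outcome_model = {
        arm: {
            name: OutcomeModel(
                baseline_mean=_BASELINE[name][0],
                baseline_sd=_BASELINE[name][1],
                month6_mean=published.ADJUSTED_EFFECTS[arm][name],
                month6_sd=_MONTH6_SD[name],
                correlation=0.5,
            )
            for name in ("pmpse", "picss", "epds", "hadsa")
        }
        for arm in arm_sizes
    }
    return GeneratorConfig(
        arm_sizes=arm_sizes,
        covariate_model=CovariateModel(),
        outcome_model=outcome_model,
        cost_model=cost_model,
        seed=seed,
    )


def _draw_covariates(rng: np.random.Generator, n: int, cm: CovariateModel) -> pd.DataFrame:
    eth_names = list(cm.ethnicity_probs)
    inc_names = list(cm.income_band_probs)
    days_lo, days_hi = cm.days_since_baseline_range
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(cm.age_mean, cm.age_sd, n), 1),
            "ethnicity": rng.choice(eth_names, n, p=list(cm.ethnicity_probs.values())),
            "employment": rng.random(n) < cm.employment_prob,
            "income_band": rng.choice(inc_names, n, p=list(cm.income_band_probs.values())),
            "prenatal_course": rng.random(n) < cm.prenatal_prob,
            "skin_to_skin": rng.random(n) < cm.skin_to_skin_prob,
            "days_since_baseline": rng.integers(days_lo, days_hi + 1, n),
        }
    )


def _covariate_shift(cov: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear predictor contribution from configured covariate effects."""
    shift = np.zeros(len(cov))
    for key, beta in effects.items():
        if beta == 0:
            continue
        if key in ("age", "days_since_baseline"):
            shift += beta * cov[key].to_numpy(dtype=float)
        elif key in ("employment", "prenatal_course", "skin_to_skin"):
            shift += beta * cov[key].to_numpy(dtype=float)
        elif key.startswith("ethnicity_"):
            shift += beta * (cov["ethnicity"] == key.split("_", 1)[1]).to_numpy(dtype=float)
        elif key.startswith("income_"):
            shift += beta * (cov["income_band"] == key.split("_", 1)[1]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate-effect key {key!r}")
    return shift


def _split_amounts(rng: np.random.Generator, total: float) -> list:
    """Split a positive total into 1-3 bill amounts summing exactly to it."""
    n_items = int(rng.integers(1, 4))
    if n_items == 1:
        return [round(total, 2)]
    w = rng.dirichlet(np.ones(n_items) * 2.0)
    parts = np.round(total * w, 2)
    parts[-1] = round(total - parts[:-1].sum(), 2)
    # rounding can leave a non-positive residual: drop it and re-balance
    parts = [p for p in parts if p > 0]
    if not parts:
        parts = [round(total, 2)]
    diff = round(total - sum(parts), 2)
    if diff:
        parts[-1] = round(parts[-1] + diff, 2)
    return parts


# visit-category sampling weights, loosely following the service-use table
_PROVIDER_WEIGHTS = np.array([0.40, 0.18, 0.16, 0.04, 0.02, 0.02, 0.18])
_CONDITIONS = {
    "infant": ["spit up (milk)", "excessive eye discharge", "infantile eczema", "diaper rash", "others"],
    "maternal": ["insufficient milk supply", "breast engorgement", "mastitis", "prolonged lochia", "others"],
}
_CONDITION_WEIGHTS = {
    "infant": np.array([0.16, 0.04, 0.10, 0.05, 0.65]),
    "maternal": np.array([0.22, 0.19, 0.12, 0.02, 0.45]),
}


def generate_trial(cfg: GeneratorConfig, seed: int | None = None) -> TrialDataset:
    """Draw a synthetic trial dataset; deterministic given ``(cfg, seed)``.

    Scores are clipped to the instrument range after the Gaussian draw.
    Zero-cost participants carry no cost items; positive totals are split
    into 1-3 itemized bills preserving the total to the cent.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    out_shift_cfg = cfg.covariate_effects.get("outcome_shift", {})
    cost_shift_cfg = cfg.covariate_effects.get("cost_log_shift", {})

    part_frames = []
    item_rows = []
    counter = 0
    for arm in sorted(cfg.arm_sizes, key=lambda a: ARMS.index(a) if a in ARMS else 99):
        n = cfg.arm_sizes[arm]
        cm = (
            cfg.covariate_model[arm]
            if isinstance(cfg.covariate_model, dict)
            else cfg.covariate_model
        )
        cov = _draw_covariates(rng, n, cm)
        ids = [f"{arm[0].upper()}{counter + i + 1:05d}" for i in range(n)]
        counter += n
        frame = pd.DataFrame({"id": ids, "arm": arm})
        frame = pd.concat([frame, cov], axis=1)

        out_shift = _covariate_shift(cov, out_shift_cfg)
        for spec in cfg.outcomes:
            om = cfg.outcome_model[arm][spec.name]
            z0, z1 = rng.standard_normal(n), rng.standard_normal(n)
            base = om.baseline_mean + om.baseline_sd * z0
            m6 = (
                om.month6_mean
                + om.month6_sd * (om.correlation * z0 + np.sqrt(1 - om.correlation**2) * z1)
                + out_shift
            )
            frame[spec.baseline_col] = np.clip(base, spec.scale_min, spec.scale_max).round(2)
            frame[spec.month6_col] = np.clip(m6, spec.scale_min, spec.scale_max).round(2)

        mix = cfg.cost_model[arm]
        is_zero = rng.random(n) < mix.p0
        scale = mix.mean_positive / mix.shape
        mult = np.exp(_covariate_shift(cov, cost_shift_cfg))
        totals = np.where(
            is_zero, 0.0, rng.gamma(mix.shape, scale, n) * mult
        )
        totals = np.round(totals, 2)
        # a positive draw rounding to 0.00 would break "zero iff no items"
        totals[(~is_zero) & (totals < 0.01)] = 0.01
        frame["total_cost"] = totals

        for pid, total in zip(ids, totals):
            if total == 0:
                continue
            for amount in _split_amounts(rng, float(total)):
                cclass = "infant" if rng.random() < 0.6 else "maternal"
                item_rows.append(
                    {
                        "id": pid,
                        "period": PERIODS[int(rng.choice(3, p=[0.4, 0.3, 0.3]))],
                        "provider": PROVIDERS[
                            int(rng.choice(len(PROVIDERS), p=_PROVIDER_WEIGHTS))
                        ],
                        "condition_class": cclass,
                        "condition": _CONDITIONS[cclass][
                            int(rng.choice(5, p=_CONDITION_WEIGHTS[cclass]))
                        ],
                        "amount": amount,
                    }
                )
        part_frames.append(frame)

    participants = pd.concat(part_frames, ignore_index=True)
    cost_items = pd.DataFrame(
        item_rows, columns=["id", "period", "provider", "condition_class", "condition", "amount"]
    )
    return validate_trial_data(participants, cost_items, cfg.outcomes)
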