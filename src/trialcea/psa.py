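"""Probabilistic sensitivity analysis by nonparametric bootstrap.

Participants are resampled with replacement *within arm* (preserving the
randomized per-arm sample sizes), the effectiveness and two-part cost
models are refitted on every replicate, and the recycled-prediction
adjusted per-arm (cost, effect) pairs are stored.  The draws feed
cost-effectiveness planes (incremental point clouds with quadrant
fractions) and cost-effectiveness acceptability curves via net monetary
benefit, NMB = lambda * oriented effect - cost.

Replicate seeds are spawned from a single seed sequence, so runs are
deterministic and extending ``n_reps`` leaves earlier replicates unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjusted_models import (
    DEFAULT_COST_COVARIATES,
    DEFAULT_EFFECT_COVARIATES,
    CostModelSpec,
    EffectModelSpec,
    ModelFitError,
    adjusted_arm_means,
    fit_effect_model,
    fit_two_part_cost,
)
from .cea import orient_effect
from .trial_data import TrialDataset

__all__ = [
    "BootstrapConfig",
    "BootstrapDraws",
    "bootstrap_draws",
    "CEPlane",
    "ce_plane",
    "CEAC",
    "ceac",
    "default_wtp_grid",
]


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid, 0-500 SGD per score unit in steps of 5.

    Covers the region where the acceptability curves plateau (around
    SGD 100 per self-efficacy/social-support point and SGD 400 per
    depression/anxiety point).
    """
    return np.arange(0.0, 505.0, 5.0)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``resample=False`` is a test hook: every replicate is the identity
    sample, so all draws equal the base-case estimates.
    """

    n_reps: int = 10_000
    seed: int = 0
    stratify_by_arm: bool = True  # fixed: preserves the randomized design
    refit_covariates: bool = True
    resample: bool = True
    max_failure_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.stratify_by_arm:
            raise ValueError("resampling is stratified by arm by design")


@dataclass
class BootstrapDraws:
    """Replicate x arm adjusted draws.

    ``costs[r, a]`` is the adjusted total cost; ``effects[r, a, k]`` the
    adjusted *oriented* effect for outcome ``k``.  ``flagged`` marks kept
    replicates that contained an all-zero-cost arm.
    """

    arms: list
    outcome_names: list
    costs: np.ndarray
    effects: np.ndarray
    n_failed: int = 0
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_reps(self) -> int:
        return self.costs.shape[0]

    def arm_index(self, arm: str) -> int:
        return self.arms.index(arm)

    def outcome_index(self, name: str) -> int:
        return self.outcome_names.index(name)


def bootstrap_draws(
    ds: TrialDataset,
    program_costs: dict,
    cfg: BootstrapConfig,
    effect_covariates=DEFAULT_EFFECT_COVARIATES,
    cost_spec: CostModelSpec = CostModelSpec(),
) -> BootstrapDraws:
    """Stratified bootstrap with per-replicate model refits.

    Replicates where a model cannot be fitted (rank deficiency or probit
    separation in an unlucky resample) are dropped and counted; a failure
    rate above ``cfg.max_failure_rate`` aborts with diagnostics.
    """
    df = ds.participants.reset_index(drop=True)
    arms = ds.arms
    outcomes = list(ds.outcomes)
    arm_rows = {a: np.flatnonzero((df["arm"] == a).to_numpy()) for a in arms}

    if not cfg.refit_covariates:
        effect_covariates = ()
        cost_spec = CostModelSpec(covariates=())

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    costs = np.full((cfg.n_reps, len(arms)), np.nan)
    effects = np.full((cfg.n_reps, len(arms), len(outcomes)), np.nan)
    flagged = np.zeros(cfg.n_reps, dtype=bool)
    kept = np.zeros(cfg.n_reps, dtype=bool)
    failures: list[str] = []

    for r in range(cfg.n_reps):
        rng = np.random.default_rng(children[r])
        if cfg.resample:
            idx = np.concatenate(
                [rng.choice(rows, size=rows.size, replace=True) for rows in arm_rows.values()]
            )
        else:
            idx = np.arange(len(df))
        rep = df.iloc[idx].reset_index(drop=True)
        ds_rep = TrialDataset.__new__(TrialDataset)  # skip re-validation on resamples
        ds_rep.participants = rep
        ds_rep.cost_items = ds.cost_items
        ds_rep.outcomes = ds.outcomes
        ds_rep.n_excluded = 0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                effect_fits = {
                    spec.name: fit_effect_model(
                        ds_rep, EffectModelSpec(spec, tuple(effect_covariates))
                    )
                    for spec in outcomes
                }
                cost_fit = fit_two_part_cost(ds_rep, cost_spec)
        except ModelFitError as exc:
            failures.append(str(exc))
            continue
        if cost_fit.zero_cost_arms:
            flagged[r] = True
        ests = adjusted_arm_means(effect_fits, cost_fit, ds_rep, program_costs)
        by_arm = {e.arm: e for e in ests}
        for j, a in enumerate(arms):
            costs[r, j] = by_arm[a].adjusted_total_cost
            for k, spec in enumerate(outcomes):
                effects[r, j, k] = orient_effect(by_arm[a].adjusted_effect[spec.name], spec)
        kept[r] = True

    n_failed = int((~kept).sum())
    if cfg.n_reps > 0 and n_failed / cfg.n_reps > cfg.max_failure_rate:
        examples = "\n  ".join(failures[:5])
        raise RuntimeError(
            f"{n_failed}/{cfg.n_reps} bootstrap replicates failed "
            f"(> {cfg.max_failure_rate:.0%} allowed); first failures:\n  {examples}"
        )
    return BootstrapDraws(
        list(arms),
        [o.name for o in outcomes],
        costs[kept],
        effects[kept],
        n_failed,
        flagged[kept],
    )


@dataclass
class CEPlane:
    """Incremental point cloud of comparator vs reference.

    Quadrant convention (documented, closed on the right/upper edges):
    a point is *east* when delta-effect > 0 or exactly 0, *lower* when
    delta-cost < 0.  The four fractions partition the replicates, so they
    sum to 1; identical arms put every point at the origin, which falls in
    the upper-right cell.
    """

    reference: str
    comparator: str
    outcome: str
    delta_effect: np.ndarray
    delta_cost: np.ndarray
    quadrants: dict

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_effect": self.delta_effect, "delta_cost": self.delta_cost}
        )


def ce_plane(
    draws: BootstrapDraws, reference: str, comparator: str, outcome_name: str
) -> CEPlane:
    """Per-replicate (delta effect, delta cost) pairs and quadrant fractions."""
    ir, ic = draws.arm_index(reference), draws.arm_index(comparator)
    k = draws.outcome_index(outcome_name)
    d_eff = draws.effects[:, ic, k] - draws.effects[:, ir, k]
    d_cost = draws.costs[:, ic] - draws.costs[:, ir]
    east = d_eff >= 0
    lower = d_cost < 0
    n = max(len(d_eff), 1)
    quadrants = {
        "more_effective_less_costly": float((east & lower).sum() / n),
        "more_effective_more_costly": float((east & ~lower).sum() / n),
        "less_effective_less_costly": float((~east & lower).sum() / n),
        "less_effective_more_costly": float((~east & ~lower).sum() / n),
    }
    return CEPlane(reference, comparator, outcome_name, d_eff, d_cost, quadrants)


@dataclass
class CEAC:
    """Cost-effectiveness acceptability curves.

    ``probabilities`` is a DataFrame indexed by the willingness-to-pay grid
    with one column per arm: the fraction of replicates in which the arm
    has the maximal net monetary benefit (ties split equally), so each row
    sums to 1.
    """

    outcome: str
    wtp: np.ndarray
    probabilities: pd.DataFrame


def ceac(draws: BootstrapDraws, wtp_grid, outcome_name: str) -> CEAC:
    """Acceptability curves via net monetary benefit on the oriented scale.

    At lambda = 0 the NMB reduces to minus cost, so the curve value is the
    fraction of replicates in which the arm is cheapest.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    k = draws.outcome_index(outcome_name)
    eff = draws.effects[:, :, k]  # reps x arms
    cost = draws.costs
    n_reps = eff.shape[0]
    probs = np.zeros((wtp.size, len(draws.arms)))
    for i, lam in enumerate(wtp):
        nmb = lam * eff - cost
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-12
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = weights.mean(axis=0)
    frame = pd.DataFrame(probs, index=pd.Index(wtp, name="wtp"), columns=draws.arms)
    return CEAC(outcome_name, wtp, frame)
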