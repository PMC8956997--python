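"""Cost-effectiveness arithmetic: ICERs, dominance, deterministic scenarios.

Effects are oriented so that higher is always better before any incremental
comparison: depression and anxiety scores are inverted by mapping a score
``s`` to ``scale_max - s``.  The additive constant cancels in every
incremental effect, so ICERs are invariant to the choice of inversion
constant.

Dominance follows the three-arm convention of the source analysis:
*dominant* means best in both cost and effect among all arms, *dominated*
means worst in both.  Among the remaining arms, ICERs are computed along
the cost-ascending frontier (each arm against the previous non-dominated
one), with strong and extended dominance flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .adjusted_models import ArmEstimates
from .program_costing import ProgramCostSpec, apply_cost_multiplier, per_participant_program_cost
from .trial_data import OutcomeSpec

__all__ = [
    "orient_effect",
    "icer",
    "ICERResult",
    "classify_dominance",
    "DominanceResult",
    "ScenarioSpec",
    "build_scenario_table",
]

#: |delta E| below this is treated as a zero incremental effect.
EFFECT_TIE_TOL = 1e-9


def orient_effect(score: float, outcome: OutcomeSpec) -> float:
    """Map a raw score to the higher-is-better orientation.

    ``higher_better`` outcomes pass through; ``lower_better`` outcomes are
    inverted to ``scale_max - score``.
    """
    if outcome.direction == "higher_better":
        return float(score)
    return float(outcome.scale_max - score)


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    ``delta_effect`` is on the oriented (higher-is-better) scale.  ``icer``
    is delta_cost / delta_effect when the ratio is meaningful, else None.
    ``status`` is one of ``dominant`` (comparator cheaper or equal and more
    effective), ``dominated`` (costlier or equal and less effective),
    ``icer`` (a genuine trade-off) or ``undefined`` (no effect difference).
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str


def icer(
    reference: ArmEstimates, comparator: ArmEstimates, outcome: OutcomeSpec
) -> ICERResult:
    """Incremental cost-effectiveness of ``comparator`` versus ``reference``."""
    d_cost = comparator.adjusted_total_cost - reference.adjusted_total_cost
    d_eff = orient_effect(comparator.adjusted_effect[outcome.name], outcome) - orient_effect(
        reference.adjusted_effect[outcome.name], outcome
    )
    if abs(d_eff) < EFFECT_TIE_TOL:
        status, ratio = "undefined", None
    elif d_eff > 0 and d_cost <= 0:
        status, ratio = "dominant", None
    elif d_eff < 0 and d_cost >= 0:
        status, ratio = "dominated", None
    else:
        status, ratio = "icer", d_cost / d_eff
    return ICERResult(reference.arm, comparator.arm, d_cost, d_eff, ratio, status)


@dataclass
class DominanceResult:
    """Per-arm dominance labels and the cost-ascending ICER chain.

    ``status`` maps arm to ``"dominant"`` / ``"dominated"`` / ``"reference"``
    (cheapest arm in the ICER chain) / an :class:`ICERResult`.
    ``order`` lists arms by ascending adjusted total cost.
    ``pairwise_dominated_by`` records, for every arm, the arms that beat it
    on both cost and effect (extended diagnostics beyond the headline
    labels).  ``cost_ties`` flags ties broken by effect.
    """

    outcome: str
    order: list
    status: dict
    pairwise_dominated_by: dict
    cost_ties: bool = False

    def label(self, arm: str) -> str:
        s = self.status[arm]
        if isinstance(s, ICERResult):
            if s.status == "icer":
                return f"{s.icer:.1f}"
            return s.status.capitalize()
        return {"dominant": "Dominant", "dominated": "Dominated", "reference": "N/A"}[s]


def classify_dominance(arms: list, outcome: OutcomeSpec) -> DominanceResult:
    """Label dominant/dominated arms and build the ICER chain.

    An arm is *dominant* when it is least-cost and best-effect among all
    arms, *dominated* when most-cost and worst-effect.  Ties in cost are
    broken by the better oriented effect and flagged.  The remaining arms
    are walked in ascending cost; each is compared with the previous
    non-dominated arm: a strong-dominance relation (no effect gain at extra
    cost) marks it dominated, otherwise an ICER is recorded.
    """
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    oriented = {
        a.arm: orient_effect(a.adjusted_effect[outcome.name], outcome) for a in arms
    }
    costs = {a.arm: a.adjusted_total_cost for a in arms}
    by_arm = {a.arm: a for a in arms}

    ordered = sorted(arms, key=lambda a: (a.adjusted_total_cost, -oriented[a.arm]))
    order = [a.arm for a in ordered]
    cost_ties = len({round(c, 9) for c in costs.values()}) < len(costs)

    best_eff = max(oriented.values())
    worst_eff = min(oriented.values())
    min_cost = min(costs.values())
    max_cost = max(costs.values())

    status: dict = {}
    pairwise = {
        a: sorted(
            b
            for b in costs
            if b != a and costs[b] <= costs[a] and oriented[b] >= oriented[a]
            and (costs[b] < costs[a] or oriented[b] > oriented[a])
        )
        for a in costs
    }
    for arm in order:
        if costs[arm] == min_cost and oriented[arm] == best_eff:
            status[arm] = "dominant"
        elif costs[arm] == max_cost and oriented[arm] == worst_eff:
            status[arm] = "dominated"

    # ICER chain over arms without a global label, ascending cost
    chain = [a for a in order if a not in status]
    prev = None
    for arm in chain:
        if prev is None:
            status[arm] = "reference"
            prev = arm
            continue
        res = icer(by_arm[prev], by_arm[arm], outcome)
        status[arm] = res
        if res.status != "dominated":
            prev = arm  # dominated arms do not become the new comparator base

    return DominanceResult(outcome.name, order, status, pairwise, cost_ties)


@dataclass(frozen=True)
class ScenarioSpec:
    """A deterministic sensitivity scenario.

    Either an override of the program lifetime (years) or a common program
    cost multiplier; ``label`` names the row block in the report.
    ``component_override`` optionally fixes the per-participant program
    component per arm directly (used when reproducing published scenario
    panels whose components are not derivable from the raw inputs).
    """

    label: str
    lifetime_years: float | None = None
    multiplier: float = 1.0
    component_override: dict | None = None


def scenario_program_costs(
    specs: dict,
    scenario: ScenarioSpec,
    horizon_years: float,
    n_served: dict,
) -> dict:
    """Per-arm per-participant program cost under a scenario."""
    out = {}
    for arm, spec in specs.items():
        if scenario.component_override is not None:
            out[arm] = scenario.multiplier * scenario.component_override.get(arm, 0.0)
            continue
        s = spec
        if scenario.lifetime_years is not None:
            s = s.with_lifetime(scenario.lifetime_years)
            # lifetime overrides invalidate any calibrated base-case component
            s = replace(s, per_participant_override=None)
        s = apply_cost_multiplier(s, scenario.multiplier * spec.multiplier)
        out[arm] = per_participant_program_cost(s, horizon_years, n_served.get(arm))
    return out


def build_scenario_table(
    base_arms: list,
    program_specs: dict,
    scenarios: list,
    outcomes,
    horizon_years: float = 0.5,
    n_served: dict | None = None,
) -> pd.DataFrame:
    """Deterministic scenario report (one row per arm per scenario).

    ``base_arms`` carry the scenario-invariant adjusted health-care costs
    and adjusted effects; each scenario only moves the program component of
    the total cost, after which dominance and ICERs are re-derived per
    outcome.  Rows are sorted by total cost within each scenario.
    """
    n_served = n_served or {}
    rows = []
    for scen in scenarios:
        prog = scenario_program_costs(program_specs, scen, horizon_years, n_served)
        arms = [
            ArmEstimates(
                a.arm,
                a.adjusted_effect,
                a.adjusted_health_cost,
                a.adjusted_health_cost + prog.get(a.arm, 0.0),
            )
            for a in base_arms
        ]
        doms = {o.name: classify_dominance(arms, o) for o in outcomes}
        order = doms[outcomes[0].name].order
        for arm in order:
            est = next(a for a in arms if a.arm == arm)
            row = {
                "scenario": scen.label,
                "arm": arm,
                "adjusted_cost": round(est.adjusted_total_cost, 2),
            }
            for o in outcomes:
                row[f"{o.name}_effect"] = est.adjusted_effect[o.name]
                row[f"{o.name}_icer"] = doms[o.name].label(arm)
            rows.append(row)
    return pd.DataFrame(rows)
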