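"""Five-year national budget-impact projection.

Scales the per-mother cost structure of each program to an annual national
cohort of first-time mothers at several coverage levels, accumulating
program and health-care costs over the horizon with no discounting:

* cumulative program cost at year t = upfront + t * recurring
  + t * coverage * cohort * per-mother delivery cost;
* cumulative health-care cost at year t = t * coverage * cohort
  * per-mother health-care cost (the unadjusted arm mean);
* total = program + health care.

The upfront amounts enter undepreciated (annuitization applies only to the
per-participant average-cost derivation in the trial analysis).  The web
program cost is coverage-independent (no marginal delivery cost); the home
program cost is coverage-proportional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import published

__all__ = ["ArmProjection", "ProjectionSpec", "ProjectionTable", "project", "reduced_cost"]


@dataclass(frozen=True)
class ArmProjection:
    """Per-arm cost inputs to the projection (all SGD)."""

    upfront: float = 0.0
    recurring_annual: float = 0.0
    per_mother_delivery: float = 0.0
    per_mother_health_cost: float = 0.0


@dataclass(frozen=True)
class ProjectionSpec:
    """Projection settings; defaults reproduce the published table."""

    annual_cohort: int = published.ANNUAL_COHORT
    coverage_levels: tuple = published.COVERAGE_LEVELS
    years: int = published.PROJECTION_YEARS
    arms: dict = field(default_factory=dict)  # arm -> ArmProjection

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for c in self.coverage_levels:
            if not 0.0 < c <= 1.0:
                raise ValueError(f"coverage {c} outside (0, 1]")
        ctrl = self.arms.get("control")
        if ctrl is not None and (
            ctrl.upfront or ctrl.recurring_annual or ctrl.per_mother_delivery
        ):
            raise ValueError("control arm must have zero program components")


def default_projection_spec() -> ProjectionSpec:
    """Published projection inputs: 20,000 mothers/yr at 10/50/100% coverage.

    The home upfront training fee is carried at its rounded value of 233,
    matching the published table's arithmetic; per-mother health-care costs
    are the unadjusted arm means.
    """
    return ProjectionSpec(
        arms={
            "web": ArmProjection(
                upfront=published.WEB_UPFRONT,
                recurring_annual=published.WEB_RECURRING_ANNUAL,
                per_mother_delivery=0.0,
                per_mother_health_cost=published.HEALTH_COST_MEAN["web"],
            ),
            "home": ArmProjection(
                upfront=round(published.HOME_UPFRONT),  # 233.40 -> 233
                recurring_annual=0.0,
                per_mother_delivery=published.HOME_VISIT_COST,
                per_mother_health_cost=published.HEALTH_COST_MEAN["home"],
            ),
            "control": ArmProjection(
                per_mother_health_cost=published.HEALTH_COST_MEAN["control"]
            ),
        }
    )


@dataclass
class ProjectionTable:
    """Cumulative cost table: arm x cost type x coverage x year, plus upfront."""

    table: pd.DataFrame

    def cell(self, arm: str, cost_type: str, coverage: float, year: int) -> float:
        t = self.table
        row = t[
            (t["arm"] == arm)
            & (t["cost_type"] == cost_type)
            & (t["coverage"] == coverage)
        ]
        if row.empty:
            raise KeyError((arm, cost_type, coverage))
        return float(row.iloc[0][f"year_{year}"])

    def total(self, arm: str, coverage: float, year: int) -> float:
        return self.cell(arm, "total", coverage, year)


def project(spec: ProjectionSpec) -> ProjectionTable:
    """Compute the cumulative projection table (cells rounded to whole SGD)."""
    rows = []
    for arm, ap in spec.arms.items():
        for coverage in spec.coverage_levels:
            mothers_per_year = coverage * spec.annual_cohort
            program = {
                t: ap.upfront
                + t * ap.recurring_annual
                + t * mothers_per_year * ap.per_mother_delivery
                for t in range(1, spec.years + 1)
            }
            health = {
                t: t * mothers_per_year * ap.per_mother_health_cost
                for t in range(1, spec.years + 1)
            }
            for cost_type, series, upfront in (
                ("program", program, ap.upfront),
                ("health_care", health, 0.0),
                ("total", {t: program[t] + health[t] for t in program}, ap.upfront),
            ):
                row = {
                    "arm": arm,
                    "cost_type": cost_type,
                    "coverage": coverage,
                    "upfront": round(upfront),
                }
                row.update({f"year_{t}": round(series[t]) for t in series})
                rows.append(row)
    return ProjectionTable(pd.DataFrame(rows))


def reduced_cost(
    table: ProjectionTable, arm_a: str, arm_b: str, coverage: float, year: int
) -> float:
    """Cumulative total-cost saving of ``arm_a`` relative to ``arm_b``.

    Positive when ``arm_a`` is cheaper: total(arm_b) - total(arm_a).
    """
    return table.total(arm_b, coverage, year) - table.total(arm_a, coverage, year)
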