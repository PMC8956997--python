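"""Participant-level trial data model, file I/O and descriptive cost summaries.

The analysis set is a three-arm randomized trial of postnatal-care programs
(web-based psychoeducation, home-based psychoeducation, routine care) with
four instrument scores measured at baseline and six months, and per-period
health-service cost records collected as full bills.

Data live in two delimiter-separated tables:

* ``participants.csv`` (wide) — one row per mother: arm, covariates,
  baseline and month-6 scores, total six-month health-care cost.
* ``cost_items.csv`` (long) — one row per health-service bill, keyed by
  participant id: period, provider, condition class, condition, amount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeSpec",
    "DEFAULT_OUTCOMES",
    "ARMS",
    "PROVIDERS",
    "CONDITION_CLASSES",
    "PERIODS",
    "TrialDataset",
    "SchemaError",
    "TrialValidationError",
    "load_trial_data",
    "save_trial_data",
    "summarize_costs",
    "CostSummary",
]

#: Study arms, in the order they are reported.
ARMS = ("web", "home", "control")

#: Closed provider category list for cost records.
PROVIDERS = (
    "general practitioner/private clinic",
    "hospital outpatient",
    "accident & emergency",
    "inpatient",
    "polyclinic",
    "over-the-counter",
    "other",
)

CONDITION_CLASSES = ("infant", "maternal")

#: Follow-up periods over the six-month horizon.
PERIODS = ("0-1 mo", "1-3 mo", "3-6 mo")


@dataclass(frozen=True)
class OutcomeSpec:
    """An outcome instrument: score range and whether higher scores are better.

    Parameters
    ----------
    name : str
        Short instrument key, used as a column-name stem
        (``{name}_baseline`` / ``{name}_month6``).
    scale_min, scale_max : float
        Attainable total-score range of the instrument.
    direction : {"higher_better", "lower_better"}
        Clinical orientation of the raw score.
    """

    name: str
    scale_min: float
    scale_max: float
    direction: str

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError(f"{self.name}: scale_min must be < scale_max")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")

    @property
    def baseline_col(self) -> str:
        return f"{self.name}_baseline"

    @property
    def month6_col(self) -> str:
        return f"{self.name}_month6"

    def in_range(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.scale_min) & (x <= self.scale_max)


#: The four built-in instruments: maternal parental self-efficacy (PMPSE),
#: perinatal infant-care social support (PICSS), postnatal depression (EPDS)
#: and anxiety (HADS-A).
DEFAULT_OUTCOMES = (
    OutcomeSpec("pmpse", 17, 68, "higher_better"),
    OutcomeSpec("picss", 22, 88, "higher_better"),
    OutcomeSpec("epds", 0, 30, "lower_better"),
    OutcomeSpec("hadsa", 0, 21, "lower_better"),
)

#: Covariate columns every participant table must carry.
COVARIATE_COLUMNS = (
    "age",
    "ethnicity",
    "employment",
    "income_band",
    "prenatal_course",
    "skin_to_skin",
    "days_since_baseline",
)

_PARTICIPANT_BASE_COLUMNS = ("id", "arm") + COVARIATE_COLUMNS + ("total_cost",)
_COST_ITEM_COLUMNS = ("id", "period", "provider", "condition_class", "condition", "amount")


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class TrialValidationError(ValueError):
    """One or more rows violate dataset invariants.

    The ``problems`` attribute lists one human-readable diagnostic per
    offending row, each naming the participant id and field.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... ({len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} validation problem(s):\n  {preview}{more}")


@dataclass
class TrialDataset:
    """Validated participant-level trial data.

    Attributes
    ----------
    participants : pandas.DataFrame
        Wide table, one row per participant in the analysis set.
    cost_items : pandas.DataFrame
        Long table of individual health-service bills.
    outcomes : tuple of OutcomeSpec
        Instruments present in the participant table.
    n_excluded : int
        Participants dropped for missing month-6 scores (complete-case rule).
    """

    participants: pd.DataFrame
    cost_items: pd.DataFrame
    outcomes: tuple = DEFAULT_OUTCOMES
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.participants = self.participants.reset_index(drop=True)
        self.cost_items = self.cost_items.reset_index(drop=True)

    @property
    def arms(self) -> list:
        """Arms present, in canonical order first, then any extras."""
        present = set(self.participants["arm"])
        ordered = [a for a in ARMS if a in present]
        return ordered + sorted(present - set(ARMS))

    def arm_sizes(self) -> dict:
        return self.participants["arm"].value_counts().to_dict()

    def subset(self, ids: Iterable) -> "TrialDataset":
        ids = list(ids)
        part = self.participants[self.participants["id"].isin(ids)]
        items = self.cost_items[self.cost_items["id"].isin(ids)]
        return TrialDataset(part.copy(), items.copy(), self.outcomes)

    def equals(self, other: "TrialDataset") -> bool:
        """Field-by-field equality of the two tables (row order sensitive)."""
        try:
            pd.testing.assert_frame_equal(
                self.participants, other.participants, check_dtype=False
            )
            pd.testing.assert_frame_equal(
                self.cost_items, other.cost_items, check_dtype=False
            )
        except AssertionError:
            return False
        return self.outcomes == other.outcomes


def _required_participant_columns(outcomes) -> list:
    cols = list(_PARTICIPANT_BASE_COLUMNS)
    for spec in outcomes:
        cols += [spec.baseline_col, spec.month6_col]
    return cols


def validate_trial_data(
    participants: pd.DataFrame,
    cost_items: pd.DataFrame,
    outcomes=DEFAULT_OUTCOMES,
) -> TrialDataset:
    """Check invariants and assemble a :class:`TrialDataset`.

    Participants with any missing month-6 score are excluded (complete-case
    analysis set); their count is recorded on the returned dataset and
    reported with a warning.  Hard invariant violations (scores out of
    instrument range, negative costs, totals that do not match the itemized
    bills, duplicate ids) raise :class:`TrialValidationError` with row-level
    diagnostics.
    """
    required = _required_participant_columns(outcomes)
    missing = [c for c in required if c not in participants.columns]
    if missing:
        raise SchemaError(f"participants table is missing column(s): {missing}")
    missing_items = [c for c in _COST_ITEM_COLUMNS if c not in cost_items.columns]
    if missing_items:
        raise SchemaError(f"cost_items table is missing column(s): {missing_items}")

    participants = participants.copy()
    cost_items = cost_items.copy()

    # complete-case rule: drop rows missing any month-6 score
    m6_cols = [spec.month6_col for spec in outcomes]
    incomplete = participants[m6_cols].isna().any(axis=1)
    n_excluded = int(incomplete.sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} participant(s) with missing month-6 scores "
            "(complete-case analysis set)",
            stacklevel=2,
        )
        excluded_ids = set(participants.loc[incomplete, "id"])
        participants = participants[~incomplete]
        cost_items = cost_items[~cost_items["id"].isin(excluded_ids)]

    problems: list[str] = []
    if participants["id"].duplicated().any():
        dups = participants.loc[participants["id"].duplicated(), "id"].tolist()
        problems.append(f"duplicate participant id(s): {dups}")
    if participants["arm"].nunique() < 2:
        problems.append("dataset must contain at least 2 distinct arms")

    for spec in outcomes:
        for col in (spec.baseline_col, spec.month6_col):
            vals = participants[col]
            bad = participants.loc[vals.notna() & ~spec.in_range(vals.fillna(spec.scale_min))]
            for _, row in bad.iterrows():
                problems.append(
                    f"id {row['id']}: {col}={row[col]} outside {spec.name.upper()} "
                    f"range {spec.scale_min:g}-{spec.scale_max:g}"
                )

    neg = participants[participants["total_cost"] < 0]
    for _, row in neg.iterrows():
        problems.append(f"id {row['id']}: total_cost {row['total_cost']} < 0")

    bad_amount = cost_items[cost_items["amount"] <= 0]
    for _, row in bad_amount.iterrows():
        problems.append(f"id {row['id']}: cost item amount {row['amount']} must be > 0")
    bad_provider = cost_items[~cost_items["provider"].isin(PROVIDERS)]
    for _, row in bad_provider.iterrows():
        problems.append(f"id {row['id']}: unknown provider {row['provider']!r}")
    bad_class = cost_items[~cost_items["condition_class"].isin(CONDITION_CLASSES)]
    for _, row in bad_class.iterrows():
        problems.append(f"id {row['id']}: unknown condition_class {row['condition_class']!r}")
    bad_period = cost_items[~cost_items["period"].isin(PERIODS)]
    for _, row in bad_period.iterrows():
        problems.append(f"id {row['id']}: unknown period {row['period']!r}")

    # totals must equal itemized sums, to the cent; zero total iff no items
    item_sums = cost_items.groupby("id")["amount"].sum()
    for _, row in participants.iterrows():
        s = float(item_sums.get(row["id"], 0.0))
        if abs(s - float(row["total_cost"])) > 0.005:
            problems.append(
                f"id {row['id']}: total_cost {row['total_cost']:.2f} != "
                f"sum of cost items {s:.2f}"
            )

    if problems:
        raise TrialValidationError(problems)

    return TrialDataset(participants, cost_items, tuple(outcomes), n_excluded)


def load_trial_data(path, outcomes=DEFAULT_OUTCOMES) -> TrialDataset:
    """Read ``participants.csv`` + ``cost_items.csv`` from a directory and validate.

    ``path`` may be the directory or the participants file itself (the cost
    items file is then looked up next to it).
    """
    path = Path(path)
    if path.is_dir():
        part_path = path / "participants.csv"
        items_path = path / "cost_items.csv"
    else:
        part_path = path
        items_path = path.with_name("cost_items.csv")
    if not part_path.exists():
        raise FileNotFoundError(part_path)
    if not items_path.exists():
        raise FileNotFoundError(items_path)
    participants = pd.read_csv(part_path)
    cost_items = pd.read_csv(items_path)
    return validate_trial_data(participants, cost_items, outcomes)


def save_trial_data(ds: TrialDataset, out_dir) -> dict:
    """Write the dataset as the canonical CSV pair; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    part_path = out_dir / "participants.csv"
    items_path = out_dir / "cost_items.csv"
    ds.participants.to_csv(part_path, index=False, float_format="%.6g")
    ds.cost_items.to_csv(items_path, index=False, float_format="%.2f")
    return {"participants": part_path, "cost_items": items_path}


@dataclass
class CostSummary:
    """Descriptive service-use summary (one row per arm / per category)."""

    totals: pd.DataFrame      # per arm: n, n_zero, zero_fraction, mean, sd
    providers: pd.DataFrame   # per arm x provider: visits, mean, sd of bills
    conditions: pd.DataFrame  # per arm x condition_class x condition


def _mean_sd(x: np.ndarray) -> tuple:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (np.nan, np.nan)
    if x.size == 1:
        return (float(x[0]), 0.0)
    return (float(np.mean(x)), float(np.std(x, ddof=1)))


def summarize_costs(ds: TrialDataset) -> CostSummary:
    """Per-arm cost descriptives in the shape of the service-use table.

    Total-cost mean/SD are over *all* participants of the arm (zeros
    included); per-provider and per-condition means are per visit, over the
    visits in that category only.  Arms with no participants are omitted
    with a warning.
    """
    if len(ds.participants) == 0:
        raise ValueError("empty dataset")

    totals_rows = []
    for arm in ds.arms:
        sub = ds.participants[ds.participants["arm"] == arm]
        if len(sub) == 0:
            warnings.warn(f"arm {arm!r} has no participants; omitted", stacklevel=2)
            continue
        costs = sub["total_cost"].to_numpy(dtype=float)
        mean, sd = _mean_sd(costs)
        totals_rows.append(
            {
                "arm": arm,
                "n": len(sub),
                "n_zero": int((costs == 0).sum()),
                "zero_fraction": float((costs == 0).mean()),
                "mean": mean,
                "sd": sd,
            }
        )
    totals = pd.DataFrame(totals_rows)

    items = ds.cost_items.merge(
        ds.participants[["id", "arm"]], on="id", how="left", validate="many_to_one"
    )

    def _category_table(group_cols) -> pd.DataFrame:
        rows = []
        for key, grp in items.groupby(group_cols, sort=False):
            if not isinstance(key, tuple):
                key = (key,)
            mean, sd = _mean_sd(grp["amount"].to_numpy())
            rows.append(dict(zip(group_cols, key), visits=len(grp), mean=mean, sd=sd))
        return pd.DataFrame(rows)

    providers = _category_table(["arm", "provider"])
    conditions = _category_table(["arm", "condition_class", "condition"])
    return CostSummary(totals, providers, conditions)
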