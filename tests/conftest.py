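import numpy as np
import pandas as pd
import pytest

from trialcea import default_config, generate_trial
from trialcea import published as pub
from trialcea.adjusted_models import ArmEstimates
from trialcea.trial_data import DEFAULT_OUTCOMES, TrialDataset, validate_trial_data


def make_participants(rows):
    """Build a participants frame from (id, arm, total_cost) triples with
    neutral covariates and mid-scale outcome scores."""
    base = {
        "age": 30.0,
        "ethnicity": "chinese",
        "employment": True,
        "income_band": ">5000",
        "prenatal_course": False,
        "skin_to_skin": True,
        "days_since_baseline": 182,
    }
    scores = {}
    for spec in DEFAULT_OUTCOMES:
        mid = (spec.scale_min + spec.scale_max) / 2
        scores[spec.baseline_col] = mid
        scores[spec.month6_col] = mid
    recs = [
        {"id": pid, "arm": arm, "total_cost": cost, **base, **scores}
        for pid, arm, cost in rows
    ]
    return pd.DataFrame(recs)


def make_cost_items(participants):
    """One bill per positive-cost participant, matching the total."""
    rows = [
        {
            "id": r["id"],
            "period": "0-1 mo",
            "provider": "hospital outpatient",
            "condition_class": "maternal",
            "condition": "others",
            "amount": r["total_cost"],
        }
        for _, r in participants.iterrows()
        if r["total_cost"] > 0
    ]
    return pd.DataFrame(
        rows, columns=["id", "period", "provider", "condition_class", "condition", "amount"]
    )


def make_dataset(rows) -> TrialDataset:
    part = make_participants(rows)
    return validate_trial_data(part, make_cost_items(part))


@pytest.fixture
def tiny_ds() -> TrialDataset:
    """Two arms of four: costs {0,0,100,300} (web) and {50,150,0,200} (control)."""
    return make_dataset(
        [
            ("w1", "web", 0.0),
            ("w2", "web", 0.0),
            ("w3", "web", 100.0),
            ("w4", "web", 300.0),
            ("c1", "control", 50.0),
            ("c2", "control", 150.0),
            ("c3", "control", 0.0),
            ("c4", "control", 200.0),
        ]
    )


@pytest.fixture(scope="session")
def synth_ds() -> TrialDataset:
    """Default calibrated synthetic trial at the published arm sizes."""
    return generate_trial(default_config(seed=11), seed=11)


@pytest.fixture(scope="session")
def big_ds() -> TrialDataset:
    """~50,000 per arm for recovery/calibration checks (shared across tests)."""
    cfg = default_config(seed=3).scaled(780)
    return generate_trial(cfg, seed=3)


@pytest.fixture
def published_arms() -> list:
    """ArmEstimates carrying the published adjusted costs and effects."""
    return [
        ArmEstimates(
            arm,
            dict(pub.ADJUSTED_EFFECTS[arm]),
            pub.ADJUSTED_HEALTH_COST[arm],
            pub.ADJUSTED_TOTAL_COST[arm],
        )
        for arm in ("web", "control", "home")
    ]
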