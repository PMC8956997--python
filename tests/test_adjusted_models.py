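import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from trialcea.adjusted_models import (
    CostModelSpec,
    EffectModelSpec,
    ModelFitError,
    adjusted_arm_means,
    fit_all,
    fit_effect_model,
    fit_two_part_cost,
)
from trialcea.synthetic_trial import CovariateModel, default_config, generate_trial
from trialcea.trial_data import DEFAULT_OUTCOMES, TrialDataset

from conftest import make_dataset

PMPSE = DEFAULT_OUTCOMES[0]


def test_intercept_per_arm_two_part_reproduces_arm_means(tiny_ds):
    """With arm indicators only, P(zero), E[cost|>0] and the expected cost
    are the closed-form arm sample statistics."""
    fit = fit_two_part_cost(tiny_ds, CostModelSpec(covariates=()))
    X_web = fit.design.matrix(tiny_ds.participants, arm_override="web")
    assert fit.prob_positive(X_web)[0] == pytest.approx(0.5, abs=1e-6)
    assert fit.mean_positive(X_web)[0] == pytest.approx(200.0, rel=1e-6)
    assert fit.expected_cost_for_arm(tiny_ds.participants, "web") == pytest.approx(
        100.0, rel=1e-6
    )
    assert fit.expected_cost_for_arm(tiny_ds.participants, "control") == pytest.approx(
        100.0, rel=1e-6  # control arm mean of {50,150,0,200}
    )
    assert fit.n_zero_by_arm == {"control": 1, "web": 2}


def test_two_part_with_covariates_recovers_saturated_means(synth_ds):
    """Adjusted expected costs stay near arm means when covariates carry no
    signal (they are independent of cost in the generator)."""
    fit = fit_two_part_cost(synth_ds)
    raw = synth_ds.participants.groupby("arm")["total_cost"].mean()
    for arm in synth_ds.arms:
        adj = fit.expected_cost_for_arm(synth_ds.participants, arm)
        assert adj == pytest.approx(raw[arm], rel=0.15)
        assert adj > 0


def test_all_positive_costs_skips_hurdle():
    ds = make_dataset(
        [("a", "web", 100.0), ("b", "web", 300.0), ("c", "control", 150.0), ("d", "control", 50.0)]
    )
    fit = fit_two_part_cost(ds, CostModelSpec(covariates=()))
    assert fit.part1_params is None
    X = fit.design.matrix(ds.participants, arm_override="web")
    assert fit.prob_positive(X).max() == 1.0
    assert fit.expected_cost_for_arm(ds.participants, "web") == pytest.approx(200.0, rel=1e-6)


def test_no_positive_costs_anywhere_is_error():
    ds = make_dataset([("a", "web", 0.0), ("b", "control", 0.0)])
    with pytest.raises(ModelFitError, match="no positive-cost"):
        fit_two_part_cost(ds, CostModelSpec(covariates=()))


def test_arm_without_positive_costs_predicted_zero():
    ds = make_dataset(
        [("a", "web", 0.0), ("b", "web", 0.0),
         ("c", "control", 100.0), ("d", "control", 50.0), ("e", "control", 0.0)]
    )
    with pytest.warns(UserWarning, match="no positive costs"):
        fit = fit_two_part_cost(ds, CostModelSpec(covariates=()))
    assert fit.zero_cost_arms == ("web",)
    assert fit.expected_cost_for_arm(ds.participants, "web") == 0.0


def test_empty_covariate_list_gives_raw_arm_means(synth_ds):
    """Intercept+arm effect model: recycled means equal raw arm means exactly."""
    fits = {
        "pmpse": fit_effect_model(synth_ds, EffectModelSpec(PMPSE, covariates=()))
    }
    cost_fit = fit_two_part_cost(synth_ds, CostModelSpec(covariates=()))
    ests = adjusted_arm_means(fits, cost_fit, synth_ds)
    raw_scores = synth_ds.participants.groupby("arm")["pmpse_month6"].mean()
    raw_costs = synth_ds.participants.groupby("arm")["total_cost"].mean()
    for est in ests:
        assert est.adjusted_effect["pmpse"] == pytest.approx(raw_scores[est.arm], abs=1e-8)
        assert est.adjusted_health_cost == pytest.approx(raw_costs[est.arm], rel=1e-5)


def test_constant_outcome_gives_zero_contrasts(synth_ds):
    ds = TrialDataset(
        synth_ds.participants.assign(pmpse_month6=50.0),
        synth_ds.cost_items,
        synth_ds.outcomes,
    )
    fit = fit_effect_model(ds, EffectModelSpec(PMPSE))
    means = {a: fit.predict_mean_for_arm(ds.participants, a) for a in ds.arms}
    vals = list(means.values())
    assert vals[0] == pytest.approx(vals[1], abs=1e-8)
    assert vals[0] == pytest.approx(vals[2], abs=1e-8)
    assert vals[0] == pytest.approx(50.0, abs=1e-8)


def test_program_cost_additivity(synth_ds):
    fits, cost_fit = fit_all(synth_ds)
    without = adjusted_arm_means(fits, cost_fit, synth_ds, None)
    with_prog = adjusted_arm_means(fits, cost_fit, synth_ds, {"web": 10.0})
    for a, b in zip(without, with_prog):
        expected = a.adjusted_total_cost + (10.0 if a.arm == "web" else 0.0)
        assert b.adjusted_total_cost == pytest.approx(expected, abs=1e-9)
        assert b.adjusted_health_cost == pytest.approx(a.adjusted_health_cost)


def test_permutation_invariance(synth_ds):
    shuffled = TrialDataset(
        synth_ds.participants.sample(frac=1.0, random_state=0),
        synth_ds.cost_items,
        synth_ds.outcomes,
    )
    f1, c1 = fit_all(synth_ds)
    f2, c2 = fit_all(shuffled)
    e1 = adjusted_arm_means(f1, c1, synth_ds)
    e2 = adjusted_arm_means(f2, c2, shuffled)
    for a, b in zip(e1, e2):
        assert a.arm == b.arm
        assert a.adjusted_health_cost == pytest.approx(b.adjusted_health_cost, rel=1e-6)
        for k in a.adjusted_effect:
            assert a.adjusted_effect[k] == pytest.approx(b.adjusted_effect[k], abs=1e-6)


def test_rank_deficiency_names_collinear_columns(synth_ds):
    df = synth_ds.participants.copy()
    df["age"] = 30.0  # constant column collides with the intercept
    ds = TrialDataset(df, synth_ds.cost_items, synth_ds.outcomes)
    with pytest.raises(ModelFitError, match="collinear.*age"):
        fit_effect_model(ds, EffectModelSpec(PMPSE, covariates=("age",)))


def test_min_cases_guard():
    ds = make_dataset([("a", "web", 10.0), ("b", "control", 0.0), ("c", "control", 5.0)])
    with pytest.raises(ModelFitError, match="guard"):
        fit_effect_model(ds, EffectModelSpec(PMPSE, covariates=()))


def test_adjustment_reduces_confounding_bias():
    """With employment imbalanced across arms and shifting both outcome and
    cost, the recycled-prediction contrast is closer to the generator truth
    than the raw contrast."""
    cfg = default_config(seed=0).scaled(30)
    cm = {
        "web": CovariateModel(employment_prob=0.95),
        "home": CovariateModel(employment_prob=0.5),
        "control": CovariateModel(employment_prob=0.30),
    }
    effects = {"outcome_shift": {"employment": 4.0}, "cost_log_shift": {"employment": 0.8}}
    cfg = dataclasses.replace(cfg, covariate_model=cm, covariate_effects=effects)
    ds = generate_trial(cfg, seed=21)

    true_contrast = cfg.outcome_model["web"]["pmpse"].true_month6_mean(
        PMPSE
    ) - cfg.outcome_model["control"]["pmpse"].true_month6_mean(PMPSE)
    # true contrast ignores the covariate shift difference: the adjustment
    # should remove the (0.95-0.30)*4 employment-driven gap
    raw = ds.participants.groupby("arm")["pmpse_month6"].mean()
    raw_contrast = raw["web"] - raw["control"]

    fits = {"pmpse": fit_effect_model(ds, EffectModelSpec(PMPSE))}
    cost_fit = fit_two_part_cost(ds)
    ests = {e.arm: e for e in adjusted_arm_means(fits, cost_fit, ds)}
    adj_contrast = ests["web"].adjusted_effect["pmpse"] - ests["control"].adjusted_effect["pmpse"]

    # raw gap carries the (0.95-0.30)*4 = 2.6-point employment imbalance;
    # adjustment should remove most of it (clipping leaves a small residual)
    assert abs(adj_contrast - true_contrast) < abs(raw_contrast - true_contrast)
    assert abs(adj_contrast - true_contrast) < 1.0
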