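import numpy as np
import pandas as pd
import pytest

from trialcea.adjusted_models import adjusted_arm_means, fit_all
from trialcea.psa import (
    BootstrapConfig,
    BootstrapDraws,
    bootstrap_draws,
    ce_plane,
    ceac,
    default_wtp_grid,
)

PROG = {"web": 50.915, "home": 77.797, "control": 0.0}


@pytest.fixture(scope="module")
def small_draws(synth_ds):
    cfg = BootstrapConfig(n_reps=80, seed=7)
    return bootstrap_draws(synth_ds, PROG, cfg)


def hand_draws(costs, effects, arms=("a", "b"), outcome="pmpse"):
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)[:, :, None]
    return BootstrapDraws(list(arms), [outcome], costs, effects)


def test_identity_resample_reproduces_base_case(synth_ds):
    fits, cost_fit = fit_all(synth_ds)
    base = {e.arm: e for e in adjusted_arm_means(fits, cost_fit, synth_ds, PROG)}
    cfg = BootstrapConfig(n_reps=1, seed=0, resample=False)
    draws = bootstrap_draws(synth_ds, PROG, cfg)
    for j, arm in enumerate(draws.arms):
        assert draws.costs[0, j] == pytest.approx(base[arm].adjusted_total_cost, rel=1e-9)


def test_same_seed_bit_identical(synth_ds):
    cfg = BootstrapConfig(n_reps=40, seed=13)
    a = bootstrap_draws(synth_ds, PROG, cfg)
    b = bootstrap_draws(synth_ds, PROG, cfg)
    assert np.array_equal(a.costs, b.costs)
    assert np.array_equal(a.effects, b.effects)


def test_extending_reps_keeps_prefix(synth_ds):
    short = bootstrap_draws(synth_ds, PROG, BootstrapConfig(n_reps=20, seed=13))
    long = bootstrap_draws(synth_ds, PROG, BootstrapConfig(n_reps=40, seed=13))
    assert np.array_equal(long.costs[:20], short.costs)
    assert np.array_equal(long.effects[:20], short.effects)


class TestCEPlane:
    def test_quadrant_fractions_partition(self, small_draws):
        plane = ce_plane(small_draws, "control", "web", "pmpse")
        assert sum(plane.quadrants.values()) == pytest.approx(1.0)

    def test_identical_arms_at_origin_boundary_convention(self, small_draws):
        plane = ce_plane(small_draws, "web", "web", "pmpse")
        assert np.all(plane.delta_effect == 0)
        assert np.all(plane.delta_cost == 0)
        assert plane.quadrants["more_effective_more_costly"] == 1.0

    def test_cheaper_and_better_concentrates_lower_right(self):
        """Synthetic truth: comparator beats reference in every replicate."""
        draws = hand_draws(
            costs=[[100, 80], [120, 90], [110, 70]],
            effects=[[50, 55], [51, 56], [49, 57]],
        )
        plane = ce_plane(draws, "a", "b", "pmpse")
        assert plane.quadrants["more_effective_less_costly"] == 1.0


class TestCEAC:
    def test_probabilities_sum_to_one(self, small_draws):
        curve = ceac(small_draws, default_wtp_grid(), "pmpse")
        assert np.allclose(curve.probabilities.sum(axis=1), 1.0)
        assert ((curve.probabilities >= 0) & (curve.probabilities <= 1)).all().all()

    def test_lambda_zero_is_cheapest_fraction(self, small_draws):
        curve = ceac(small_draws, [0.0], "pmpse")
        cheapest = small_draws.costs.argmin(axis=1)
        for j, arm in enumerate(small_draws.arms):
            assert curve.probabilities.iloc[0][arm] == pytest.approx(
                (cheapest == j).mean()
            )

    def test_always_dominant_arm_has_unit_curve(self):
        draws = hand_draws(
            costs=[[100, 80], [120, 90]], effects=[[50, 55], [51, 56]]
        )
        curve = ceac(draws, default_wtp_grid(), "pmpse")
        assert (curve.probabilities["b"] == 1.0).all()
        assert (curve.probabilities["a"] == 0.0).all()

    def test_brute_force_enumeration_oracle(self):
        """Two replicates, two arms, hand-picked values: compare against
        explicit per-replicate NMB maximization (with a tie)."""
        draws = hand_draws(costs=[[100, 130], [100, 90]], effects=[[50, 53], [52, 50]])
        lam = 10.0
        # rep 0: NMB a = 10*50-100 = 400, b = 10*53-130 = 400  -> tie, split
        # rep 1: NMB a = 10*52-100 = 420, b = 10*50-90  = 410  -> a wins
        curve = ceac(draws, [lam], "pmpse")
        assert curve.probabilities.iloc[0]["a"] == pytest.approx(0.75)
        assert curve.probabilities.iloc[0]["b"] == pytest.approx(0.25)

    def test_empty_grid_rejected(self, small_draws):
        with pytest.raises(ValueError, match="empty"):
            ceac(small_draws, [], "pmpse")


def test_bootstrap_rejects_bad_config():
    with pytest.raises(ValueError):
        BootstrapConfig(n_reps=0)
    with pytest.raises(ValueError):
        BootstrapConfig(stratify_by_arm=False)


def test_resampling_preserves_arm_sizes(synth_ds, small_draws):
    # stratification: every replicate carries all three arms, so no draw
    # can be missing (NaN) in any cell
    assert not np.isnan(small_draws.costs).any()
    assert not np.isnan(small_draws.effects).any()
    assert small_draws.costs.shape == (80, 3)
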