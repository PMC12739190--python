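import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ddrs import (ConfigurationError, InfeasiblePerturbationError, WeightConfig,
                  perturb_weights, sugar_weight_experiment, tornado_analysis)
from ddrs.score import score_cohort
from tests.conftest import make_cohort


class TestPerturbWeights:
    def test_identity_factor(self):
        base = WeightConfig()
        assert perturb_weights(base, "S", 1.0) == base

    def test_hand_renormalization_up(self):
        w = perturb_weights(WeightConfig(), "S", 1.2)
        assert w.w_S == pytest.approx(0.48)
        assert w.w_A == pytest.approx(0.52 / 0.60 * 0.20)   # 0.17333...
        assert w.w_K == pytest.approx(0.52 / 0.60 * 0.25)   # 0.21666...
        assert w.w_Q == pytest.approx(0.13)

    def test_hand_renormalization_down(self):
        w = perturb_weights(WeightConfig(), "S", 0.75)      # w_S -> 0.30
        assert w.as_tuple() == pytest.approx((0.30, 7 / 30, 7 / 24, 0.175))

    def test_infeasible_perturbation(self):
        with pytest.raises(InfeasiblePerturbationError):
            perturb_weights(WeightConfig(), "S", 2.6)
        with pytest.raises(ConfigurationError):
            perturb_weights(WeightConfig(), "X", 1.1)

    @given(comp=st.sampled_from(["S", "A", "K", "Q"]),
           factor=st.floats(min_value=0.05, max_value=2.0),
           wS=st.floats(min_value=0.05, max_value=0.6),
           wA=st.floats(min_value=0.05, max_value=0.3))
    @settings(max_examples=100, deadline=None)
    def test_always_sums_to_one(self, comp, factor, wS, wA):
        rest = 1.0 - wS - wA
        base = WeightConfig(w_S=wS, w_A=wA, w_K=rest * 0.6, w_Q=rest * 0.4)
        assume(factor * base.weight_of(comp) < 1.0)
        w = perturb_weights(base, comp, factor)
        assert sum(w.as_tuple()) == pytest.approx(1.0, abs=1e-9)
        lo, hi = sorted([base.weight_of(comp), w.weight_of(comp)])
        if factor != 1.0:
            assert lo < hi


class TestTornado:
    def test_zero_pct_gives_all_zero_ranges(self, calibrated_cohort):
        rows = tornado_analysis(calibrated_cohort.head(100), pct=0.0)
        assert all(r.delta_range == 0.0 for r in rows)

    def test_rows_sorted_and_cover_all_components(self, calibrated_cohort):
        rows = tornado_analysis(calibrated_cohort)
        assert sorted(r.component for r in rows) == ["A", "K", "Q", "S"]
        deltas = [r.delta_range for r in rows]
        assert deltas == sorted(deltas, reverse=True)

    def test_sugar_tops_calibrated_cohort(self, calibrated_cohort):
        rows = tornado_analysis(calibrated_cohort)
        assert rows[0].component == "S"

    def test_iid_equal_components_rank_by_weight(self):
        """Equal-mean, equal-variance components order as S > K > A > Q."""
        rng = np.random.default_rng(8)
        n = 5000
        comps = [100 * rng.beta(2, 2, n) for _ in range(4)]
        # risk terms use 100-K and 100-Q; flip so all four terms share one mean
        cohort = make_cohort(comps[0], comps[1], 100 - comps[2], 100 - comps[3])
        order = [r.component for r in tornado_analysis(cohort)]
        assert order == ["S", "K", "A", "Q"]

    def test_constant_sugar_still_contributes_mean_shift(self):
        """With S constant, sugar's bar reflects only the mean lever arm."""
        rng = np.random.default_rng(9)
        n = 10
        cohort = make_cohort(np.full(n, 50.0), rng.uniform(0, 100, n),
                             rng.uniform(0, 100, n), rng.uniform(0, 100, n))
        rows = {r.component: r for r in tornado_analysis(cohort)}
        # brute force: delta = 0.4 * w_S * mean(S)
        assert rows["S"].delta_range == pytest.approx(0.4 * 0.40 * 50.0, abs=1e-9)


class TestSugarWeightExperiment:
    def test_weight_invariance_on_the_diagonal(self):
        # S = A = 100-K = 100-Q: DDRS equals the common value for any unit-sum weights
        cohort = make_cohort([60, 30], [60, 30], [40, 70], [40, 70])
        assert sugar_weight_experiment(cohort, renormalize=True) == pytest.approx(0.0, abs=1e-9)

    def test_two_profile_hand_arithmetic(self):
        cohort = make_cohort([80, 40], [20, 20], [80, 80], [80, 80])
        # term means: S=60, A=20, 100-K=20, 100-Q=20
        # one-at-a-time: mean(w_S) = w_S*60 + 0.2*20 + 0.25*20 + 0.15*20 = w_S*60 + 12
        low, high = 0.30 * 60 + 12, 0.50 * 60 + 12
        expected = 100 * (high - low) / low
        assert sugar_weight_experiment(cohort) == pytest.approx(expected, abs=1e-9)

    def test_calibrated_cohort_rise_near_22_pct(self, calibrated_cohort):
        rise = sugar_weight_experiment(calibrated_cohort)
        assert rise == pytest.approx(22.0, abs=6.0)

    def test_renormalized_mode_uses_unit_sum_weights(self, calibrated_cohort):
        sub = calibrated_cohort.head(500)
        rise = sugar_weight_experiment(sub, renormalize=True)
        w_low = perturb_weights(WeightConfig(), "S", 0.30 / 0.40)
        w_high = perturb_weights(WeightConfig(), "S", 0.50 / 0.40)
        m_low = score_cohort(sub, w_low).mean()
        m_high = score_cohort(sub, w_high).mean()
        assert rise == pytest.approx(100 * (m_high - m_low) / m_low, abs=1e-9)
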