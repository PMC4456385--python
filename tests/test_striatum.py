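import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgrl import (
    LEARNING_GAINS,
    SELECTION_GAINS,
    GainParams,
    StriatalWeights,
    SubjectCondition,
    apply_da_condition,
    compute_utility,
    gain,
    msn_response,
    td_error,
    update_weights,
    utility_difference,
)

#: gain constants as published for the weight-update context (the packaged
#: defaults recalibrate the D2 and risk-pool entries; see docs/methods.md)
PUBLISHED_LEARNING = GainParams(
    context="learning",
    constants={
        "D1": (1.0, -50.0, 0.0),
        "D2": (1.0, 50.0, -1.0),
        "hD1": (0.05, -0.01, -0.05),
        "hD2": (0.05, 0.01, 0.05),
    },
)


class TestGains:
    def test_d1_midpoint_is_zero(self):
        assert gain("D1", 0.0, PUBLISHED_LEARNING) == pytest.approx(0.0, abs=1e-12)
        assert gain("D1", 0.0, LEARNING_GAINS) == pytest.approx(0.0, abs=1e-12)

    def test_d1_value_at_small_positive_error(self):
        # 2 / (1 + e^-5) - 1 evaluated directly
        assert gain("D1", 0.1, PUBLISHED_LEARNING) == pytest.approx(0.9866142981514305, rel=1e-12)
        assert gain("D1", 0.1, LEARNING_GAINS) == pytest.approx(0.9866142981514305, rel=1e-12)

    def test_risk_gain_is_sum_of_half_sigmoids(self):
        # with near-flat slopes the sum sits at ~0.05 (two half-heights)
        assert gain("D1D2", 0.0, PUBLISHED_LEARNING) == pytest.approx(0.05, abs=1e-3)
        got = gain("hD1", 0.3, LEARNING_GAINS) + gain("hD2", 0.3, LEARNING_GAINS)
        assert gain("D1D2", 0.3, LEARNING_GAINS) == pytest.approx(got, rel=1e-12)

    @pytest.mark.parametrize("params", [PUBLISHED_LEARNING, LEARNING_GAINS, SELECTION_GAINS])
    def test_d1_increasing_d2_decreasing(self, params):
        grid = np.linspace(-2, 2, 401)
        lam1 = gain("D1", grid, params)
        lam2 = gain("D2", grid, params)
        # monotone over the full range; strictly so around the midpoint
        # (the steep sigmoids saturate to float-exact +-1 in the tails)
        assert np.all(np.diff(lam1) >= 0) and np.all(np.diff(lam2) <= 0)
        mid = np.linspace(-0.08, 0.08, 41)
        assert np.all(np.diff(gain("D1", mid - params.coeffs("D1")[2], params)) > 0)
        assert np.all(np.diff(gain("D2", mid - params.coeffs("D2")[2], params)) < 0)

    @pytest.mark.parametrize("params", [PUBLISHED_LEARNING, LEARNING_GAINS])
    def test_risk_gain_u_shape(self, params):
        base = gain("D1D2", 0.0, params)
        for d in (-2.0, -1.0, 1.0, 2.0):
            assert gain("D1D2", d, params) >= base

    def test_unknown_kind_rejected(self):
        with pytest.raises(KeyError):
            gain("D3", 0.0, LEARNING_GAINS)

    def test_vectorised_matches_scalar(self):
        grid = np.linspace(-1, 1, 7)
        vec = gain("D2", grid, SELECTION_GAINS)
        assert vec == pytest.approx([gain("D2", d, SELECTION_GAINS) for d in grid])


class TestMsnResponse:
    def test_response_equals_weight_for_one_hot_input(self):
        w = StriatalWeights()
        w.w_d1[2, 1] = 0.7
        w.w_d1d2[0, 0] = -0.2
        assert msn_response(w, 2, 1) == (0.7, 0.0, 0.0)
        assert msn_response(w, 0, 0) == (0.0, 0.0, -0.2)
        assert msn_response(StriatalWeights(), 1, 0) == (0.0, 0.0, 0.0)

    def test_out_of_range_indices_rejected(self):
        w = StriatalWeights()
        with pytest.raises(IndexError):
            msn_response(w, 4, 0)
        with pytest.raises(IndexError):
            msn_response(w, 0, 2)


class TestTdErrorAndCondition:
    def test_td_error_examples(self):
        assert td_error(1, 0) == 1
        assert td_error(0, 0.4) == pytest.approx(-0.4)
        assert td_error(-1, -1) == 0

    def test_controls_pass_through(self, conditions):
        assert apply_da_condition(0.5, conditions["HC"]) == 0.5
        assert apply_da_condition(-0.7, conditions["HC"]) == -0.7

    def test_off_clamps_from_above_only(self, conditions):
        off = conditions["PD-OFF"]
        assert apply_da_condition(0.5, off) == pytest.approx(0.001)
        assert apply_da_condition(-0.5, off) == -0.5

    def test_medication_adds_after_clamp(self, conditions):
        on = conditions["PD-ON-ICD"]
        assert apply_da_condition(0.5, on) == pytest.approx(0.061)
        assert apply_da_condition(-0.5, on) == pytest.approx(-0.44)

    @given(delta=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conditioned_error_respects_bounds(self, delta):
        off = SubjectCondition.from_group("PD-OFF")
        on = SubjectCondition.from_group("PD-ON-nonICD")
        assert apply_da_condition(delta, off) <= off.delta_lim
        assert apply_da_condition(delta, on) <= on.delta_lim + on.delta_med

    def test_medication_without_clamp_rejected(self):
        with pytest.raises(ValueError):
            SubjectCondition(group="X", alpha_d1=1, alpha_d2=1, alpha_d1d2=0, delta_med=0.06)


class TestUtility:
    def test_risk_adjustment_flips_with_valence(self):
        assert compute_utility(0.5, 0.2, 1.0) == pytest.approx(0.3)
        assert compute_utility(-0.5, 0.2, 1.0) == pytest.approx(-0.3)
        assert compute_utility(0.4, 0.3, 0.0) == pytest.approx(0.4)

    def test_zero_value_carries_no_risk_adjustment(self):
        assert compute_utility(0.0, 5.0, 1.0) == 0.0

    @given(q=st.floats(-2, 2), h=st.floats(-2, 2))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_zero_risk_sensitivity_reduces_to_value(self, q, h):
        assert compute_utility(q, h, 0.0) == q

    def test_utility_difference(self):
        assert utility_difference(0.3, 0.1) == pytest.approx(0.2)
        assert utility_difference(0.3, None) == 0.0  # first trial
        assert utility_difference(0.4, 0.4) == 0.0


class TestWeightUpdate:
    def test_update_magnitude_from_gain(self, conditions):
        w = StriatalWeights()
        out = update_weights(w, 1, 0, 0.1, conditions["HC"], PUBLISHED_LEARNING)
        assert out.w_d1[1, 0] == pytest.approx(0.01 * 0.9866142981514305, rel=1e-9)
        assert np.count_nonzero(out.w_d1) == 1

    def test_zero_error_leaves_value_weight_unchanged(self, conditions):
        w = StriatalWeights()
        out = update_weights(w, 0, 0, 0.0, conditions["HC"], PUBLISHED_LEARNING)
        assert out.w_d1[0, 0] == 0.0

    def test_update_is_local(self, conditions):
        rng = np.random.default_rng(3)
        w = StriatalWeights(w_d1=rng.normal(size=(4, 2)), w_d2=rng.normal(size=(4, 2)),
                            w_d1d2=rng.normal(size=(4, 2)))
        out = update_weights(w, 2, 1, -0.5, conditions["HC"])
        for a, b in ((w.w_d1, out.w_d1), (w.w_d2, out.w_d2), (w.w_d1d2, out.w_d1d2)):
            mask = np.ones((4, 2), bool)
            mask[2, 1] = False
            assert np.array_equal(a[mask], b[mask])

    def test_repeated_updates_track_reward_direction(self, conditions):
        # with a fixed stochastic reward schedule, Q(s,a) drifts toward the
        # empirical mean reward over many updates
        rng = np.random.default_rng(1)
        w = StriatalWeights()
        hc = conditions["HC"]
        for _ in range(1000):
            r = 1.0 if rng.random() < 0.8 else 0.0
            delta = td_error(r, w.w_d1[0, 0])
            w = update_weights(w, 0, 0, delta, hc)
        assert w.w_d1[0, 0] > 0.5


class TestSubjectTable:
    def test_group_parameters_load_exactly(self, conditions):
        rows = {
            "HC": (1, 0.185, 0.997, None, None),
            "PD-OFF": (1, 0.991, 0.033, 0.001, None),
            "PD-ON-ICD": (1, 0.046, 0.001, 0.001, 0.06),
            "PD-ON-nonICD": (1, 0.916, 0.160, 0.001, 0.06),
        }
        for g, (a1, a2, a12, lim, med) in rows.items():
            c = conditions[g]
            assert (c.alpha_d1, c.alpha_d2, c.alpha_d1d2) == (a1, a2, a12)
            assert c.delta_lim == lim and c.delta_med == med
            assert (c.eta_d1, c.eta_d2, c.eta_d1d2) == (0.01, 0.1, 0.1)

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError):
            SubjectCondition.from_group("PD-ON")
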