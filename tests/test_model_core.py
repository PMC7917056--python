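"""Unit tests for the kinetic rate laws and their elementary transforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from floralpattern.model_core import (
    FieldState,
    GridSpec,
    KineticParams,
    ModelOptions,
    ag_rate,
    ap1_rate,
    effective_ap1,
    heaviside_gate,
    laplacian_matrix,
    lfy_rate,
    noflux_laplacian,
    tfl1_rate,
    uniform_fixed_point,
)

profiles = arrays(
    float,
    st.integers(3, 25),
    elements=st.floats(0.0, 100.0, allow_nan=False),
)


class TestGridSpec:
    def test_default_diameter_is_66_um(self):
        grid = GridSpec()
        assert grid.n_cells == 15
        assert grid.diameter == pytest.approx(66.0)
        assert grid.center_cell == 8

    @pytest.mark.parametrize("kwargs", [{"n_cells": 2}, {"cell_length": 0.0}])
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)


class TestKineticParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k3"):
            KineticParams(k3=-1.0)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError, match="beta1"):
            KineticParams(beta1=0.0)

    def test_defaults_satisfy_intervals_except_exempt_k5(self):
        p = KineticParams()
        assert p.interval_violations() == {}
        # the published k5 interval excludes the published k5 value
        assert p.interval_violations(exempt=()) == {
            "k5": (0.09, (0.9, 1.5))
        }

    def test_out_of_interval_flagged_by_name(self):
        p = KineticParams(k9=0.6)
        assert "k9" in p.interval_violations()


class TestModelOptions:
    def test_defaults(self):
        o = ModelOptions()
        assert (o.gate_scope, o.denominator_scope) == ("all_production", "shared")
        assert (o.ap1_feedback, o.exclusion_driver) == ("raw", "AG")
        assert o.clip_negative

    def test_unknown_enum_value_rejected(self):
        with pytest.raises(ValueError, match="gate_scope"):
            ModelOptions(gate_scope="sometimes")


class TestEffectiveAp1:
    @pytest.mark.parametrize(
        "ap1, ag, beta1, expected",
        [
            ([1.0, 1.0], [0.0, 0.0], 0.05, [1.0, 1.0]),  # no AG, no exclusion
            ([2.0], [0.05], 0.05, [1.0]),  # ag = beta1: half suppression
            ([1.0], [0.45], 0.05, [0.1]),  # 1 * (1 - 0.45/0.50)
        ],
    )
    def test_known_values(self, ap1, ag, beta1, expected):
        out = effective_ap1(np.array(ap1), np.array(ag), beta1)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_length_mismatch_and_bad_beta(self):
        with pytest.raises(ValueError):
            effective_ap1(np.ones(3), np.ones(2), 0.05)
        with pytest.raises(ValueError):
            effective_ap1(np.ones(3), np.ones(3), 0.0)

    @given(profiles, st.floats(1e-3, 10.0))
    def test_bounded_between_zero_and_ap1(self, v, beta1):
        ap1 = v
        ag = v[::-1].copy()
        out = effective_ap1(ap1, ag, beta1)
        assert np.all(out >= 0.0)
        assert np.all(out <= ap1 + 1e-12)


class TestHeavisideGate:
    @pytest.mark.parametrize(
        "t, gate, expected",
        [(17999.0, 18000.0, 0.0), (18000.0, 18000.0, 1.0), (57600.0, 18000.0, 1.0)],
    )
    def test_boundary_convention_right_continuous(self, t, gate, expected):
        assert heaviside_gate(t, gate) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            heaviside_gate(-1.0)


class TestNofluxLaplacian:
    def test_uniform_field_gives_zeros(self):
        np.testing.assert_array_equal(noflux_laplacian(np.full(15, 3.7)), 0.0)

    def test_hand_evaluated_spike(self):
        # mirrored ghost cells: ends see themselves as the missing neighbour
        np.testing.assert_array_equal(
            noflux_laplacian(np.array([0.0, 1.0, 0.0])), [1.0, -2.0, 1.0]
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            noflux_laplacian(np.array([1.0, 2.0]))

    @given(profiles)
    def test_conservation_sum_is_zero(self, v):
        assert noflux_laplacian(v).sum() == pytest.approx(
            0.0, abs=1e-9 * max(1.0, np.abs(v).max())
        )

    @given(profiles)
    def test_matrix_form_agrees(self, v):
        np.testing.assert_allclose(
            laplacian_matrix(v.size) @ v, noflux_laplacian(v), atol=1e-12
        )


def _uniform_state(t=0.0, lfy=0.0, ap1=0.0, ag=0.0, tfl1=0.0, wus=0.0, n=15):
    return FieldState.uniform(n, t=t, lfy=lfy, ap1=ap1, ag=ag, tfl1=tfl1, wus=wus)


class TestRateLaws:
    def test_lfy_rate_uniform_balance(self, uniform_params):
        # k1 - k4 with defaults: 0.03 - 0.04 = -0.01
        state = _uniform_state(lfy=1.0)
        np.testing.assert_allclose(lfy_rate(state, uniform_params), -0.01)

    def test_lfy_rate_zero_state_gives_k1(self, uniform_params):
        np.testing.assert_allclose(lfy_rate(_uniform_state(), uniform_params), 0.03)

    def test_lfy_coupling_vanishes_on_any_uniform_state(self, uniform_params):
        state = _uniform_state(lfy=2.3, ap1=1.1, tfl1=0.4)
        with_eps = lfy_rate(state, uniform_params)
        without = lfy_rate(state, uniform_params.replace(epsilon=0.0))
        np.testing.assert_array_equal(with_eps, without)

    def test_ap1_rate_zero_state_gives_k5(self, uniform_params):
        np.testing.assert_allclose(ap1_rate(_uniform_state(), uniform_params), 0.09)

    def test_ap1_rate_direct_evaluation(self, uniform_params):
        state = _uniform_state(lfy=1.0, tfl1=1.0)
        # 0.09 + 0.05 - 0.02
        np.testing.assert_allclose(ap1_rate(state, uniform_params), 0.12)

    def test_ag_rate_closed_gate_silences_production(self, uniform_params):
        state = _uniform_state(t=100.0, lfy=5.0, ap1=2.0, wus=1.0)
        np.testing.assert_array_equal(ag_rate(state, uniform_params), 0.0)

    def test_ag_rate_zero_state_after_gate(self, uniform_params):
        state = _uniform_state(t=20000.0)
        np.testing.assert_array_equal(ag_rate(state, uniform_params), 0.0)

    def test_ag_rate_direct_evaluation_shared_denominator(self):
        p = KineticParams(k9=0.5)
        state = _uniform_state(t=20000.0, lfy=1.548, ap1=2.85, tfl1=1.256, wus=1.0)
        expected = (0.5 + 0.025 * 1.548) / (1.0 + 0.55 * 2.85) - 0.03 * 1.256
        np.testing.assert_allclose(ag_rate(state, p), expected, rtol=1e-12)
        assert expected == pytest.approx(0.172, abs=5e-3)

    def test_ag_rate_alternate_readings_differ(self):
        p = KineticParams()
        state = _uniform_state(t=1000.0, lfy=1.5, ap1=2.0, wus=1.0)
        gated_all = ag_rate(state, p, ModelOptions())
        gated_wus = ag_rate(state, p, ModelOptions(gate_scope="wus_term_only"))
        # pre-gate: the wus-only reading lets the LFY term through
        assert np.all(gated_all == 0.0 - p.k12 * state.ag - p.k11 * state.tfl1)
        assert np.all(gated_wus > gated_all)

    def test_tfl1_rate_zero_state_gives_k13(self, uniform_params):
        np.testing.assert_allclose(tfl1_rate(_uniform_state(), uniform_params), 0.9)

    def test_tfl1_rate_negative_under_strong_repression(self, uniform_params):
        state = _uniform_state(lfy=50.0, ap1=50.0)
        assert np.all(tfl1_rate(state, uniform_params) < 0.0)


class TestUniformFixedPoint:
    def test_table_defaults(self, uniform_params):
        # frozen from the independent 3x3 linear solve (numpy.linalg.solve
        # on the balance equations), cross-checked by long simulation
        lfy, ap1, tfl1 = uniform_fixed_point(uniform_params)
        assert lfy == pytest.approx(1.5390625, abs=1e-9)
        assert ap1 == pytest.approx(2.8359375, abs=1e-9)
        assert tfl1 == pytest.approx(1.2578125, abs=1e-9)

    def test_fixed_point_zeroes_the_rates(self, uniform_params):
        lfy, ap1, tfl1 = uniform_fixed_point(uniform_params)
        state = _uniform_state(lfy=lfy, ap1=ap1, tfl1=tfl1)
        p = uniform_params.replace(epsilon=0.0)
        np.testing.assert_allclose(lfy_rate(state, p), 0.0, atol=1e-12)
        np.testing.assert_allclose(ap1_rate(state, p), 0.0, atol=1e-12)
        np.testing.assert_allclose(tfl1_rate(state, p), 0.0, atol=1e-12)

    def test_decoupled_closed_form(self):
        p = KineticParams(k2=0, k3=0, k6=0, k7=0, k14=0, k15=0)
        lfy, ap1, tfl1 = uniform_fixed_point(p)
        assert lfy == pytest.approx(0.75)
        assert ap1 == pytest.approx(1.8)
        assert tfl1 == pytest.approx(0.9 / 0.55)

    def test_all_production_zero(self):
        p = KineticParams(k1=0, k5=0, k13=0)
        assert uniform_fixed_point(p) == (0.0, 0.0, 0.0)

    def test_negative_component_pinned_at_zero(self):
        # with k5 = 0.9 the unconstrained solve drives tfl1 negative;
        # the reduced 2x2 system gives (19.5, 37.5) by hand algebra
        p = KineticParams(k5=0.9)
        lfy, ap1, tfl1 = uniform_fixed_point(p)
        assert tfl1 == 0.0
        assert lfy == pytest.approx(19.5, rel=1e-9)
        assert ap1 == pytest.approx(37.5, rel=1e-9)
        # clipping is consistent: tfl1 rate at the pinned point is negative
        state = _uniform_state(lfy=lfy, ap1=ap1, tfl1=0.0)
        assert np.all(tfl1_rate(state, p) < 0.0)


class TestFieldState:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ag"):
            FieldState(0.0, np.ones(15), np.ones(15), np.ones(14),
                       np.ones(15), np.ones(15), np.ones(15))

    def test_ap1_T_identity_holds(self):
        rng = np.random.default_rng(42)
        state = FieldState(0.0, *(rng.uniform(0, 2, 15) for _ in range(6)))
        expected = state.ap1 * (1.0 - state.ag / (state.ag + 0.05))
        np.testing.assert_allclose(state.ap1_T(0.05), expected, rtol=1e-12)

    def test_array_round_trip(self):
        state = FieldState.uniform(15, lfy=1.0, tfl1=0.1, wus=1.0)
        again = FieldState.from_array(state.t, state.as_array())
        np.testing.assert_array_equal(again.as_array(), state.as_array())
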