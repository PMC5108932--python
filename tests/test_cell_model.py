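"""Single-cell model: current formulas, derivatives, resting state."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardiofiber import (CellParameters, CellState, INITIAL_STATE, N_STATES,
                         STATE_NAMES, cell_derivatives, compute_IK1,
                         compute_INa, currents, nernst_potassium)
from cardiofiber import _kernel
from cardiofiber.cell_model import validate_state

K_I_REF = float(INITIAL_STATE[STATE_NAMES.index("K_i")])

# hand-evaluated values of the printed I_K1 formula at the reference
# constants (K_o = 5.4 mM, k_mK1 = 10 mM, K_i = 136.5644281 mM, 310 K)
E_K_REF = -86.29606699785626
IK1_AT_EK_PLUS_10 = 0.8766233766233766
IK1_AT_EK_PLUS_30 = 1.481878890919491


class TestComputeIK1:
    def test_zero_driving_force_at_reversal(self, default_params):
        ek = nernst_potassium(default_params, K_I_REF)
        assert ek == pytest.approx(E_K_REF, rel=1e-12)
        assert compute_IK1(ek, default_params) == pytest.approx(0.0, abs=1e-12)

    def test_half_rectification_symmetry_point(self, default_params):
        # at V = E_K + 10 the rectification denominator is exactly 2, so
        # the current is G_K1 * K_o/(K_o + k_mK1) * 5
        p = default_params
        expected = p.G_K1 * p.K_o / (p.K_o + p.k_mK1) * 5.0
        got = compute_IK1(E_K_REF + 10.0, p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(IK1_AT_EK_PLUS_10, rel=1e-12)

    def test_matches_hand_evaluated_formula(self, default_params):
        got = compute_IK1(E_K_REF + 30.0, default_params)
        assert got == pytest.approx(IK1_AT_EK_PLUS_30, rel=1e-12)

    def test_rejects_non_finite_voltage(self, default_params):
        with pytest.raises(ValueError):
            compute_IK1(float("nan"), default_params)

    def test_linear_in_conductance(self, default_params):
        v = np.linspace(-120.0, 60.0, 37)
        doubled = default_params.replace(G_K1=2 * default_params.G_K1)
        np.testing.assert_allclose(compute_IK1(v, doubled),
                                   2.0 * compute_IK1(v, default_params),
                                   rtol=1e-14)

    def test_inward_rectification_interior_maximum(self, default_params):
        # the outward current rises just above E_K and falls again at
        # depolarised potentials: an interior maximum, not monotone
        v = np.linspace(E_K_REF, 40.0, 200)
        i = compute_IK1(v, default_params)
        k = int(np.argmax(i))
        assert 0 < k < v.size - 1
        assert i[k] > i[-1] and i[k] > i[0]


class TestComputeINa:
    def test_closed_activation_gate(self, default_params):
        assert compute_INa(-20.0, 0.0, 0.7, default_params) == 0.0

    def test_zero_at_reversal(self, default_params):
        p = default_params
        na = float(INITIAL_STATE[STATE_NAMES.index("Na_i")])
        e_rev = p.RTF * np.log((p.Na_o + p.P_mh * p.K_o)
                               / (na + p.P_mh * K_I_REF))
        assert compute_INa(e_rev, 0.5, 0.5, p) == pytest.approx(0.0, abs=1e-12)

    def test_conductance_times_driving_force(self, default_params):
        p = default_params
        na = float(INITIAL_STATE[STATE_NAMES.index("Na_i")])
        e_rev = p.RTF * np.log((p.Na_o + p.P_mh * p.K_o)
                               / (na + p.P_mh * K_I_REF))
        # G_Na = 0.5 uS, full gates, 50 mV below reversal: -25 nA
        assert compute_INa(e_rev - 50.0, 1.0, 1.0, p) == pytest.approx(-25.0)

    @pytest.mark.parametrize("m,h", [(-0.1, 0.5), (1.1, 0.5), (0.5, 2.0)])
    def test_rejects_out_of_range_gates(self, default_params, m, h):
        with pytest.raises(ValueError):
            compute_INa(-40.0, m, h, default_params)

    def test_linear_in_conductance(self, default_params):
        p2 = default_params.replace(G_Na=2 * default_params.G_Na)
        v = np.linspace(-80, 40, 13)
        np.testing.assert_allclose(
            compute_INa(v, 0.3, 0.6, p2),
            2 * compute_INa(v, 0.3, 0.6, default_params), rtol=1e-14)


class TestCurrents:
    def test_total_equals_component_sum(self, default_rest, default_params):
        c = currents(default_rest, default_params)
        assert c.I_ion_total == pytest.approx(
            sum(c.components.values()), rel=1e-12)

    def test_component_map_exposes_ik1_and_ina(self, default_rest,
                                               default_params):
        c = currents(default_rest, default_params)
        assert c.I_K1 == c.components["i_K1"]
        assert c.I_Na == c.components["i_Na"]


class TestCellDerivatives:
    def test_rest_is_a_fixed_point(self, default_rest, default_params):
        # the rest point was obtained by root-finding on this same RHS;
        # re-assert the residual in model units
        dy = cell_derivatives(default_rest, 0.0, default_params)
        assert np.max(np.abs(dy)) < 1e-6

    def test_gate_at_steady_value_has_zero_derivative(self, default_params):
        y = INITIAL_STATE.copy()
        V = y[0]
        a, b = _kernel.m_gate_rates(V, default_params.delta_m)
        y[STATE_NAMES.index("m")] = a / (a + b)
        dy = cell_derivatives(y, 0.0, default_params)
        assert dy[STATE_NAMES.index("m")] == pytest.approx(0.0, abs=1e-12)
        a, b = _kernel.h_gate_rates(V)
        y[STATE_NAMES.index("h")] = a / (a + b)
        dy = cell_derivatives(y, 0.0, default_params)
        assert dy[STATE_NAMES.index("h")] == pytest.approx(0.0, abs=1e-12)

    def test_external_current_enters_linearly(self, default_rest,
                                              default_params):
        d0 = cell_derivatives(default_rest, 0.0, default_params, I_ext=0.0)
        d1 = cell_derivatives(default_rest, 0.0, default_params, I_ext=-100.0)
        assert d1[0] - d0[0] == pytest.approx(100.0 / default_params.C_m)
        np.testing.assert_allclose(d1[1:], d0[1:], rtol=1e-12)

    def test_rejects_wrong_state_length(self, default_params):
        with pytest.raises(ValueError):
            cell_derivatives(np.zeros(21), 0.0, default_params)


class TestRestingState:
    def test_resting_potential_near_minus_90(self, default_rest):
        assert default_rest.V == pytest.approx(-90.0, abs=5.0)

    def test_ik1_nearly_zero_at_rest(self, default_rest, default_params):
        # V_rest sits close to E_K: essentially no driving force
        c = currents(default_rest, default_params)
        assert abs(c.I_K1) < 0.5

    def test_rest_is_stationary_under_reintegration(self, resting_cell_trace,
                                                    default_rest):
        assert np.max(np.abs(resting_cell_trace.V - default_rest.V)) < 0.1

    def test_rest_state_is_valid(self, default_rest):
        assert validate_state(default_rest.vector, strict=False)


class TestStateContainers:
    def test_state_vector_length_is_22(self):
        assert N_STATES == 22
        with pytest.raises(ValueError):
            CellState(np.zeros(21))

    def test_json_round_trip(self, tmp_path, default_rest):
        path = tmp_path / "state.json"
        default_rest.to_json(path)
        back = CellState.from_json(path)
        np.testing.assert_allclose(back.vector, default_rest.vector,
                                   rtol=0, atol=0)

    def test_named_attribute_access(self, default_rest):
        assert default_rest.V == default_rest.vector[0]
        assert default_rest.K_i == default_rest.vector[
            STATE_NAMES.index("K_i")]

    @given(st.floats(min_value=0.05, max_value=5.0))
    def test_parameter_positivity_enforced(self, g):
        CellParameters(G_K1=g)  # valid
        with pytest.raises(ValueError):
            CellParameters(G_K1=-g)


def test_trajectory_preserves_gate_bounds_and_concentrations(
        suprathreshold_cell_trace, default_params, default_rest):
    """Gates stay in [0,1] and concentrations positive along an AP."""
    # re-run a short window storing the full state at the end
    from cardiofiber import StimulusProtocol, simulate
    pr = StimulusProtocol(amplitude=-40.0, target_cells=(1,))
    tr = simulate(default_params, pr, (0.0, 120.0),
                  y0=default_rest.vector.copy())
    assert validate_state(tr.y_final, strict=False)
    assert np.all(np.isfinite(suprathreshold_cell_trace.V))
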