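"""Fiber assembly: gap-junction coupling, sealed ends, flattening."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardiofiber import (CellParameters, FiberConfig, N_STATES,
                         cell_derivatives, fiber_derivatives, gap_currents,
                         jac_sparsity, resting_fiber_state,
                         StimulusProtocol, simulate)


class TestGapCurrents:
    def test_uniform_voltage_carries_no_current(self):
        assert np.allclose(gap_currents(np.full(10, -85.0), 10.0), 0.0)

    def test_microsiemens_times_millivolts(self):
        # 10 mV step at 10 uS -> 100 nA across the interface
        v = np.array([-80.0, -90.0])
        assert gap_currents(v, 10.0)[0] == pytest.approx(100.0)

    @given(st.lists(st.floats(min_value=-120, max_value=60), min_size=2,
                    max_size=30))
    def test_net_coupling_current_conserves_charge(self, vlist):
        j = gap_currents(np.array(vlist), 7.5)
        inflow = np.r_[0.0, j] - np.r_[j, 0.0]   # per-cell coupling input
        assert sum(inflow) == pytest.approx(0.0, abs=1e-9)

    def test_rejects_single_cell(self):
        with pytest.raises(ValueError):
            gap_currents(np.array([-85.0]), 10.0)


class TestFiberDerivatives:
    def test_two_identical_cells_behave_as_isolated(self, default_rest,
                                                    default_params):
        cfg = FiberConfig(n_cells=2, cell_params=default_params)
        y = np.tile(default_rest.vector, 2)
        d = fiber_derivatives(y, 0.0, cfg)
        d_iso = cell_derivatives(default_rest, 0.0, default_params)
        np.testing.assert_allclose(d[:N_STATES], d_iso, rtol=1e-12)
        np.testing.assert_allclose(d[N_STATES:], d_iso, rtol=1e-12)

    def test_zero_coupling_decouples_cells(self, default_rest,
                                           default_params):
        cfg = FiberConfig(n_cells=3, G_gj=0.0, cell_params=default_params)
        y = np.tile(default_rest.vector, 3)
        y[0] += 20.0            # depolarise cell 1 only
        d = fiber_derivatives(y, 0.0, cfg)
        state1 = y[:N_STATES]
        d_iso = cell_derivatives(state1, 0.0, default_params)
        np.testing.assert_allclose(d[:N_STATES], d_iso, rtol=1e-12)

    def test_coupling_arithmetic_for_depolarised_cell(self, default_rest,
                                                      default_params):
        # middle cell 10 mV above both neighbours at 10 uS loses exactly
        # two 100 nA outflows: dV/dt drops by 200/C_m versus isolation
        cfg = FiberConfig(n_cells=3, G_gj=10.0, cell_params=default_params)
        y = np.tile(default_rest.vector, 3)
        y[N_STATES] += 10.0
        d = fiber_derivatives(y, 0.0, cfg)
        d_iso = cell_derivatives(y[N_STATES:2 * N_STATES], 0.0,
                                 default_params)
        drop = d_iso[0] - d[N_STATES]
        assert drop == pytest.approx(200.0 / default_params.C_m, rel=1e-9)

    def test_rejects_dimension_mismatch(self, default_params):
        cfg = FiberConfig(n_cells=4, cell_params=default_params)
        with pytest.raises(ValueError):
            fiber_derivatives(np.zeros(3 * N_STATES), 0.0, cfg)
        with pytest.raises(ValueError):
            fiber_derivatives(np.zeros(4 * N_STATES), 0.0, cfg,
                              stim=np.zeros(3))


class TestUniformFiber:
    def test_hundred_cell_fiber_exposes_2200_states(self):
        cfg = FiberConfig(n_cells=100)
        assert cfg.n_states == 2200
        assert resting_fiber_state(cfg).shape == (2200,)

    def test_interior_translation_invariance(self, default_rest,
                                             default_params):
        cfg = FiberConfig(n_cells=12, cell_params=default_params)
        y = np.tile(default_rest.vector, 12)
        d = fiber_derivatives(y, 0.0, cfg).reshape(12, N_STATES)
        for i in range(1, 11):
            np.testing.assert_allclose(d[i], d[1], rtol=1e-12)

    def test_rest_broadcast_is_a_fixed_point(self, default_rest,
                                             default_params):
        cfg = FiberConfig(n_cells=20, cell_params=default_params)
        y = np.tile(default_rest.vector, 20)
        assert np.max(np.abs(fiber_derivatives(y, 0.0, cfg))) < 1e-6


def test_sealed_end_mirror_symmetry(small_fiber):
    """Stimulating both ends identically gives a mirror-symmetric
    voltage profile at all times (sealed-end/Neumann symmetry)."""
    n = small_fiber.n_cells
    pr = StimulusProtocol(amplitude=-40.0, target_cells=(1, 2, n - 1, n))
    tr = simulate(small_fiber, pr, (0.0, 30.0))
    np.testing.assert_allclose(tr.V, tr.V[:, ::-1], atol=1e-4)


def test_jacobian_sparsity_is_block_tridiagonal():
    pat = jac_sparsity(5)
    assert pat.shape == (5 * N_STATES, 5 * N_STATES)
    dense = pat.toarray()
    # a voltage couples to its neighbours' voltages...
    assert dense[0, N_STATES] and dense[N_STATES, 0]
    # ...but never to states two cells away
    assert not dense[:N_STATES, 2 * N_STATES:].any()


def test_config_validation():
    with pytest.raises(ValueError):
        FiberConfig(n_cells=1)
    with pytest.raises(ValueError):
        FiberConfig(G_gj=-1.0)
    assert FiberConfig().L_c == 74.0
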