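"""Measurement protocols: AP detection, thresholds, CV, lambda, APD."""

import numpy as np
import pytest

from cardiofiber import (CellParameters, FiberConfig, StimulusProtocol,
                         find_cell_threshold, measure_apd, simulate)
from cardiofiber.engine import SimulationTrace
from cardiofiber.protocols import activation_time, detect_ap


def _trace_from(t, v):
    v = np.asarray(v, float).reshape(-1, 1)
    pr = StimulusProtocol(amplitude=-1.0, target_cells=(1,))
    return SimulationTrace(t=np.asarray(t, float), V=v, protocol=pr,
                           y_final=np.zeros(22))


class TestDetectAP:
    def test_suprathreshold_cell_trace(self, suprathreshold_cell_trace):
        tr = suprathreshold_cell_trace
        assert detect_ap(tr.cell(1), tr.t, (5.0, 55.0))
        assert tr.cell(1).max() > 20.0   # a full AP, not a hump

    def test_resting_trace_has_no_ap(self, resting_cell_trace):
        tr = resting_cell_trace
        assert not detect_ap(tr.cell(1), tr.t, (0.0, 1000.0))

    def test_subthreshold_response_not_detected(self, default_params,
                                                default_rest,
                                                cell_threshold_default):
        # one 0.5 nA grid step below threshold: a passive hump that
        # peaks well below 0 mV and decays back to rest
        amp = cell_threshold_default.amplitude + 0.5
        pr = StimulusProtocol(amplitude=amp, target_cells=(1,))
        tr = simulate(default_params, pr, (0.0, 100.0),
                      y0=default_rest.vector.copy())
        assert not detect_ap(tr.cell(1), tr.t, (5.0, 55.0))
        assert tr.cell(1).max() < -20.0

    def test_empty_window_raises(self, resting_cell_trace):
        with pytest.raises(ValueError):
            detect_ap(resting_cell_trace.cell(1), resting_cell_trace.t,
                      (2000.0, 2100.0))


class TestAPD:
    def test_trapezoid_width_recovered_exactly(self):
        # constructed waveform: instant upstroke at t=10, plateau at
        # +20 mV until t=110, instant drop back to rest
        t = np.linspace(0.0, 200.0, 4001)  # 0.05 ms sampling
        v = np.full_like(t, -85.0)
        v[(t >= 10.0) & (t < 110.0)] = 20.0
        apd = measure_apd(_trace_from(t, v), level=0.9)
        assert apd == pytest.approx(100.0, abs=0.1)

    def test_no_ap_raises(self, resting_cell_trace):
        with pytest.raises(ValueError):
            measure_apd(resting_cell_trace)

    def test_apd_levels_are_ordered(self, suprathreshold_cell_trace,
                                    default_rest):
        tr = suprathreshold_cell_trace
        apd50 = measure_apd(tr, level=0.5, v_rest=default_rest.V)
        apd90 = measure_apd(tr, level=0.9, v_rest=default_rest.V)
        assert 0 < apd50 < apd90
        assert 40.0 < apd90 < 600.0   # physiological ventricular range

    def test_unrepolarised_trace_reports_inf(self):
        t = np.linspace(0.0, 100.0, 2001)
        v = np.where(t < 10.0, -85.0, 15.0)   # never repolarises
        assert measure_apd(_trace_from(t, v)) == np.inf


class TestActivationTime:
    def test_maximum_upstroke_instant(self):
        t = np.linspace(0.0, 10.0, 1001)
        v = -85.0 + 100.0 / (1.0 + np.exp(-(t - 4.0) / 0.2))
        assert activation_time(t, v) == pytest.approx(4.0, abs=0.02)

    def test_ties_resolve_to_earliest(self):
        t = np.linspace(0.0, 5.0, 501)
        v = np.zeros_like(t)
        assert activation_time(t, v) == t[0]


class TestCellThreshold:
    def test_bracket_equals_literal_incremental_search(self):
        """The accelerated search must reproduce the pure 0.5 nA
        incremental scan on several parameter points."""
        for kw in ({}, {"G_Na": 2.0}, {"G_K1": 1.0}):
            p = CellParameters(**kw)
            fast = find_cell_threshold(p, method="bracket")
            slow = find_cell_threshold(p, method="incremental")
            assert fast.amplitude == slow.amplitude, kw
            assert fast.n_simulations < slow.n_simulations

    def test_threshold_on_resolution_grid(self, cell_threshold_default):
        r = cell_threshold_default
        assert not r.inexcitable
        assert r.resolution == 0.5
        assert abs(r.amplitude / r.resolution
                   - round(r.amplitude / r.resolution)) < 1e-9

    def test_magnitude_monotone_in_gna(self):
        # more sodium conductance -> easier to excite
        mags = [find_cell_threshold(CellParameters(G_Na=g)).magnitude
                for g in (0.25, 0.5, 2.0)]
        assert mags[0] >= mags[1] >= mags[2]
        assert mags[0] > mags[2]

    def test_magnitude_monotone_in_gk1(self):
        # more inward rectifier -> harder to excite
        mags = [find_cell_threshold(CellParameters(G_K1=g)).magnitude
                for g in (0.3, 0.5, 2.0)]
        assert mags[0] <= mags[1] <= mags[2]
        assert mags[0] < mags[2]
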