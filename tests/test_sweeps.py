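"""Sweep machinery: grids, ratio semantics, shape classification."""

import numpy as np
import pytest

from cardiofiber import SweepSpec, default_grids, run_sweep, summarize_shape
from cardiofiber.sweeps import (GGJ_GRID, GK1_RANGE, GNA_RANGE, GGJ_RANGE,
                                RATIOS, gk1_grid, gna_grid)


class TestSummarizeShape:
    def test_monotone_sequences(self):
        assert summarize_shape([1, 3, 6, 10, 15]) == "monotone-increasing"
        assert summarize_shape([15, 10, 6, 3, 1]) == "monotone-decreasing"

    def test_single_interior_extremum_is_biphasic(self):
        assert summarize_shape([5, 3, 2, 4, 8]) == "biphasic"

    def test_two_extrema_is_triphasic(self):
        assert summarize_shape([5, 2, 6, 9, 3, 1]) == "triphasic"

    def test_noise_floor_suppresses_quantisation(self):
        # 0.4 nA wiggles are below the 0.5 nA search resolution
        assert summarize_shape([10.0, 10.4, 10.1, 12.0, 14.0]) == \
            "monotone-increasing"

    def test_flat_and_too_short(self):
        assert summarize_shape([1.0, 1.1, 0.9, 1.0]) == "flat"
        with pytest.raises(ValueError):
            summarize_shape([1, 2, 3])

    def test_ignores_inexcitable_gaps(self):
        assert summarize_shape([1, 2, np.nan, 4, 8]) == "monotone-increasing"


class TestSpecSemantics:
    @pytest.mark.parametrize("ratio,expected_gna", [
        ((1, 2), 2.0), ((1, 1), 1.0), ((2, 1), 0.5)])
    def test_ratio_maps_grid_to_gna(self, ratio, expected_gna):
        # ratio a:b means (G_K1, G_Na) = (g, g*b/a); the grid indexes G_K1
        spec = SweepSpec(mode="reciprocal", ratio=ratio, grid=(1.0,))
        (gk1, gna), = spec.conductances()
        assert gk1 == 1.0 and gna == pytest.approx(expected_gna)

    def test_independent_modes_hold_the_other_conductance(self):
        s = SweepSpec(mode="independent-GNa", grid=(2.0,), target="cell",
                      measurements=("threshold",))
        assert s.conductances() == [(0.5, 2.0)]
        s = SweepSpec(mode="independent-GK1", grid=(2.0,), target="cell",
                      measurements=("threshold",))
        assert s.conductances() == [(2.0, 0.5)]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(mode="both")
        with pytest.raises(ValueError):
            SweepSpec(target="cell", measurements=("cv",))
        with pytest.raises(ValueError):
            SweepSpec(measurements=("foo",))


class TestDefaultGrids:
    def test_ggj_grid_spans_study_range_including_baseline(self):
        assert len(GGJ_GRID) == 8
        assert 10.0 in GGJ_GRID
        assert min(GGJ_GRID) == 0.1 and max(GGJ_GRID) == 20.0

    def test_all_reciprocal_ratios_present(self):
        specs = default_grids()
        ratios = {s.ratio for s in specs.values() if s.mode == "reciprocal"}
        assert ratios == set(RATIOS)

    def test_no_grid_value_outside_stated_ranges(self):
        for name, spec in default_grids().items():
            for gk1, gna in spec.conductances():
                if spec.mode != "independent-GNa":
                    assert GK1_RANGE[0] <= gk1 <= GK1_RANGE[1], name
                if spec.mode == "independent-GNa":
                    assert GNA_RANGE[0] <= gna <= GNA_RANGE[1], name
            for ggj in spec.G_gj:
                if np.isfinite(ggj):
                    assert GGJ_RANGE[0] <= ggj <= GGJ_RANGE[1], name

    def test_gk1_grid_refined_near_excitability_boundary(self):
        g = gk1_grid()
        steps = np.diff(g[(g >= 1.0) & (g <= 1.6)])
        assert np.all(steps <= 0.1 + 1e-9)
        assert gna_grid()[0] == 0.2


class TestRunSweep:
    def test_cell_threshold_sweep_records(self, tmp_path):
        """A small real sweep: |threshold| grows with G_K1, records are
        well-formed, and rows are flushed to CSV as they complete."""
        csv = tmp_path / "sweep.csv"
        spec = SweepSpec(mode="independent-GK1", grid=(0.5, 1.0, 2.0),
                         target="cell", measurements=("threshold",),
                         G_gj=(np.nan,))
        df = run_sweep(spec, csv_path=csv)
        assert len(df) == 3
        assert (df["error"] == "").all()
        assert not df["inexcitable"].any()
        mags = -df["threshold_nA"].to_numpy()
        assert np.all(np.diff(mags) >= 0) and mags[-1] > mags[0]
        on_disk = np.loadtxt(csv, delimiter=",", skiprows=1, usecols=3)
        np.testing.assert_allclose(on_disk, df["threshold_nA"])

    def test_sweep_is_deterministic_at_grid_resolution(self):
        spec = SweepSpec(mode="independent-GK1", grid=(0.75,), target="cell",
                         measurements=("threshold",), G_gj=(np.nan,))
        a = run_sweep(spec)["threshold_nA"].iloc[0]
        b = run_sweep(spec)["threshold_nA"].iloc[0]
        assert a == b
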