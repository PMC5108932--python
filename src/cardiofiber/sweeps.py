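"""Parameter sweeps: independent and reciprocal conductance modulation.

Two sweep modes drive the study: *independent* modulation changes a
single conductance (G_Na or G_K1) with the other held at its 0.5 uS
default, and *reciprocal* modulation changes both in tandem at a fixed
G_K1:G_Na ratio (1:2, 1:1, or 2:1).  The grid always indexes G_K1 in
reciprocal mode; the G_Na value follows from the ratio, so ratio a:b
maps grid value g to (G_K1, G_Na) = (g, g*b/a).

Each grid point yields one record (threshold, optionally CV and the
space constant); per-point failures are recorded and the sweep
continues.  Sweeps are deterministic and resumable: records are flushed
to CSV as they are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_model import CellParameters
from .fiber_model import FiberConfig
from . import protocols

__all__ = ["SweepSpec", "run_sweep", "summarize_shape", "default_grids",
           "RATIOS", "GGJ_GRID"]

MODES = ("independent-GNa", "independent-GK1", "reciprocal")
RATIOS = ((1, 2), (1, 1), (2, 1))

# conductance ranges of the study (uS)
GNA_RANGE = (0.2, 5.0)
GK1_RANGE = (0.3, 5.0)
GGJ_RANGE = (0.1, 20.0)

#: the eight coupling conductances of the G_gj sweeps, uS
GGJ_GRID = (0.1, 0.2, 0.3, 0.5, 1.0, 5.0, 10.0, 20.0)


def gna_grid(step_coarse: float = 0.25) -> np.ndarray:
    """Default G_Na grid, 0.2-5 uS."""
    g = np.unique(np.r_[0.2, np.arange(0.25, 5.0 + 1e-9, step_coarse)])
    return g[(g >= GNA_RANGE[0] - 1e-9) & (g <= GNA_RANGE[1] + 1e-9)]


def gk1_grid(fine_lo: float = 1.0, fine_hi: float = 1.6) -> np.ndarray:
    """Default G_K1 grid, 0.3-5 uS: 0.1 uS steps near the excitability
    boundary and 0.25 uS steps elsewhere."""
    coarse = np.arange(0.25, 5.0 + 1e-9, 0.25)
    fine = np.arange(fine_lo, fine_hi + 1e-9, 0.1)
    g = np.unique(np.round(np.r_[0.3, coarse, fine], 10))
    return g[(g >= GK1_RANGE[0] - 1e-9) & (g <= GK1_RANGE[1] + 1e-9)]


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep over a conductance grid.

    ``target`` selects isolated-cell or fiber measurements; ``ratio``
    only applies in reciprocal mode.  ``measurements`` is a subset of
    {"threshold", "cv", "lambda"} ("cv" and "lambda" require a fiber).
    """

    mode: str = "reciprocal"
    ratio: tuple = (1, 1)
    grid: tuple = field(default_factory=lambda: tuple(gk1_grid()))
    G_gj: tuple = (10.0,)
    target: str = "fiber"
    measurements: tuple = ("threshold",)
    n_cells: int = 100
    base_params: CellParameters = field(default_factory=CellParameters)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.target not in ("cell", "fiber"):
            raise ValueError("target must be 'cell' or 'fiber'")
        bad = set(self.measurements) - {"threshold", "cv", "lambda"}
        if bad:
            raise ValueError(f"unknown measurements {bad}")
        if self.target == "cell" and set(self.measurements) != {"threshold"}:
            raise ValueError("cell sweeps measure thresholds only")
        if self.mode == "reciprocal":
            a, b = self.ratio
            if not (a > 0 and b > 0):
                raise ValueError("ratio weights must be positive")

    def conductances(self) -> list[tuple[float, float]]:
        """(G_K1, G_Na) pairs over the grid."""
        out = []
        for g in self.grid:
            if self.mode == "independent-GNa":
                out.append((self.base_params.G_K1, float(g)))
            elif self.mode == "independent-GK1":
                out.append((float(g), self.base_params.G_Na))
            else:
                a, b = self.ratio
                out.append((float(g), float(g) * b / a))
        return out

    def replace(self, **kw) -> "SweepSpec":
        return replace(self, **kw)


def _measure_point(spec: SweepSpec, gk1: float, gna: float,
                   ggj: float) -> dict:
    params = spec.base_params.replace(G_K1=gk1, G_Na=gna)
    rec = {"G_K1": gk1, "G_Na": gna, "G_gj": ggj,
           "threshold_nA": np.nan, "inexcitable": False,
           "cv_cm_s": np.nan, "lambda_cells": np.nan,
           "n_sims": 0, "error": ""}
    thr = None
    if "threshold" in spec.measurements or "cv" in spec.measurements:
        if spec.target == "cell":
            thr = protocols.find_cell_threshold(params)
        else:
            cfg = FiberConfig(n_cells=spec.n_cells, G_gj=ggj,
                              cell_params=params)
            thr = protocols.find_fiber_threshold(cfg)
        rec["n_sims"] += thr.n_simulations
        rec["inexcitable"] = thr.inexcitable
        if not thr.inexcitable:
            rec["threshold_nA"] = thr.amplitude
    if spec.target == "fiber":
        cfg = FiberConfig(n_cells=spec.n_cells, G_gj=ggj, cell_params=params)
        if "cv" in spec.measurements and thr is not None and not thr.inexcitable:
            cv = protocols.measure_cv(cfg, threshold=thr)
            rec["cv_cm_s"] = cv.cv_cm_s
        if "lambda" in spec.measurements:
            fit = protocols.measure_space_constant(cfg)
            rec["lambda_cells"] = fit.lam_cells
    return rec


def run_sweep(spec: SweepSpec, *, csv_path: str | Path | None = None,
              progress=None) -> pd.DataFrame:
    """Run all grid points of ``spec``; one row per (grid value, G_gj).

    Integrator failures at a point are caught, recorded in the ``error``
    column, and the sweep continues.  If ``csv_path`` is given, records
    are appended to the file as they complete (resumable output).
    """
    rows = []
    path = Path(csv_path) if csv_path else None
    if path is not None and path.exists():
        path.unlink()
    for ggj in spec.G_gj:
        for gk1, gna in spec.conductances():
            try:
                rec = _measure_point(spec, gk1, gna, ggj)
            except Exception as exc:  # keep sweeping; report at the point
                rec = {"G_K1": gk1, "G_Na": gna, "G_gj": ggj,
                       "threshold_nA": np.nan, "inexcitable": False,
                       "cv_cm_s": np.nan, "lambda_cells": np.nan,
                       "n_sims": 0, "error": f"{type(exc).__name__}: {exc}"}
            rows.append(rec)
            if path is not None:
                pd.DataFrame([rec]).to_csv(path, mode="a", index=False,
                                           header=not path.exists())
            if progress is not None:
                progress(rec)
    return pd.DataFrame(rows)


def summarize_shape(values, *, noise_floor: float = 0.5) -> str:
    """Classify a measurement-vs-grid curve by its sign changes.

    Successive differences smaller than ``noise_floor`` (the threshold
    search resolution, for threshold curves) are treated as quantisation
    noise.  Returns "monotone-increasing", "monotone-decreasing",
    "biphasic" (one interior extremum), "triphasic" (two), "flat", or
    "complex".
    """
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 finite points to classify")
    d = np.diff(v)
    signs = np.sign(d[np.abs(d) > noise_floor])
    if signs.size == 0:
        return "flat"
    # collapse runs of equal sign
    runs = [signs[0]]
    for s in signs[1:]:
        if s != runs[-1]:
            runs.append(s)
    n_changes = len(runs) - 1
    if n_changes == 0:
        return "monotone-increasing" if runs[0] > 0 else "monotone-decreasing"
    if n_changes == 1:
        return "biphasic"
    if n_changes == 2:
        return "triphasic"
    return "complex"


def default_grids() -> dict[str, SweepSpec]:
    """The sweep specifications behind the study's figure families.

    Keys name the measurement family; every grid stays inside the stated
    ranges (G_Na 0.2-5, G_K1 0.3-5, G_gj 0.1-20 uS).
    """
    cell = dict(target="cell", measurements=("threshold",), G_gj=(np.nan,))
    fiber = dict(target="fiber", G_gj=(10.0,))
    specs = {
        "cell-threshold-vs-GNa": SweepSpec(mode="independent-GNa",
                                           grid=tuple(gna_grid()), **cell),
        "cell-threshold-vs-GK1": SweepSpec(mode="independent-GK1",
                                           grid=tuple(gk1_grid()), **cell),
        "fiber-threshold-vs-GNa": SweepSpec(
            mode="independent-GNa", grid=tuple(gna_grid()),
            measurements=("threshold",), **fiber),
        "fiber-threshold-cv-vs-GK1": SweepSpec(
            mode="independent-GK1", grid=tuple(gk1_grid()),
            measurements=("threshold", "cv"), **fiber),
        "lambda-vs-GNa": SweepSpec(
            mode="independent-GNa", grid=tuple(gna_grid()),
            measurements=("lambda",), **fiber),
        "lambda-vs-GK1": SweepSpec(
            mode="independent-GK1", grid=tuple(gk1_grid()),
            measurements=("lambda",), **fiber),
    }
    for a, b in RATIOS:
        specs[f"cell-threshold-reciprocal-{a}to{b}"] = SweepSpec(
            mode="reciprocal", ratio=(a, b), grid=tuple(gk1_grid()), **cell)
        specs[f"fiber-threshold-cv-reciprocal-{a}to{b}"] = SweepSpec(
            mode="reciprocal", ratio=(a, b), grid=tuple(gk1_grid()),
            measurements=("threshold", "cv"), **fiber)
    specs["fiber-reciprocal-1to1-vs-Ggj"] = SweepSpec(
        mode="reciprocal", ratio=(1, 1), grid=tuple(gk1_grid()),
        G_gj=GGJ_GRID, target="fiber", measurements=("threshold", "cv"))
    specs["lambda-reciprocal-1to1-vs-Ggj"] = SweepSpec(
        mode="reciprocal", ratio=(1, 1), grid=tuple(gk1_grid()),
        G_gj=GGJ_GRID, target="fiber", measurements=("lambda",))
    return specs
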