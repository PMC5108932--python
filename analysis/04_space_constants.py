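#!/usr/bin/env python
"""Passive space constants vs G_Na, G_K1 and G_gj.

Long (100 ms) subthreshold pulses let the fiber reach steady state; the
exponential decay length of the end-of-pulse voltage profile is the
space constant lambda (in 74 um cell lengths).  Expected: lambda is flat
in G_Na, falls as ~1/sqrt(G_K1), and rises as ~sqrt(G_gj) — the linear
cable-theory picture, which the passive-fixture oracles verify exactly.

A fixed -5 nA pulse is used for the G_Na and G_K1 comparisons (isolating
the conductance effect); the G_gj sweep uses the default per-point
95%-of-threshold amplitude.  Writes results/space_constants.csv.
Runtime: a few minutes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cardiofiber import CellParameters, FiberConfig, measure_space_constant

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for gna in (0.2, 0.5, 1.0, 2.0, 5.0):
    fit = measure_space_constant(
        FiberConfig(cell_params=CellParameters(G_Na=gna)), amplitude=-5.0)
    rows.append({"sweep": "vs-GNa", "G_Na": gna, "G_K1": 0.5, "G_gj": 10.0,
                 "lambda_cells": fit.lam_cells, "residual_mV": fit.residual_norm})
for gk1 in (0.3, 0.5, 0.75, 1.0, 1.5, 2.0):
    # -3 nA stays subthreshold down to G_K1 = 0.3 uS (low G_K1 lowers
    # the long-pulse rheobase)
    fit = measure_space_constant(
        FiberConfig(cell_params=CellParameters(G_K1=gk1)), amplitude=-3.0)
    rows.append({"sweep": "vs-GK1", "G_Na": 0.5, "G_K1": gk1, "G_gj": 10.0,
                 "lambda_cells": fit.lam_cells, "residual_mV": fit.residual_norm})
for ggj in (0.1, 0.5, 1.0, 5.0, 10.0, 20.0):
    fit = measure_space_constant(FiberConfig(G_gj=ggj))
    rows.append({"sweep": "vs-Ggj", "G_Na": 0.5, "G_K1": 0.5, "G_gj": ggj,
                 "lambda_cells": fit.lam_cells, "residual_mV": fit.residual_norm})

df = pd.DataFrame(rows)
df.to_csv(OUT / "space_constants.csv", index=False)

k1 = df[df.sweep == "vs-GK1"]
print("lambda vs GNa:", df[df.sweep == "vs-GNa"]["lambda_cells"].round(2).tolist())
print("lambda*sqrt(GK1):",
      (k1["lambda_cells"] * np.sqrt(k1["G_K1"])).round(2).tolist())
print("lambda vs Ggj:", df[df.sweep == "vs-Ggj"]["lambda_cells"].round(2).tolist())
print(f"wrote {OUT/'space_constants.csv'}")
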