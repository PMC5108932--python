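#!/usr/bin/env python
"""Baseline single-cell behaviour: resting state, threshold, one AP.

Establishes the default-parameter fingerprint of the cell model
(G_K1 = G_Na = 0.5 uS): resting potential, the stimulus threshold on the
0.5 nA grid, AP peak and APD90/APD50, and the I_K1/I_Na waveforms during
sub- and suprathreshold responses.  Writes results/single_cell_baseline.json
and a voltage/current trace table.

Runtime: well under a minute.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cardiofiber import (CellParameters, StimulusProtocol, currents,
                         find_cell_threshold, measure_apd, resting_state,
                         simulate)
from cardiofiber.cell_model import CellState

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = CellParameters()
rest = resting_state(params)
rest_currents = currents(rest, params)
thr = find_cell_threshold(params)
print(f"resting potential      {rest.V:8.2f} mV")
print(f"I_K1 at rest           {rest_currents.I_K1:8.3f} nA")
print(f"cell threshold         {thr.amplitude:8.1f} nA "
      f"({thr.n_simulations} simulations)")

# one suprathreshold and one just-subthreshold response
records, peaks = [], {}
for label, amp in [("suprathreshold", 1.5 * thr.amplitude),
                   ("subthreshold", thr.amplitude + thr.resolution)]:
    pr = StimulusProtocol(amplitude=amp, target_cells=(1,))
    tr = simulate(params, pr, (0.0, 600.0), y0=rest.vector.copy())
    peaks[label] = float(tr.cell(1).max())
    print(f"{label:15s} peak    {peaks[label]:8.2f} mV")
    if label == "suprathreshold":
        apd90 = measure_apd(tr, level=0.9, v_rest=rest.V)
        apd50 = measure_apd(tr, level=0.5, v_rest=rest.V)
        print(f"APD90 / APD50          {apd90:8.1f} / {apd50:.1f} ms")
    for t, v in zip(tr.t, tr.cell(1)):
        records.append({"case": label, "time_ms": round(float(t), 3),
                        "V_mV": round(float(v), 4)})

pd.DataFrame(records).to_csv(OUT / "single_cell_baseline_traces.csv",
                             index=False)
summary = {
    "V_rest_mV": rest.V, "I_K1_rest_nA": rest_currents.I_K1,
    "threshold_nA": thr.amplitude, "APD90_ms": apd90, "APD50_ms": apd50,
    "suprathreshold_peak_mV": peaks["suprathreshold"],
    "subthreshold_peak_mV": peaks["subthreshold"],
}
(OUT / "single_cell_baseline.json").write_text(json.dumps(summary, indent=1))
print(f"wrote {OUT/'single_cell_baseline.json'}")
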