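#!/usr/bin/env python
"""Fiber thresholds and conduction velocities; the excitability boundary.

Coarse 100-cell fiber sweeps at G_gj = 10 uS: threshold and CV vs G_Na,
vs G_K1 (locating the loss of excitability above G_K1 ~ 1.3 uS), and
under 1:1 reciprocal modulation (which keeps the fiber excitable far
beyond the independent boundary while CV *increases* with the tandem
conductance — the G_Na effect dominates conduction).

Writes results/fiber_threshold_cv.csv.  Runtime: ~10-20 minutes.
"""

from pathlib import Path

import pandas as pd

from cardiofiber import SweepSpec, run_sweep

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

specs = {
    "independent-GNa": SweepSpec(mode="independent-GNa",
                                 grid=(0.2, 0.5, 1.0, 2.0, 5.0),
                                 measurements=("threshold", "cv")),
    "independent-GK1": SweepSpec(mode="independent-GK1",
                                 grid=(0.3, 0.5, 0.8, 1.0, 1.2, 1.3, 1.4, 2.0),
                                 measurements=("threshold", "cv")),
    "reciprocal-1:1": SweepSpec(mode="reciprocal", ratio=(1, 1),
                                grid=(0.5, 1.0, 1.5, 2.5, 3.5, 5.0),
                                measurements=("threshold", "cv")),
}

frames = []
for name, spec in specs.items():
    df = run_sweep(spec, csv_path=OUT / f"fiber_{name.replace(':','to')}.csv",
                   progress=lambda r: print("  ", {k: r[k] for k in
                                                   ("G_K1", "G_Na",
                                                    "threshold_nA",
                                                    "inexcitable",
                                                    "cv_cm_s")}))
    df.insert(0, "sweep", name)
    frames.append(df)
    exc = df[~df["inexcitable"]]
    print(f"{name}: excitable at {len(exc)}/{len(df)} points; "
          f"CV range {exc['cv_cm_s'].min():.1f}-{exc['cv_cm_s'].max():.1f} cm/s")

pd.concat(frames).to_csv(OUT / "fiber_threshold_cv.csv", index=False)
print(f"wrote {OUT/'fiber_threshold_cv.csv'}")
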