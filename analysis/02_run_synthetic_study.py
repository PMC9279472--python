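#!/usr/bin/env python
"""Run the full synthetic loading study and recover the injected openings.

Generates 10 specimens x 5 graded-deficiency conditions x 2 loading
configurations with published-magnitude opening increments, measures every
volume on its baseline-anchored grid, and compares the recovered
condition-vs-intact contrasts with the injected truth.
Writes results/study/ (SCD tables, heat maps, statistics) and
results/recovered_contrasts.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from varusscd import PhantomSpec, StudyDesign
from varusscd.pipeline import RunConfig, run_study

OUT = Path("results")
OUT.mkdir(exist_ok=True)

design = StudyDesign(seed=1)
cfg = RunConfig(design=design,
                base_spec=PhantomSpec(gap_mm=8.7, condyle_radius_mm=30.0),
                seed=1, output_dir=str(OUT / "study"))
summary = run_study(cfg)
print(f"retained grid points per specimen: "
      f"{summary['retained_grid_points']['mean']:.0f}")

table = summary["table"]
wide = table[table.measure == "compmean"].pivot_table(
    index="specimen", columns=["condition", "configuration"],
    values="value_mm")

rows = []
for cond, inc, drift in zip(design.conditions, design.opening_increment_mm,
                            design.unloaded_drift_mm):
    d_lo = wide[(cond, "LO")] - wide[("intact", "LO")]
    d_ul = wide[(cond, "UL")] - wide[("intact", "UL")]
    rows.append({"condition": cond,
                 "recovered_loaded_mm": d_lo.mean(),
                 "injected_loaded_mm": inc,
                 "se_mm": d_lo.std(ddof=1) / np.sqrt(len(d_lo)),
                 "recovered_unloaded_mm": d_ul.mean(),
                 "injected_unloaded_mm": drift})
rec = pd.DataFrame(rows)
rec.to_csv(OUT / "recovered_contrasts.csv", index=False)
print(rec.round(3).to_string(index=False))

ok = (np.abs(rec.recovered_loaded_mm - rec.injected_loaded_mm)
      <= 2 * rec.se_mm.replace(0, np.inf))
print(f"\nloaded contrasts within 2 SE of injection: {int(ok.sum())}/{len(ok)}")
print(summary["anova"].effects.round(4).to_string(index=False))
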