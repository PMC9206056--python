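#!/usr/bin/env python
"""Score every diary night sleep/wake and derive the per-night variables.

Reads the simulated cohort from scratch/cohort/, applies the weighted
medium-sensitivity rule (threshold 40), and writes one row per valid
athlete-night to scratch/nights.csv plus a per-night-variable median (IQR)
summary to results/night_variable_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import somnoreg as sr

ROOT = Path(__file__).resolve().parents[1]

VARIABLES = [
    "bedtime_min",
    "onset_min",
    "offset_min",
    "midpoint_min",
    "sleep_period_h",
    "total_sleep_time_h",
    "sleep_efficiency_pct",
    "sleep_onset_latency_min",
]

if __name__ == "__main__":
    timelines = sr.read_epoch_table(ROOT / "scratch" / "cohort" / "epochs.csv")
    diaries = sr.read_diary_table(ROOT / "scratch" / "cohort" / "diary.csv")
    _, nights = sr.score_cohort(timelines, diaries)
    nights.to_csv(ROOT / "scratch" / "nights.csv", index=False)

    rows = []
    for var in VARIABLES:
        med, q1, q3 = np.percentile(nights[var], [50, 25, 75])
        rows.append({"variable": var, "median": med, "q1": q1, "q3": q3})
    summary = pd.DataFrame(rows)
    out = ROOT / "results" / "night_variable_summary.csv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, index=False, float_format="%.2f")
    print(f"scored {len(nights)} valid nights from {len(diaries)} diary entries")
    print(summary.to_string(index=False))
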