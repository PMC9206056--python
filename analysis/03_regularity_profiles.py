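#!/usr/bin/env python
"""Per-athlete profiles: SRI, medians, MADs, night-to-night variation.

Builds athlete aggregates from the scored nights, computes each athlete's
SRI over their longest whole number of weeks, classifies the top/bottom
SRI quintiles as regular/irregular sleepers, and writes
scratch/profiles.csv plus a cohort-level summary to
results/profile_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import somnoreg as sr
from somnoreg.sleep_scoring import NightSummary

ROOT = Path(__file__).resolve().parents[1]


def summaries_from_frame(nights: pd.DataFrame) -> list[NightSummary]:
    nights = nights.copy()
    nights["anchor"] = pd.to_datetime(nights["anchor"])
    return [NightSummary(**row) for row in nights.to_dict("records")]


if __name__ == "__main__":
    nights = pd.read_csv(ROOT / "scratch" / "nights.csv")
    profiles = sr.build_profiles(summaries_from_frame(nights))
    profiles.to_csv(ROOT / "scratch" / "profiles.csv", index=False)

    rows = []
    for col in [
        "sri", "med_bedtime_min", "med_onset_min", "med_offset_min",
        "med_tst_h", "med_eff_pct", "med_sol_min",
        "mad_onset_min", "mad_offset_min",
        "var_onset_min", "var_offset_min", "var_tst_min", "var_eff_pct",
    ]:
        med, q1, q3 = np.percentile(profiles[col].dropna(), [50, 25, 75])
        rows.append({"variable": col, "median": med, "q1": q1, "q3": q3})
    summary = pd.DataFrame(rows)
    summary.to_csv(
        ROOT / "results" / "profile_summary.csv", index=False,
        float_format="%.2f",
    )
    counts = profiles["regularity_class"].value_counts()
    print(f"profiles for {len(profiles)} athletes")
    print(
        f"regular sleepers (top SRI quintile): {counts.get('regular', 0)}; "
        f"irregular (bottom quintile): {counts.get('irregular', 0)}"
    )
    print(summary.to_string(index=False))
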