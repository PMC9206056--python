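#!/usr/bin/env python
"""Compare sleep characteristics between regular and irregular sleepers.

For each sleep variable: entire-group and per-group median (IQR), the
two-sided Wilcoxon rank-sum p value, and the effect size r with a
bootstrap 95% CI and magnitude label.  Writes
results/group_comparison.csv.
"""

from pathlib import Path

import pandas as pd

import somnoreg as sr

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    profiles = pd.read_csv(ROOT / "scratch" / "profiles.csv")
    table = sr.compare_groups(profiles, sr.TABLE_VARIABLES, seed=7)
    table.to_csv(
        ROOT / "results" / "group_comparison.csv", index=False,
        float_format="%.4f",
    )
    for _, row in table.iterrows():
        flag = "*" if row["significant"] else " "
        print(
            f"{row['variable']:40s} p={row['p_value']:.3f}{flag} "
            f"r={row['effect_size_r']:+.2f} "
            f"({row['ci_low']:+.2f} to {row['ci_high']:+.2f}); "
            f"{row['magnitude']}"
        )
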