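#!/usr/bin/env python
"""Simulate the study cohort: ~200 athletes, 7+ nights of 1-min actigraphy.

Writes the raw epoch/diary/ground-truth CSVs under scratch/cohort/ (large
files, not part of the deliverable) and prints the cohort's shape.
"""

from pathlib import Path

import somnoreg as sr

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"

if __name__ == "__main__":
    cfg = sr.GeneratorConfig(seed=7)
    cohort = sr.generate_cohort(cfg)
    sr.write_cohort(cohort, OUT)
    nights = len(cohort.diaries)
    print(f"simulated {len(cohort.timelines)} athletes, {nights} diary nights")
    print(f"nights per athlete: {nights / len(cohort.timelines):.1f} on average")
    print(f"wrote epochs/diary/ground-truth CSVs to {OUT}")
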