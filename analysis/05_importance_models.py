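#!/usr/bin/env python
"""Variable-importance models for total sleep time and sleep efficiency.

80/20 split, VIF >= 10 collinearity filter, tenfold cross-validation with
5 repeats, final OLS fit, held-out R^2 and range-normalised RMSE, and
scaled-|t| importance.  Writes results/model_<outcome>.json and importance
bar plots under scratch/figures/.
"""

from pathlib import Path

import pandas as pd

import somnoreg as sr
from somnoreg.importance_models import ModelSpec, fit_importance_model

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    profiles = pd.read_csv(ROOT / "scratch" / "profiles.csv")
    figdir = ROOT / "scratch" / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    for outcome in ("total_sleep_time", "sleep_efficiency"):
        report = fit_importance_model(
            profiles, ModelSpec(outcome=outcome, seed=7)
        )
        out = ROOT / "results" / f"model_{outcome}.json"
        out.write_text(report.to_json() + "\n")
        ranked = sorted(
            report.importance.items(), key=lambda kv: -kv[1]
        )
        print(f"\n{outcome}:")
        print(
            f"  train R^2 = {report.r2_train:.2f}, CV R^2 = {report.cv_r2:.2f}, "
            f"test R^2 = {report.r2_test:.2f}, NRMSE = "
            f"{report.nrmse_test_percent:.1f}%"
        )
        print(f"  removed by VIF filter: {list(report.removed_predictors)}")
        print("  importance:", ", ".join(f"{k}={v:.0f}" for k, v in ranked))

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names, scores = zip(*sorted(report.importance.items(), key=lambda kv: kv[1]))
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1.2))
        ax.barh(names, scores)
        ax.set_xlabel("importance (scaled |t|)")
        ax.set_title(outcome)
        fig.tight_layout()
        fig.savefig(figdir / f"importance_{outcome}.png", dpi=120)
        plt.close(fig)
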