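"""Descriptive summaries and regular-vs-irregular group comparisons.

Distributions of sleep variables are skewed, so location and spread are
reported as median and interquartile range throughout.  Group differences
use the two-sided Wilcoxon rank-sum (Mann-Whitney) test; magnitudes are
expressed as the effect size r = z / sqrt(n) with a percentile-bootstrap
95% CI, labelled trivial (|r| <= 0.10), small (<= 0.3), medium (<= 0.5)
or large (> 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("somnoreg")

#: |r| upper bounds for each magnitude label (checked in order).
MAGNITUDE_THRESHOLDS = (("trivial", 0.10), ("small", 0.3), ("medium", 0.5))

#: Largest per-group size for which the exact null distribution is used.
EXACT_MAX_N = 8


def magnitude_label(r: float) -> str:
    """Magnitude label for an effect size r (applied to |r|)."""
    a = abs(r)
    for label, bound in MAGNITUDE_THRESHOLDS:
        if a <= bound:
            return label
    return "large"


def summarize_groups(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and interquartile range (25th, 75th; linear interpolation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty group")
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    z: float


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected, continuity-corrected normal z for the rank-sum test.

    Positive z means the first sample tends to be larger.
    """
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return 0.0
    diff = u_a - mu
    cc = 0.5 * np.sign(diff)
    return float((diff - cc) / np.sqrt(var))


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    The z statistic always comes from the tie- and continuity-corrected
    normal approximation (it also feeds the effect size).  The p value is
    taken from exact enumeration of rank assignments when both groups have
    at most 8 observations and there are no ties, and from the normal
    approximation otherwise.  Two identical samples give p = 1, z = 0.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    z = _rank_sum_z(x, y)
    if z == 0.0 and np.unique(np.concatenate([x, y])).size == 1:
        return WilcoxonResult(p_value=1.0, z=0.0)
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(p_value=p, z=z)


@dataclass(frozen=True)
class EffectSize:
    r: float
    ci_low: float
    ci_high: float
    label: str


def effect_size_r(
    a: Sequence[float],
    b: Sequence[float],
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> EffectSize:
    """Rank-sum effect size r = z / sqrt(n_a + n_b) with bootstrap 95% CI.

    Positive r means the first group tends to be larger.  The CI is a
    percentile bootstrap over resampling athletes within each group
    (seeded), widened if necessary to bracket the point estimate (this
    only matters for saturated effects, where resampling ties shift the
    tie-corrected z).  A degenerate bootstrap (all resampled r identical)
    collapses the CI to a point and logs a warning.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    n = x.size + y.size
    r = _rank_sum_z(x, y) / np.sqrt(n)
    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_reps)
    for k in range(bootstrap_reps):
        xs = x[rng.integers(0, x.size, x.size)]
        ys = y[rng.integers(0, y.size, y.size)]
        boot[k] = _rank_sum_z(xs, ys) / np.sqrt(n)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(lo, r), max(hi, r)
    if lo == hi:
        logger.warning("degenerate bootstrap: CI collapsed to a point")
    return EffectSize(
        r=float(r), ci_low=float(lo), ci_high=float(hi), label=magnitude_label(r)
    )


def compare_groups(
    profiles: pd.DataFrame,
    variables: Mapping[str, str],
    group_col: str = "regularity_class",
    bootstrap_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cohort-description table: entire group and regular vs irregular.

    ``variables`` maps display names to profile columns.  Each row carries
    the entire-group and per-group median (IQR), the rank-sum p value, the
    effect size r with 95% CI and magnitude label (regular relative to
    irregular), and a significance flag at ``p < alpha``.
    """
    reg = profiles[profiles[group_col] == "regular"]
    irr = profiles[profiles[group_col] == "irregular"]
    if reg.empty or irr.empty:
        raise ValueError("both a regular and an irregular group are required")
    rows = []
    for display, col in variables.items():
        entire = profiles[col].dropna().to_numpy()
        a = reg[col].dropna().to_numpy()
        b = irr[col].dropna().to_numpy()
        med_all, q1_all, q3_all = summarize_groups(entire)
        med_r, q1_r, q3_r = summarize_groups(a)
        med_i, q1_i, q3_i = summarize_groups(b)
        test = wilcoxon_rank_sum(a, b)
        es = effect_size_r(a, b, bootstrap_reps=bootstrap_reps, seed=seed)
        rows.append(
            {
                "variable": display,
                "entire_median": med_all,
                "entire_q1": q1_all,
                "entire_q3": q3_all,
                "regular_median": med_r,
                "regular_q1": q1_r,
                "regular_q3": q3_r,
                "irregular_median": med_i,
                "irregular_q1": q1_i,
                "irregular_q3": q3_i,
                "p_value": test.p_value,
                "effect_size_r": es.r,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "magnitude": es.label,
                "significant": test.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
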