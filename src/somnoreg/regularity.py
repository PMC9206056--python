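"""Sleep Regularity Index, intraindividual variability, and classification.

The Sleep Regularity Index (SRI) measures how likely an individual is to be
in the same sleep/wake state at clock times 24 h apart.  With days
``i = 1..N`` of ``M`` one-minute epochs and binary states ``s[i, j]``,

    SRI = -100 + 200 / (M (N - 1)) * sum_{i=1}^{N-1} sum_{j=1}^{M}
          delta(s[i, j], s[i+1, j])

i.e. -100 + 200 f where f is the fraction of 24-h-apart epoch pairs that
agree.  100 means an identical schedule every day; the index can be
negative (fully anti-phased half-day sleep gives -100).  The state vector
is built from sleep onset and offset only: wake after sleep onset and
daytime naps are not represented, so only diurnal shifts of the sleep
window move the score.

The index is computed over the longest whole number of weeks available
(first 7k days; a minimum of 7 days is required).  Epoch pairs with a
missing member are dropped from numerator and denominator alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sleep_scoring import NightSummary
from .timegrid_io import MINUTES_PER_DAY, minutes_since

logger = logging.getLogger("somnoreg")

WAKE = 0
SLEEP = 1
MISSING = -1

MIN_DAYS = 7
MIN_ATHLETES_FOR_QUINTILES = 5


@dataclass
class StateVector:
    """Per-minute sleep/wake/missing states on noon-anchored days."""

    athlete_id: str
    states: np.ndarray  # int8, length n_days * 1440
    start_noon: pd.Timestamp

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.size % MINUTES_PER_DAY:
            raise ValueError(
                f"state vector length {self.states.size} is not a whole "
                f"number of {MINUTES_PER_DAY}-min days"
            )

    @property
    def n_days(self) -> int:
        return self.states.size // MINUTES_PER_DAY


def build_state_vector(
    nights: Iterable[NightSummary],
    start_noon: pd.Timestamp | None = None,
    n_days: int | None = None,
    missing_epoch_policy: str = "wake",
    athlete_id: str | None = None,
) -> StateVector:
    """Rasterise sleep intervals onto the per-minute noon-anchored grid.

    Sleep epochs are exactly the minutes inside ``[onset, offset)`` of each
    valid night; everything else is wake, except that under
    ``missing_epoch_policy='mask'`` whole days without a valid night are
    marked missing instead of wake.  Overlapping sleep intervals raise.
    """
    if missing_epoch_policy not in ("wake", "mask"):
        raise ValueError(
            f"missing_epoch_policy must be 'wake' or 'mask', "
            f"got {missing_epoch_policy!r}"
        )
    nights = sorted(nights, key=lambda n: n.anchor)
    if athlete_id is None:
        athlete_id = nights[0].athlete_id if nights else "unknown"
    if start_noon is None:
        if not nights:
            raise ValueError("no nights and no explicit span given")
        start_noon = nights[0].anchor
    start_noon = pd.Timestamp(start_noon)
    if n_days is None:
        if not nights:
            raise ValueError("no nights and no explicit span given")
        n_days = int(minutes_since(start_noon, nights[-1].anchor)) // MINUTES_PER_DAY + 1

    states = np.full(n_days * MINUTES_PER_DAY, WAKE, dtype=np.int8)
    if missing_epoch_policy == "mask":
        covered = np.zeros(n_days, dtype=bool)
        for night in nights:
            day = int(round(minutes_since(start_noon, night.anchor))) // MINUTES_PER_DAY
            if 0 <= day < n_days:
                covered[day] = True
        for day in np.nonzero(~covered)[0]:
            states[day * MINUTES_PER_DAY : (day + 1) * MINUTES_PER_DAY] = MISSING

    if not nights:
        logger.warning(
            "athlete %s: no valid nights; state vector is all wake", athlete_id
        )
    for night in nights:
        s = int(round(minutes_since(start_noon, night.onset_time)))
        e = int(round(minutes_since(start_noon, night.offset_time)))
        s, e = max(s, 0), min(e, states.size)
        if e <= s:
            continue
        if (states[s:e] == SLEEP).any():
            raise ValueError(
                f"athlete {athlete_id}: overlapping sleep intervals at "
                f"night {night.night_index}"
            )
        states[s:e] = SLEEP
    return StateVector(athlete_id=athlete_id, states=states, start_noon=start_noon)


def truncate_whole_weeks(v: StateVector) -> StateVector:
    """Keep the first ``7 * floor(days / 7)`` days (longest whole weeks)."""
    if v.n_days < MIN_DAYS:
        raise ValueError(
            f"athlete {v.athlete_id}: {v.n_days} days available; the index "
            f"requires a minimum of {MIN_DAYS} nights"
        )
    keep = 7 * (v.n_days // 7)
    return StateVector(
        athlete_id=v.athlete_id,
        states=v.states[: keep * MINUTES_PER_DAY].copy(),
        start_noon=v.start_noon,
    )


def sri(v: StateVector | np.ndarray) -> float:
    """Sleep Regularity Index in ``[-100, 100]``.

    Mask-aware: epoch pairs 24 h apart with a missing member are dropped
    from both numerator and denominator.  With no missing epochs this is
    exactly the double sum over ``delta(s[i, j], s[i+1, j])`` for
    ``i = 1..N-1`` normalised by ``M (N - 1)``.
    """
    states = v.states if isinstance(v, StateVector) else np.asarray(v, np.int8)
    if states.size < 2 * MINUTES_PER_DAY:
        raise ValueError("SRI needs at least 2 days (N >= 2)")
    a = states[:-MINUTES_PER_DAY]
    b = states[MINUTES_PER_DAY:]
    ok = (a != MISSING) & (b != MISSING)
    n_pairs = int(ok.sum())
    if n_pairs == 0:
        raise ValueError("SRI undefined: every 24-h epoch pair has a missing member")
    f = float((a[ok] == b[ok]).mean())
    return -100.0 + 200.0 * f


def mad_clock(values: Sequence[float]) -> float:
    """Median absolute deviation from the individual's own median.

    Used on noon-referenced clock minutes (onset, offset, bedtime,
    midpoint) and, on their natural scales, on duration/efficiency series.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("MAD needs at least 2 values")
    return float(np.median(np.abs(x - np.median(x))))


def night_to_night_variation(
    values: Sequence[float],
    night_indices: Sequence[int] | None = None,
    aggregate: str = "median",
) -> float:
    """Median (or mean) absolute difference to the previous night.

    Pairs are formed only between consecutive nights (indices differing by
    1); e.g. onset 22:00 one night and 21:30 the next is a variation of
    30 min.  Returns NaN (and logs) when no consecutive pair exists.
    """
    x = np.asarray(values, dtype=float)
    if night_indices is None:
        idx = np.arange(1, x.size + 1)
    else:
        idx = np.asarray(night_indices)
        order = np.argsort(idx)
        idx, x = idx[order], x[order]
    consecutive = np.diff(idx) == 1
    diffs = np.abs(np.diff(x))[consecutive]
    if diffs.size == 0:
        logger.warning("no consecutive night pair; variation aggregate missing")
        return float("nan")
    if aggregate == "median":
        return float(np.median(diffs))
    if aggregate == "mean":
        return float(np.mean(diffs))
    raise ValueError(f"aggregate must be 'median' or 'mean', got {aggregate!r}")


def classify_quintiles(
    sri_by_athlete: Mapping[str, float], tie_policy: str = "inclusive"
) -> dict[str, str]:
    """Label athletes regular / irregular / middle by SRI quintile.

    Regular = top quintile (SRI at or above the empirical 80th percentile),
    irregular = bottom quintile.  Under the default inclusive policy,
    boundary ties join the extreme group (which is how the groups can end
    up unequal); 'exclusive' uses strict inequalities.  A degenerate cohort
    in which an athlete would fall in both extremes raises and asks for an
    explicit policy override.
    """
    if tie_policy not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown quintile_tie_policy {tie_policy!r}")
    ids = list(sri_by_athlete)
    if len(ids) < MIN_ATHLETES_FOR_QUINTILES:
        raise ValueError(
            f"quintile classification needs at least "
            f"{MIN_ATHLETES_FOR_QUINTILES} athletes, got {len(ids)}"
        )
    scores = np.array([sri_by_athlete[a] for a in ids], dtype=float)
    q20, q80 = np.quantile(scores, [0.2, 0.8])
    if tie_policy == "inclusive":
        regular = scores >= q80
        irregular = scores <= q20
    else:
        regular = scores > q80
        irregular = scores < q20
    if (regular & irregular).any():
        raise ValueError(
            "degenerate SRI distribution: some athletes tie into both "
            "quintile boundaries; rerun with an explicit "
            "quintile_tie_policy='exclusive' override"
        )
    out = {}
    for a, reg, irr in zip(ids, regular, irregular):
        out[a] = "regular" if reg else ("irregular" if irr else "middle")
    return out
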