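"""Actigraphy sleep/wake scoring and per-night sleep variables.

The scorer follows the standard wrist-actigraph rule: all time is wake
unless (i) the diary says the athlete was in bed attempting sleep and
(ii) the weighted activity score of the epoch is at or below the
sensitivity threshold (medium sensitivity = 40 counts).  The weighted
score for 1-min epochs is the published five-epoch window

    score(i) = 0.04 c[i-2] + 0.2 c[i-1] + 1.0 c[i] + 0.2 c[i+1] + 0.04 c[i+2]

with out-of-range neighbours treated as zero.  Ties score sleep.

From the scored window eight per-night variables are derived: bedtime,
sleep onset (first fall-asleep after bed), sleep offset (last wake before
get-up), sleep period (onset to offset), total sleep time (sleep-scored
minutes inside the period), sleep efficiency (TST as % of period), sleep
midpoint, and sleep onset latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .timegrid_io import (
    EPOCH_SECONDS,
    DiaryNight,
    EpochTimeline,
    minutes_since,
    noon_anchor,
)

logger = logging.getLogger("somnoreg")

#: Five-epoch weighting for 1-min epochs (symmetric).
WEIGHT_KERNEL = np.array([0.04, 0.2, 1.0, 0.2, 0.04])

#: Named sensitivity presets (threshold activity counts).
SENSITIVITY_PRESETS = {"low": 80, "medium": 40, "high": 20}
DEFAULT_THRESHOLD = SENSITIVITY_PRESETS["medium"]

#: Nights with more than this fraction of invalid epochs in the diary
#: window are flagged invalid and excluded from aggregates.
DEFAULT_MAX_INVALID_FRACTION = 0.1


def epoch_activity_score(
    counts: Sequence[float], i: int, weighted: bool = True
) -> float:
    """Weighted activity score of epoch ``i`` (scalar convenience form)."""
    c = np.asarray(counts, dtype=float)
    if not 0 <= i < c.size:
        raise IndexError(f"epoch index {i} outside [0, {c.size})")
    if not weighted:
        return float(c[i])
    total = 0.0
    for offset, w in zip((-2, -1, 0, 1, 2), WEIGHT_KERNEL):
        j = i + offset
        if 0 <= j < c.size:
            total += w * c[j]
    return float(total)


def epoch_activity_scores(counts: np.ndarray, weighted: bool = True) -> np.ndarray:
    """Vectorised weighted scores for a whole count sequence."""
    c = np.asarray(counts, dtype=float)
    if not weighted:
        return c.copy()
    # symmetric kernel: correlation == convolution; 'same' zero-pads edges
    return np.convolve(c, WEIGHT_KERNEL, mode="same")


@dataclass
class ScoredNight:
    """Per-epoch sleep flags for the diary window of one night."""

    athlete_id: str
    night_index: int
    bed_time: pd.Timestamp
    getup_time: pd.Timestamp
    window_start: pd.Timestamp  # start of the first epoch in the window
    flags: np.ndarray  # True = sleep-scored, one per window epoch
    invalid_fraction: float
    sensitivity_threshold: float
    is_valid: bool

    @property
    def anchor(self) -> pd.Timestamp:
        return noon_anchor(self.bed_time)

    @property
    def n_sleep_epochs(self) -> int:
        return int(self.flags.sum())


def score_sleep_wake(
    timeline: EpochTimeline,
    night: DiaryNight,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    weighted: bool = True,
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION,
    scores: np.ndarray | None = None,
) -> ScoredNight:
    """Score each epoch of a diary window sleep/wake.

    An epoch is sleep iff it lies inside ``[bed_time, getup_time)``, its
    validity mask is set, and its weighted activity score is <= threshold.
    ``scores`` may carry precomputed :func:`epoch_activity_scores` for the
    whole timeline (used by the cohort pipeline to avoid recomputation).

    Raises ``ValueError`` if the diary window is not fully covered by the
    timeline.  Nights whose window has more than ``max_invalid_fraction``
    invalid epochs, or no sleep-scored epoch at all, come back with
    ``is_valid=False``.
    """
    if not timeline.covers(night.bed_time, night.getup_time):
        raise ValueError(
            f"diary window {night.bed_time}..{night.getup_time} for athlete "
            f"{night.athlete_id!r} is not covered by the timeline "
            f"({timeline.start}..{timeline.end})"
        )
    # window epochs = epochs whose start lies in [bed, getup)
    i0 = int(
        np.ceil(
            (night.bed_time - timeline.start).total_seconds() / EPOCH_SECONDS
        )
    )
    i1 = int(
        np.ceil(
            (night.getup_time - timeline.start).total_seconds() / EPOCH_SECONDS
        )
    )
    i0, i1 = max(i0, 0), min(i1, timeline.n_epochs)
    if i1 <= i0:
        raise ValueError("diary window contains no whole epoch")
    if scores is None:
        scores = epoch_activity_scores(timeline.counts, weighted=weighted)
    window_scores = scores[i0:i1]
    window_valid = timeline.valid[i0:i1]
    flags = (window_scores <= threshold) & window_valid
    invalid_fraction = float(1.0 - window_valid.mean())
    is_valid = bool(invalid_fraction <= max_invalid_fraction and flags.any())
    if not flags.any():
        logger.warning(
            "athlete %s night %d: no sleep-scored epoch in window; "
            "night flagged invalid",
            night.athlete_id,
            night.night_index,
        )
    return ScoredNight(
        athlete_id=night.athlete_id,
        night_index=night.night_index,
        bed_time=night.bed_time,
        getup_time=night.getup_time,
        window_start=timeline.start + pd.Timedelta(seconds=i0 * EPOCH_SECONDS),
        flags=flags,
        invalid_fraction=invalid_fraction,
        sensitivity_threshold=float(threshold),
        is_valid=is_valid,
    )


@dataclass
class NightSummary:
    """The eight per-night sleep variables, noon-referenced.

    Clock quantities (``*_min``) are minutes from the noon preceding the
    night; durations are hours (period, TST) or minutes (latency);
    efficiency is a percentage.
    """

    athlete_id: str
    night_index: int
    anchor: pd.Timestamp
    bedtime_min: float
    onset_min: float
    offset_min: float
    midpoint_min: float
    sleep_period_h: float
    total_sleep_time_h: float
    sleep_efficiency_pct: float
    sleep_onset_latency_min: float

    @property
    def onset_time(self) -> pd.Timestamp:
        return self.anchor + pd.Timedelta(minutes=self.onset_min)

    @property
    def offset_time(self) -> pd.Timestamp:
        return self.anchor + pd.Timedelta(minutes=self.offset_min)


def _first_run_start(flags: np.ndarray, k: int) -> int | None:
    """Index of the first run of >= k consecutive True values, else None."""
    if k <= 1:
        idx = np.nonzero(flags)[0]
        return int(idx[0]) if idx.size else None
    window = np.convolve(flags.astype(int), np.ones(k, dtype=int), "valid")
    idx = np.nonzero(window == k)[0]
    return int(idx[0]) if idx.size else None


def summarize_night(
    scored: ScoredNight, onset_consecutive_epochs: int = 1
) -> NightSummary | None:
    """Derive the eight per-night variables from a scored night.

    Onset is the start of the first run of ``onset_consecutive_epochs``
    sleep-scored epochs after bedtime (default 1: the first epoch scored
    asleep); offset is, symmetrically, the end of the last such run before
    get-up.  Returns ``None`` for invalid nights (no sleep epoch, or too
    much invalid wear time), which are excluded from aggregates.
    """
    if not scored.is_valid:
        logger.info(
            "athlete %s night %d excluded (invalid fraction %.2f, "
            "%d sleep epochs)",
            scored.athlete_id,
            scored.night_index,
            scored.invalid_fraction,
            scored.n_sleep_epochs,
        )
        return None
    k = int(onset_consecutive_epochs)
    onset_idx = _first_run_start(scored.flags, k)
    tail = _first_run_start(scored.flags[::-1], k)
    if onset_idx is None or tail is None:
        logger.info(
            "athlete %s night %d excluded (no run of %d consecutive "
            "sleep epochs)",
            scored.athlete_id,
            scored.night_index,
            k,
        )
        return None
    offset_idx = scored.flags.size - tail  # exclusive end of last run

    anchor = scored.anchor
    window_start_min = minutes_since(anchor, scored.window_start)
    bedtime_min = minutes_since(anchor, scored.bed_time)
    onset_min = window_start_min + onset_idx
    offset_min = window_start_min + offset_idx
    period_min = offset_min - onset_min
    tst_min = float(scored.flags[onset_idx:offset_idx].sum())
    return NightSummary(
        athlete_id=scored.athlete_id,
        night_index=scored.night_index,
        anchor=anchor,
        bedtime_min=bedtime_min,
        onset_min=onset_min,
        offset_min=offset_min,
        midpoint_min=onset_min + period_min / 2.0,
        sleep_period_h=period_min / 60.0,
        total_sleep_time_h=tst_min / 60.0,
        sleep_efficiency_pct=100.0 * tst_min / period_min,
        sleep_onset_latency_min=onset_min - bedtime_min,
    )


def nights_to_frame(nights: Sequence[NightSummary]) -> pd.DataFrame:
    """Tabulate night summaries (one row per athlete-night)."""
    return pd.DataFrame(
        {
            "athlete_id": [n.athlete_id for n in nights],
            "night_index": [n.night_index for n in nights],
            "anchor": [n.anchor for n in nights],
            "bedtime_min": [n.bedtime_min for n in nights],
            "onset_min": [n.onset_min for n in nights],
            "offset_min": [n.offset_min for n in nights],
            "midpoint_min": [n.midpoint_min for n in nights],
            "sleep_period_h": [n.sleep_period_h for n in nights],
            "total_sleep_time_h": [n.total_sleep_time_h for n in nights],
            "sleep_efficiency_pct": [n.sleep_efficiency_pct for n in nights],
            "sleep_onset_latency_min": [
                n.sleep_onset_latency_min for n in nights
            ],
        }
    )
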