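"""Epoch-grid and diary data model plus delimited-table readers/writers.

Time conventions
----------------
Everything runs on a contiguous one-minute grid of activity counts per
athlete.  Missing wear time is represented by an explicit per-epoch validity
mask, never by absent rows.  Epochs are half-open intervals ``[t, t + 60 s)``;
a timestamp belongs to the epoch that contains it.

Clock-time summaries (bedtime, onset, offset, midpoint medians and their
MADs) are expressed in *minutes from the most recent 12:00 noon*, so an
entire night of sleep lies inside one "day" and no statistic has to cope
with the midnight wraparound.  Bedtime 23:00 maps to 660; 00:30 maps to 750.

Timestamps are naive local clock time.  Timezone-aware inputs (and with
them daylight-saving transitions) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("somnoreg")

EPOCH_SECONDS = 60
MINUTES_PER_DAY = 1440
NOON_MINUTE = 720
#: Diary windows longer than this are rejected as implausible night sleep.
MAX_WINDOW_HOURS = 18.0


class TableFormatError(ValueError):
    """A delimited input table violates the epoch/diary file contract."""


def _check_naive(t: pd.Timestamp, context: str) -> pd.Timestamp:
    t = pd.Timestamp(t)
    if t.tzinfo is not None:
        raise TableFormatError(
            f"{context}: timezone-aware timestamp {t!r}; this pipeline runs on "
            "naive local clock time (daylight-saving transitions unsupported)"
        )
    return t


@dataclass
class EpochTimeline:
    """Contiguous 1-min grid of non-negative activity counts for one athlete.

    ``valid`` marks epochs usable for scoring (False = off-wrist / missing).
    """

    athlete_id: str
    start: pd.Timestamp
    counts: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError(
                f"epoch_seconds must be {EPOCH_SECONDS} (1-min epochs); "
                f"got {self.epoch_seconds}"
            )
        self.start = _check_naive(self.start, f"timeline {self.athlete_id!r}")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise ValueError(
                f"timeline {self.athlete_id!r}: negative count at epoch {bad}"
            )
        if self.valid is None:
            self.valid = np.ones(self.counts.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.counts.shape:
                raise ValueError("valid mask must match counts length")

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def end(self) -> pd.Timestamp:
        """Exclusive end of the grid."""
        return self.start + pd.Timedelta(seconds=self.n_epochs * EPOCH_SECONDS)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_epochs, freq="60s")

    def index_of(self, t: pd.Timestamp) -> int:
        """Index of the epoch containing ``t`` (epochs are ``[t, t+60 s)``)."""
        delta = (pd.Timestamp(t) - self.start).total_seconds()
        return int(np.floor(delta / EPOCH_SECONDS))

    def covers(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return pd.Timestamp(start) >= self.start and pd.Timestamp(end) <= self.end


@dataclass(frozen=True)
class DiaryNight:
    """One attempted-sleep window from the diary: bed time to get-up time."""

    athlete_id: str
    night_index: int
    bed_time: pd.Timestamp
    getup_time: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bed_time", _check_naive(self.bed_time, "diary bed_time")
        )
        object.__setattr__(
            self, "getup_time", _check_naive(self.getup_time, "diary getup_time")
        )
        if not self.bed_time < self.getup_time:
            raise ValueError(
                f"diary window for {self.athlete_id!r}: bed_time "
                f"{self.bed_time} must precede getup_time {self.getup_time}"
            )
        hours = (self.getup_time - self.bed_time).total_seconds() / 3600.0
        if hours >= MAX_WINDOW_HOURS:
            raise ValueError(
                f"diary window for {self.athlete_id!r} night {self.night_index} "
                f"is {hours:.1f} h; windows must be shorter than "
                f"{MAX_WINDOW_HOURS:g} h"
            )

    @property
    def window_minutes(self) -> float:
        return (self.getup_time - self.bed_time).total_seconds() / 60.0

    @property
    def anchor(self) -> pd.Timestamp:
        """Noon preceding the night (defines the noon-to-noon day it lives in)."""
        return noon_anchor(self.bed_time)


def noon_anchor(t: pd.Timestamp) -> pd.Timestamp:
    """The most recent 12:00 noon at or before ``t``."""
    t = pd.Timestamp(t)
    midnight = t.normalize()
    noon = midnight + pd.Timedelta(hours=12)
    return noon if t >= noon else noon - pd.Timedelta(hours=24)


def to_clock_minutes(t: pd.Timestamp) -> float:
    """Minutes since the most recent 12:00 noon, in ``[0, 1440)``.

    Strictly monotone within a noon-to-noon day, so medians of night-time
    events never straddle a wrap point.
    """
    t = pd.Timestamp(t)
    frac = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    return (frac - NOON_MINUTE) % MINUTES_PER_DAY


def minutes_since(anchor: pd.Timestamp, t: pd.Timestamp) -> float:
    """Signed minutes from ``anchor`` to ``t`` (noon-referenced, unwrapped)."""
    return (pd.Timestamp(t) - pd.Timestamp(anchor)).total_seconds() / 60.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def read_epoch_table(path: str | Path) -> dict[str, EpochTimeline]:
    """Read an epoch file into one :class:`EpochTimeline` per athlete.

    Expected header: ``athlete_id,timestamp,counts[,valid]`` with ISO-8601
    timestamps, one row per minute, strictly increasing at 60-s steps per
    athlete.  Gaps, non-monotone timestamps and negative counts raise
    :class:`TableFormatError` naming the offending row.
    """
    df = _read_table(path)
    required = {"athlete_id", "timestamp", "counts"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: epoch table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out: dict[str, EpochTimeline] = {}
    for athlete_id, sub in df.groupby("athlete_id", sort=True):
        ts = sub["timestamp"].to_numpy()
        steps = np.diff(ts).astype("timedelta64[s]").astype(np.int64)
        bad = np.nonzero(steps != EPOCH_SECONDS)[0]
        if bad.size:
            i = int(bad[0])
            raise TableFormatError(
                f"{path}: athlete {athlete_id!r} has a non-60-s step at "
                f"timestamp {pd.Timestamp(ts[i + 1])} "
                f"(gap of {steps[i]} s after {pd.Timestamp(ts[i])})"
            )
        counts = sub["counts"].to_numpy()
        neg = np.nonzero(counts < 0)[0]
        if neg.size:
            i = int(neg[0])
            raise TableFormatError(
                f"{path}: athlete {athlete_id!r} has negative count "
                f"{counts[i]} at timestamp {pd.Timestamp(ts[i])}"
            )
        valid = (
            sub["valid"].to_numpy().astype(bool)
            if "valid" in sub.columns
            else None
        )
        out[str(athlete_id)] = EpochTimeline(
            athlete_id=str(athlete_id),
            start=pd.Timestamp(ts[0]),
            counts=counts,
            valid=valid,
        )
    return out


def write_epoch_table(
    timelines: Mapping[str, EpochTimeline] | Iterable[EpochTimeline],
    path: str | Path,
) -> None:
    """Write timelines as ``athlete_id,timestamp,counts,valid`` CSV."""
    if isinstance(timelines, Mapping):
        timelines = timelines.values()
    frames = []
    for tl in timelines:
        frames.append(
            pd.DataFrame(
                {
                    "athlete_id": tl.athlete_id,
                    "timestamp": tl.timestamps(),
                    "counts": tl.counts,
                    "valid": tl.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_diary_table(path: str | Path) -> list[DiaryNight]:
    """Read a diary file (``athlete_id,bed_time,getup_time``) into nights.

    Nights are sorted by bed time and ``night_index`` assigned 1..n per
    athlete.  Overlapping windows and windows of 18 h or more are rejected;
    a second night inside one noon-to-noon day is rejected (night-time sleep
    only, no naps).
    """
    df = _read_table(path)
    required = {"athlete_id", "bed_time", "getup_time"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: diary table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    df = df.copy()
    df["bed_time"] = pd.to_datetime(df["bed_time"])
    df["getup_time"] = pd.to_datetime(df["getup_time"])
    nights: list[DiaryNight] = []
    for athlete_id, sub in df.groupby("athlete_id", sort=True):
        sub = sub.sort_values("bed_time")
        prev: DiaryNight | None = None
        for k, (_, row) in enumerate(sub.iterrows(), start=1):
            try:
                night = DiaryNight(
                    athlete_id=str(athlete_id),
                    night_index=k,
                    bed_time=row["bed_time"],
                    getup_time=row["getup_time"],
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}: {exc}") from exc
            if prev is not None:
                if night.bed_time < prev.getup_time:
                    raise TableFormatError(
                        f"{path}: athlete {athlete_id!r} has overlapping diary "
                        f"windows (bed {night.bed_time} before previous get-up "
                        f"{prev.getup_time})"
                    )
                if night.anchor == prev.anchor:
                    raise TableFormatError(
                        f"{path}: athlete {athlete_id!r} has two diary windows "
                        f"in the noon-to-noon day of {prev.anchor.date()} "
                        "(night-time sleep only; naps are not modelled)"
                    )
            nights.append(night)
            prev = night
    return nights


def write_diary_table(nights: Sequence[DiaryNight], path: str | Path) -> None:
    pd.DataFrame(
        {
            "athlete_id": [n.athlete_id for n in nights],
            "bed_time": [n.bed_time for n in nights],
            "getup_time": [n.getup_time for n in nights],
        }
    ).to_csv(path, index=False)
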