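"""Synthetic athlete cohorts with known ground-truth sleep schedules.

The generator emits exactly what the pipeline consumes — per-minute
activity-count timelines and diary windows — together with the true
per-night onset/offset/TST/efficiency, so every stage can be validated
without any real recording.

Night model (all times on the noon-referenced minute axis):

* bedtime ~ athlete level + Normal(0, bedtime_jitter_sd), plus a weekend
  delay on Friday and Saturday nights;
* sleep onset = bedtime + Exponential(latency_mean) latency;
* true total sleep time ~ Normal(sleep_need, offset_jitter_sd);
* wake after sleep onset (WASO) is Poisson(waso_rate x TST hours) minutes,
  placed as short bouts strictly inside the sleep interval, so the sleep
  period = TST + WASO;
* diary get-up = offset + Uniform(0, 15) min.

Athletes differ in habitual bedtime, sleep need, jitter magnitude and WASO
propensity, which is what spreads cohort medians, MADs and SRI enough for
quintile classification to be meaningful.

Count model.  Wake minutes draw 205 + Gamma(3, 65) counts capped at 900;
WASO minutes draw uniform "restless" counts in [45, 150]; sleep minutes
are 0 except for occasional movement bursts (prob 0.05, Poisson(8) capped
at 25) kept >= 5 min away from the interval ends and >= 2 min from WASO.
These bounds make the post-weighting classification of every generated
epoch deterministic at the medium threshold of 40: wake and WASO minutes
always score wake, interior sleep minutes always score sleep, and exactly
the first and last minute of each sleep interval are eroded by neighbour
contamination.  A zero-noise configuration therefore recovers SRI = 100
and efficiency = 100% exactly, and in general recovered onset is late by
one minute, offset early by one minute, and TST short by two minutes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timegrid_io import (
    MINUTES_PER_DAY,
    DiaryNight,
    EpochTimeline,
    write_diary_table,
    write_epoch_table,
)

logger = logging.getLogger("somnoreg")

# count-model constants (see module docstring for why these bounds matter)
WAKE_FLOOR = 205
WAKE_SHAPE = 3.0
WAKE_SCALE = 65.0
WAKE_CAP = 900
SLEEP_BURST_PROB = 0.05
SLEEP_BURST_MEAN = 8.0
SLEEP_BURST_CAP = 25
WASO_COUNT_LOW = 45
WASO_COUNT_HIGH = 150
WASO_BOUT_MEAN = 5
EDGE_GAP = 5  # quiet minutes at each end of the sleep interval
WASO_MIN_GAP = 3  # minimum sleep minutes between WASO bouts

_MAX_WINDOW_MIN = 18 * 60


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings.

    Defaults emulate an elite team-sport cohort: ~200 athletes wearing the
    monitor for 7-43 nights (about 10 on average), bedtimes near 23:00,
    a sleep need near 8.3 h, efficiency in the mid-80s (%), and a modest
    Friday/Saturday delay.  Clock quantities are minutes from noon.
    """

    n_athletes: int = 203
    #: int = fixed nights for everyone; (lo, hi) = uniform; None = 7 + Poisson(2.7).
    nights_per_athlete: int | tuple[int, int] | None = None
    start_date: str = "2022-01-03"  # a Monday
    mean_bedtime: float = 660.0  # 23:00
    bedtime_jitter_sd: float = 30.0  # night-to-night, minutes
    offset_jitter_sd: float = 30.0  # SD of nightly sleep duration, minutes
    mean_sleep_need: float = 8.3  # hours of true sleep per night
    latency_mean: float = 5.0  # minutes
    waso_rate: float = 9.4  # expected wake minutes per sleep hour
    weekend_delay: float = 30.0  # added to Fri/Sat bed (and hence offset)
    # between-athlete heterogeneity
    bedtime_between_sd: float = 55.0
    sleep_need_between_sd: float = 35.0  # minutes
    waso_rate_between_sd: float = 4.0
    jitter_gsd: float = 1.6  # geometric SD of per-athlete jitter multiplier
    latency_gsd: float = 1.8  # geometric SD of per-athlete latency scale
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bedtime_jitter_sd",
            "offset_jitter_sd",
            "latency_mean",
            "waso_rate",
            "bedtime_between_sd",
            "sleep_need_between_sd",
            "waso_rate_between_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.jitter_gsd < 1.0 or self.latency_gsd < 1.0:
            raise ValueError("jitter_gsd and latency_gsd must be >= 1")
        expected_window = (
            self.latency_mean
            + self.mean_sleep_need * 60.0 * (1.0 + self.waso_rate / 60.0)
            + 15.0
        )
        if expected_window >= _MAX_WINDOW_MIN:
            raise ValueError(
                f"configuration produces diary windows of about "
                f"{expected_window / 60.0:.1f} h on average (>= 18 h); "
                "shorten sleep need, latency or WASO rate"
            )
        if isinstance(self.nights_per_athlete, int):
            if self.nights_per_athlete < 7:
                raise ValueError("nights_per_athlete must be >= 7")
        elif self.nights_per_athlete is not None:
            lo, hi = self.nights_per_athlete
            if lo < 7 or hi < lo:
                raise ValueError("nights range must satisfy 7 <= lo <= hi")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["nights_per_athlete"], tuple):
            d["nights_per_athlete"] = list(d["nights_per_athlete"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if isinstance(d.get("nights_per_athlete"), list):
            d["nights_per_athlete"] = tuple(d["nights_per_athlete"])
        return cls(**d)


@dataclass
class Cohort:
    """Generated cohort: inputs for the pipeline plus the ground truth."""

    timelines: dict[str, EpochTimeline]
    diaries: list[DiaryNight]
    truth: pd.DataFrame
    config: GeneratorConfig


def _n_nights(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.nights_per_athlete, int):
        return cfg.nights_per_athlete
    if cfg.nights_per_athlete is None:
        return int(min(7 + rng.poisson(2.7), 43))
    lo, hi = cfg.nights_per_athlete
    return int(rng.integers(lo, hi + 1))


def _place_waso(
    tst: int, waso: int, rng: np.random.Generator
) -> np.ndarray:
    """Offsets (relative to onset) of the WASO minutes, grouped in bouts.

    Bouts average :data:`WASO_BOUT_MEAN` minutes, sit >= EDGE_GAP minutes
    from either end of the interval and are separated by >= WASO_MIN_GAP
    sleep minutes.  Returns exactly ``waso`` offsets (fewer only if the
    interval is too short to host them, which is logged).
    """
    if waso <= 0:
        return np.empty(0, dtype=np.int64)
    n_bouts = max(1, int(round(waso / WASO_BOUT_MEAN)))
    while n_bouts > 1 and (
        2 * EDGE_GAP + WASO_MIN_GAP * (n_bouts - 1) > tst
    ):
        n_bouts -= 1
    if 2 * EDGE_GAP > tst:
        logger.warning("sleep interval too short for WASO placement; skipping")
        return np.empty(0, dtype=np.int64)
    # sleep gaps around the bouts: g0 + g1 + ... + g_n = tst
    minima = np.full(n_bouts + 1, WASO_MIN_GAP)
    minima[0] = minima[-1] = EDGE_GAP
    spare = tst - int(minima.sum())
    gaps = minima + rng.multinomial(spare, np.full(n_bouts + 1, 1 / (n_bouts + 1)))
    lengths = np.ones(n_bouts, dtype=np.int64)
    if waso > n_bouts:
        lengths += rng.multinomial(waso - n_bouts, np.full(n_bouts, 1 / n_bouts))
    offsets = []
    pos = 0
    for g, ln in zip(gaps[:-1], lengths):
        pos += int(g)
        offsets.extend(range(pos, pos + int(ln)))
        pos += int(ln)
    return np.asarray(offsets, dtype=np.int64)


def generate_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate diaries, activity timelines and ground truth for a cohort.

    Fully deterministic given ``cfg.seed``: every athlete draws from a
    substream spawned from the master seed, so regenerating a subset of
    athletes reproduces the same data.
    """
    start_noon = pd.Timestamp(cfg.start_date) + pd.Timedelta(hours=12)
    substreams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_athletes)
    width = max(3, len(str(cfg.n_athletes)))
    timelines: dict[str, EpochTimeline] = {}
    diaries: list[DiaryNight] = []
    truth_rows: list[dict] = []

    for a_idx, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        athlete_id = f"A{a_idx + 1:0{width}d}"
        n_nights = _n_nights(cfg, rng)

        bed_level = cfg.mean_bedtime + (
            rng.normal(0.0, cfg.bedtime_between_sd) if cfg.bedtime_between_sd else 0.0
        )
        need_min = float(
            np.clip(
                cfg.mean_sleep_need * 60.0
                + (
                    rng.normal(0.0, cfg.sleep_need_between_sd)
                    if cfg.sleep_need_between_sd
                    else 0.0
                ),
                300,
                720,
            )
        )
        jmult = (
            float(np.exp(rng.normal(0.0, np.log(cfg.jitter_gsd))))
            if cfg.jitter_gsd > 1.0
            else 1.0
        )
        bjit = cfg.bedtime_jitter_sd * jmult
        ojit = cfg.offset_jitter_sd * jmult
        lat_scale = cfg.latency_mean * (
            float(np.exp(rng.normal(0.0, np.log(cfg.latency_gsd))))
            if cfg.latency_gsd > 1.0
            else 1.0
        )
        if cfg.waso_rate <= 0:
            wrate = 0.0
        elif cfg.waso_rate_between_sd <= 0:
            wrate = cfg.waso_rate
        else:
            shape = (cfg.waso_rate / cfg.waso_rate_between_sd) ** 2
            wrate = float(rng.gamma(shape, cfg.waso_rate / shape))
            # restless sleepers are also the more irregular ones: couple the
            # WASO propensity weakly to the athlete's jitter multiplier
            # (sqrt coupling, rescaled so the cohort mean is unchanged)
            s = np.log(cfg.jitter_gsd) if cfg.jitter_gsd > 1.0 else 0.0
            wrate *= jmult**0.5 / float(np.exp(s**2 / 8.0))

        n_epochs = (n_nights + 1) * MINUTES_PER_DAY
        counts = np.minimum(
            WAKE_FLOOR + rng.gamma(WAKE_SHAPE, WAKE_SCALE, size=n_epochs),
            WAKE_CAP,
        ).astype(np.int64)

        for i in range(n_nights):
            anchor = start_noon + pd.Timedelta(days=i)
            is_weekend_night = anchor.dayofweek in (4, 5)  # Fri, Sat evening
            delay = cfg.weekend_delay if is_weekend_night else 0.0
            bed = int(
                np.clip(
                    round(
                        bed_level
                        + delay
                        + (rng.normal(0.0, bjit) if bjit else 0.0)
                    ),
                    480,
                    1080,
                )
            )
            latency = (
                int(min(round(rng.exponential(lat_scale)), 120))
                if cfg.latency_mean > 0
                else 0
            )
            tst = int(
                np.clip(
                    round(need_min + (rng.normal(0.0, ojit) if ojit else 0.0)),
                    240,
                    840,
                )
            )
            waso = int(rng.poisson(wrate * tst / 60.0)) if wrate > 0 else 0
            # keep the diary window strictly under 18 h even in sampling
            # tails: trim WASO first, then the sleep interval itself
            period_cap = _MAX_WINDOW_MIN - 1 - latency - 15
            if tst > period_cap:
                tst, waso = period_cap, 0
            waso = min(waso, period_cap - tst)
            waso_offsets = _place_waso(tst, waso, rng)
            waso = int(waso_offsets.size)
            period = tst + waso
            onset = bed + latency
            offset = onset + period
            getup = offset + int(rng.integers(0, 16))

            base = i * MINUTES_PER_DAY
            seg = np.zeros(period, dtype=np.int64)
            in_waso = np.zeros(period, dtype=bool)
            if waso:
                in_waso[waso_offsets] = True
                seg[waso_offsets] = rng.integers(
                    WASO_COUNT_LOW, WASO_COUNT_HIGH + 1, size=waso
                )
            # movement bursts: interior sleep minutes away from WASO/edges
            burst_ok = ~in_waso
            burst_ok[:EDGE_GAP] = False
            burst_ok[-EDGE_GAP:] = False
            if waso:
                near = np.zeros(period, dtype=bool)
                for d in (-2, -1, 1, 2):
                    src = np.nonzero(in_waso)[0] + d
                    src = src[(src >= 0) & (src < period)]
                    near[src] = True
                burst_ok &= ~near
            bursts = burst_ok & (rng.random(period) < SLEEP_BURST_PROB)
            if bursts.any():
                seg[bursts] = np.minimum(
                    rng.poisson(SLEEP_BURST_MEAN, size=int(bursts.sum())),
                    SLEEP_BURST_CAP,
                )
            counts[base + onset : base + offset] = seg

            diaries.append(
                DiaryNight(
                    athlete_id=athlete_id,
                    night_index=i + 1,
                    bed_time=start_noon + pd.Timedelta(minutes=base + bed),
                    getup_time=start_noon + pd.Timedelta(minutes=base + getup),
                )
            )
            truth_rows.append(
                {
                    "athlete_id": athlete_id,
                    "night_index": i + 1,
                    "anchor": anchor,
                    "bedtime_min": float(bed),
                    "onset_min": float(onset),
                    "offset_min": float(offset),
                    "total_sleep_time_h": tst / 60.0,
                    "waso_min": float(waso),
                    "sleep_period_h": period / 60.0,
                    "sleep_efficiency_pct": 100.0 * tst / period,
                    "sleep_onset_latency_min": float(latency),
                }
            )

        timelines[athlete_id] = EpochTimeline(
            athlete_id=athlete_id, start=start_noon, counts=counts
        )

    return Cohort(
        timelines=timelines,
        diaries=diaries,
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write epoch CSV, diary CSV, ground-truth CSV and a config snapshot."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_epoch_table(cohort.timelines, outdir / "epochs.csv")
    write_diary_table(cohort.diaries, outdir / "diary.csv")
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "config.json").write_text(
        json.dumps(cohort.config.to_dict(), indent=2) + "\n"
    )


RECOVERY_VARIABLES = (
    "bedtime_min",
    "onset_min",
    "offset_min",
    "total_sleep_time_h",
    "sleep_period_h",
    "sleep_efficiency_pct",
    "sleep_onset_latency_min",
)


def recovery_report(
    truth: pd.DataFrame,
    nights: pd.DataFrame,
    variables: Sequence[str] = RECOVERY_VARIABLES,
) -> pd.DataFrame:
    """Per-variable bias and RMSE of pipeline output against ground truth.

    Bias is mean(recovered - true).  Every recovered (athlete, night) key
    must exist in the ground truth; a mismatch raises.
    """
    keys = ["athlete_id", "night_index"]
    merged = nights.merge(truth, on=keys, suffixes=("_rec", "_true"), how="left")
    missing = merged[[f"{variables[0]}_true"]].isna().any(axis=1)
    if missing.any():
        bad = merged.loc[missing, keys].iloc[0]
        raise ValueError(
            f"recovered night {tuple(bad)} has no ground-truth counterpart"
        )
    rows = []
    for var in variables:
        err = merged[f"{var}_rec"] - merged[f"{var}_true"]
        rows.append(
            {
                "variable": var,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "n": int(err.size),
            }
        )
    return pd.DataFrame(rows)
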