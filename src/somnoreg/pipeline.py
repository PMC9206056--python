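"""End-to-end orchestration: timelines + diaries -> nights -> profiles.

``score_cohort`` scores every diary night against its athlete's timeline
and tabulates the eight per-night variables.  ``build_profiles`` then
aggregates per athlete: medians of each variable, MADs and night-to-night
variation of onset/offset/TST/efficiency, the SRI over the longest whole
number of weeks, and (optionally) the quintile regularity class.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import regularity, sleep_scoring
from .sleep_scoring import NightSummary, nights_to_frame
from .timegrid_io import DiaryNight, EpochTimeline

logger = logging.getLogger("somnoreg")

#: Display-name -> profile-column mapping for the cohort comparison table.
TABLE_VARIABLES: dict[str, str] = {
    "Bedtime (min from noon)": "med_bedtime_min",
    "Sleep onset (min from noon)": "med_onset_min",
    "Sleep offset (min from noon)": "med_offset_min",
    "Midpoint of sleep (min from noon)": "med_midpoint_min",
    "Sleep regularity index (AU)": "sri",
    "Sleep onset variation (min/night)": "var_onset_min",
    "Sleep offset variation (min/night)": "var_offset_min",
    "Total sleep time (h)": "med_tst_h",
    "Total sleep time variation (min/night)": "var_tst_min",
    "Sleep efficiency (%)": "med_eff_pct",
    "Sleep efficiency variation (%/night)": "var_eff_pct",
    "Sleep onset latency (min)": "med_sol_min",
}


def score_cohort(
    timelines: Mapping[str, EpochTimeline],
    diaries: Iterable[DiaryNight],
    threshold: float = sleep_scoring.DEFAULT_THRESHOLD,
    *,
    weighted: bool = True,
    onset_consecutive_epochs: int = 1,
    max_invalid_fraction: float = sleep_scoring.DEFAULT_MAX_INVALID_FRACTION,
) -> tuple[list[NightSummary], pd.DataFrame]:
    """Score every diary night and summarise it.

    Weighted activity scores are computed once per timeline and shared
    across that athlete's nights.  Invalid nights (no sleep epoch, or too
    much off-wrist time) are dropped with a log entry.
    """
    score_cache: dict[str, np.ndarray] = {}
    summaries: list[NightSummary] = []
    for night in diaries:
        timeline = timelines.get(night.athlete_id)
        if timeline is None:
            raise KeyError(f"no timeline for athlete {night.athlete_id!r}")
        if night.athlete_id not in score_cache:
            score_cache[night.athlete_id] = sleep_scoring.epoch_activity_scores(
                timeline.counts, weighted=weighted
            )
        scored = sleep_scoring.score_sleep_wake(
            timeline,
            night,
            threshold,
            weighted=weighted,
            max_invalid_fraction=max_invalid_fraction,
            scores=score_cache[night.athlete_id],
        )
        summary = sleep_scoring.summarize_night(
            scored, onset_consecutive_epochs=onset_consecutive_epochs
        )
        if summary is not None:
            summaries.append(summary)
    return summaries, nights_to_frame(summaries)


def _athlete_profile(
    nights: list[NightSummary],
    missing_epoch_policy: str,
    variation_aggregate: str,
) -> dict | None:
    """Aggregate one athlete's nights; None if too few days for the SRI."""
    sub = nights_to_frame(nights)
    idx = sub["night_index"].to_numpy()
    try:
        vec = regularity.build_state_vector(
            nights, missing_epoch_policy=missing_epoch_policy
        )
        vec = regularity.truncate_whole_weeks(vec)
        sri_value = regularity.sri(vec)
        sri_days = vec.n_days
    except ValueError as exc:
        logger.info(
            "athlete %s excluded from profiles: %s", nights[0].athlete_id, exc
        )
        return None
    onset = sub["onset_min"].to_numpy()
    offset = sub["offset_min"].to_numpy()
    tst_min = sub["total_sleep_time_h"].to_numpy() * 60.0
    eff = sub["sleep_efficiency_pct"].to_numpy()
    return {
        "athlete_id": nights[0].athlete_id,
        "n_valid_nights": len(nights),
        "sri": sri_value,
        "sri_days": sri_days,
        "med_bedtime_min": float(sub["bedtime_min"].median()),
        "med_onset_min": float(sub["onset_min"].median()),
        "med_offset_min": float(sub["offset_min"].median()),
        "med_midpoint_min": float(sub["midpoint_min"].median()),
        "med_tst_h": float(sub["total_sleep_time_h"].median()),
        "med_eff_pct": float(sub["sleep_efficiency_pct"].median()),
        "med_sol_min": float(sub["sleep_onset_latency_min"].median()),
        "mad_bedtime_min": regularity.mad_clock(sub["bedtime_min"]),
        "mad_onset_min": regularity.mad_clock(onset),
        "mad_offset_min": regularity.mad_clock(offset),
        "mad_tst_min": regularity.mad_clock(tst_min),
        "mad_eff_pct": regularity.mad_clock(eff),
        "var_onset_min": regularity.night_to_night_variation(
            onset, idx, aggregate=variation_aggregate
        ),
        "var_offset_min": regularity.night_to_night_variation(
            offset, idx, aggregate=variation_aggregate
        ),
        "var_tst_min": regularity.night_to_night_variation(
            tst_min, idx, aggregate=variation_aggregate
        ),
        "var_eff_pct": regularity.night_to_night_variation(
            eff, idx, aggregate=variation_aggregate
        ),
    }


def build_profiles(
    summaries: Iterable[NightSummary],
    *,
    missing_epoch_policy: str = "wake",
    variation_aggregate: str = "median",
    classify: bool = True,
    quintile_tie_policy: str = "inclusive",
) -> pd.DataFrame:
    """Per-athlete aggregate profiles, one row per athlete.

    Medians, MADs and night-to-night variation use all valid nights; the
    SRI uses the first whole number of weeks of the athlete's span.
    Athletes spanning fewer than 7 days are excluded (logged).  With
    ``classify=True`` a ``regularity_class`` column is added from the SRI
    quintiles of the athletes present.
    """
    by_athlete: dict[str, list[NightSummary]] = {}
    for s in summaries:
        by_athlete.setdefault(s.athlete_id, []).append(s)
    rows = []
    for athlete_id in sorted(by_athlete):
        prof = _athlete_profile(
            by_athlete[athlete_id], missing_epoch_policy, variation_aggregate
        )
        if prof is not None:
            rows.append(prof)
    profiles = pd.DataFrame(rows)
    if classify and not profiles.empty:
        classes = regularity.classify_quintiles(
            dict(zip(profiles["athlete_id"], profiles["sri"])),
            tie_policy=quintile_tie_policy,
        )
        profiles["regularity_class"] = profiles["athlete_id"].map(classes)
    return profiles


def run_pipeline(
    timelines: Mapping[str, EpochTimeline],
    diaries: Iterable[DiaryNight],
    threshold: float = sleep_scoring.DEFAULT_THRESHOLD,
    **profile_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Timelines + diaries -> (nights table, profiles table)."""
    summaries, nights = score_cohort(timelines, diaries, threshold)
    profiles = build_profiles(summaries, **profile_kwargs)
    return nights, profiles
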