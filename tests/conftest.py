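import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import somnoreg as sr

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

NOON = pd.Timestamp("2022-01-03 12:00")


@pytest.fixture(scope="session")
def small_cohort() -> sr.Cohort:
    """A 20-athlete, 14-night cohort with default noise levels."""
    cfg = sr.GeneratorConfig(n_athletes=20, nights_per_athlete=14, seed=5)
    return sr.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_cohort) -> pd.DataFrame:
    _, profiles = sr.run_pipeline(
        small_cohort.timelines, small_cohort.diaries
    )
    return profiles


def make_night(
    counts,
    bed_min: int = 660,
    getup_min: int = 1140,
    athlete: str = "A",
    valid=None,
    start: pd.Timestamp = NOON,
):
    """Timeline + diary night on a 2-day grid starting at noon."""
    counts = np.asarray(counts)
    tl = sr.EpochTimeline(athlete, start, counts, valid=valid)
    night = sr.DiaryNight(
        athlete,
        1,
        start + pd.Timedelta(minutes=bed_min),
        start + pd.Timedelta(minutes=getup_min),
    )
    return tl, night


def make_summary(
    athlete: str,
    night_index: int,
    anchor: pd.Timestamp,
    onset_min: float,
    offset_min: float,
    bedtime_min: float | None = None,
    efficiency: float = 100.0,
) -> sr.NightSummary:
    """A consistent NightSummary from an onset/offset pair (for SRI tests)."""
    bedtime_min = onset_min if bedtime_min is None else bedtime_min
    period_h = (offset_min - onset_min) / 60.0
    return sr.NightSummary(
        athlete_id=athlete,
        night_index=night_index,
        anchor=anchor,
        bedtime_min=bedtime_min,
        onset_min=onset_min,
        offset_min=offset_min,
        midpoint_min=(onset_min + offset_min) / 2.0,
        sleep_period_h=period_h,
        total_sleep_time_h=period_h * efficiency / 100.0,
        sleep_efficiency_pct=efficiency,
        sleep_onset_latency_min=onset_min - bedtime_min,
    )
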