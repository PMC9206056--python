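"""State vectors, the SRI formula, MAD/variation statistics, quintiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import somnoreg as sr
from somnoreg.regularity import MISSING, SLEEP, WAKE

from conftest import NOON, make_summary


def intervals_to_states(intervals, n_days):
    """Brute-force per-minute membership oracle."""
    states = np.zeros(n_days * 1440, dtype=np.int8)
    for t in range(states.size):
        for s, e in intervals:
            if s <= t < e:
                states[t] = 1
    return states


def sri_double_sum(states, n_days):
    """The double-sum form: sum of delta(s[i,j], s[i+1,j]) over i, j."""
    s = np.asarray(states).reshape(n_days, 1440)
    m = 1440
    total = sum(
        int(s[i, j] == s[i + 1, j]) for i in range(n_days - 1) for j in range(m)
    )
    return -100.0 + 200.0 / (m * (n_days - 1)) * total


def nightly(intervals):
    return [
        make_summary("A", k + 1, NOON + pd.Timedelta(days=d), onset, offset)
        for k, (d, onset, offset) in enumerate(intervals)
    ]


def test_repeated_night_fills_expected_epochs():
    nights = nightly([(d, 660, 1140) for d in range(7)])
    vec = sr.build_state_vector(nights)
    assert vec.n_days == 7
    assert int((vec.states == SLEEP).sum()) == 7 * 480


def test_state_vector_matches_membership_oracle():
    rng = np.random.default_rng(0)
    night_plan, intervals = [], []
    for d in range(5):
        onset = int(rng.integers(500, 800))
        offset = onset + int(rng.integers(200, 600))
        night_plan.append((d, onset, offset))
        intervals.append((d * 1440 + onset, d * 1440 + offset))
    vec = sr.build_state_vector(nightly(night_plan))
    np.testing.assert_array_equal(
        vec.states, intervals_to_states(intervals, 5)
    )


def test_no_valid_nights_gives_all_wake_and_warns(caplog):
    with caplog.at_level("WARNING", logger="somnoreg"):
        vec = sr.build_state_vector(
            [], start_noon=NOON, n_days=7, athlete_id="A"
        )
    assert (vec.states == WAKE).all()
    assert "all wake" in caplog.text


def test_overlapping_intervals_rejected():
    nights = [
        make_summary("A", 1, NOON, 700, 1500),  # runs past next noon
        make_summary("A", 2, NOON + pd.Timedelta(days=1), 30, 500),
    ]
    with pytest.raises(ValueError, match="overlap"):
        sr.build_state_vector(nights)


def test_mask_policy_marks_uncovered_days_missing():
    nights = nightly([(d, 660, 1140) for d in (0, 1, 2, 3, 5, 6)])
    vec = sr.build_state_vector(nights, n_days=7, missing_epoch_policy="mask")
    day4 = vec.states[4 * 1440 : 5 * 1440]
    assert (day4 == MISSING).all()
    assert (vec.states[:1440] != MISSING).all()


@pytest.mark.parametrize("days_in, days_out", [(10, 7), (14, 14), (21, 21)])
def test_whole_week_truncation(days_in, days_out):
    vec = sr.StateVector("A", np.zeros(days_in * 1440, np.int8), NOON)
    assert sr.truncate_whole_weeks(vec).n_days == days_out


def test_truncation_requires_seven_days():
    vec = sr.StateVector("A", np.zeros(6 * 1440, np.int8), NOON)
    with pytest.raises(ValueError, match="7"):
        sr.truncate_whole_weeks(vec)


def test_identical_week_scores_100():
    nights = nightly([(d, 660, 1140) for d in range(7)])
    assert sr.sri(sr.build_state_vector(nights)) == 100.0


def test_antiphase_half_day_sleep_scores_minus_100():
    # sleep 00:00-12:00 on day 1 (second half of the noon day) and
    # 12:00-24:00 on day 2: every 24-h pair mismatches
    states = np.zeros(2 * 1440, np.int8)
    states[720:1440] = SLEEP
    states[1440:2160] = SLEEP
    assert sr.sri(states) == -100.0


def test_four_hour_shift_worked_example():
    # 8-h sleep 22:00-06:00 then 02:00-10:00: f = 2/3
    nights = nightly([(0, 600, 1080), (1, 840, 1320)])
    assert sr.sri(sr.build_state_vector(nights)) == pytest.approx(100 / 3)


@pytest.mark.parametrize("quarters", [0, 1, 2, 3, 4])
def test_sri_equals_linear_function_of_match_fraction(quarters):
    # 12-h sleep shifted by s minutes day-to-day: f = 1 - 2s/1440
    shift = (4 - quarters) * 180
    states = np.zeros(2 * 1440, np.int8)
    states[0:720] = SLEEP
    states[1440 + shift : 1440 + shift + 720] = SLEEP
    f = quarters / 4.0
    assert sr.sri(states) == pytest.approx(-100.0 + 200.0 * f)


def test_sri_matches_double_sum_oracle_on_random_schedules():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n_days = int(rng.integers(2, 8))
        states = rng.integers(0, 2, n_days * 1440).astype(np.int8)
        assert sr.sri(states) == pytest.approx(sri_double_sum(states, n_days))


def test_sri_mask_aware_pair_fraction():
    rng = np.random.default_rng(2)
    states = rng.integers(0, 2, 4 * 1440).astype(np.int8)
    states[rng.random(states.size) < 0.1] = MISSING
    a, b = states[:-1440], states[1440:]
    keep = (a != MISSING) & (b != MISSING)
    expected = -100.0 + 200.0 * (a[keep] == b[keep]).mean()
    assert sr.sri(states) == pytest.approx(expected)


def test_sri_errors():
    with pytest.raises(ValueError, match="2 days"):
        sr.sri(np.zeros(1440, np.int8))
    with pytest.raises(ValueError, match="missing"):
        sr.sri(np.full(2 * 1440, MISSING, np.int8))


def test_sri_invariant_to_clock_translation_and_relabeling():
    rng = np.random.default_rng(3)
    base = [(d, int(o), int(o + 420)) for d, o in
            enumerate(rng.integers(500, 900, 7))]
    ref = sr.sri(sr.build_state_vector(nightly(base)))
    for k in (-120, 37, 100):  # shifted intervals stay inside each day
        shifted = [(d, o + k, e + k) for d, o, e in base]
        assert sr.sri(sr.build_state_vector(nightly(shifted))) == pytest.approx(ref)
    states = sr.build_state_vector(nightly(base)).states
    assert sr.sri((1 - states).astype(np.int8)) == pytest.approx(ref)


# --- MAD and night-to-night variation -------------------------------------


def two_pass_median(x):
    x = sorted(x)
    n = len(x)
    return x[n // 2] if n % 2 else 0.5 * (x[n // 2 - 1] + x[n // 2])


@pytest.mark.parametrize(
    "values, expected",
    [
        ([660, 660, 660], 0.0),
        ([600, 630, 660], 30.0),  # deviations {30, 0, 30}
        ([0, 10, 20, 1000], 10.0),
    ],
)
def test_mad_examples(values, expected):
    assert sr.mad_clock(values) == expected


def test_mad_matches_two_pass_median_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.normal(660, 50, int(rng.integers(2, 40))).tolist()
        med = two_pass_median(x)
        expected = two_pass_median([abs(v - med) for v in x])
        assert sr.mad_clock(x) == pytest.approx(expected)


@given(
    st.lists(st.floats(0, 1440), min_size=2, max_size=20),
    st.floats(-720, 720),
)
def test_mad_translation_invariant(values, shift):
    assert sr.mad_clock([v + shift for v in values]) == pytest.approx(
        sr.mad_clock(values), abs=1e-9
    )


def test_previous_night_variation_examples():
    # onset 22:00 one night, 21:30 the next -> 30 min variation
    assert sr.night_to_night_variation([600, 570]) == 30.0
    assert sr.night_to_night_variation([660] * 5) == 0.0
    assert sr.night_to_night_variation([0, 60, 0]) == 60.0
    assert sr.night_to_night_variation([0, 30, 90], aggregate="mean") == 45.0


def test_variation_uses_only_consecutive_nights():
    # nights 1, 2, 5: only the (1, 2) pair counts
    assert sr.night_to_night_variation([600, 640, 0], [1, 2, 5]) == 40.0
    assert np.isnan(sr.night_to_night_variation([600, 640], [1, 3]))


@given(
    st.lists(st.floats(0, 1440), min_size=2, max_size=15),
    st.floats(-500, 500),
)
def test_variation_translation_invariant(values, shift):
    a = sr.night_to_night_variation(values)
    b = sr.night_to_night_variation([v + shift for v in values])
    assert a == pytest.approx(b, abs=1e-9)


# --- quintile classification ----------------------------------------------


def quantile_type7(sorted_vals, q):
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def test_ten_distinct_scores_give_two_per_extreme():
    scores = {f"a{i}": float(i) for i in range(10)}
    classes = sr.classify_quintiles(scores)
    assert sum(c == "regular" for c in classes.values()) == 2
    assert sum(c == "irregular" for c in classes.values()) == 2
    assert classes["a9"] == "regular" and classes["a0"] == "irregular"


def test_degenerate_ties_demand_policy_override():
    scores = {f"a{i}": 85.0 for i in range(6)}
    with pytest.raises(ValueError, match="policy"):
        sr.classify_quintiles(scores)
    classes = sr.classify_quintiles(scores, tie_policy="exclusive")
    assert all(c == "middle" for c in classes.values())


def test_too_few_athletes_rejected():
    with pytest.raises(ValueError, match="5"):
        sr.classify_quintiles({"a": 80.0, "b": 85.0})


def test_classification_matches_sorting_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        scores = {f"a{i}": float(v) for i, v in
                  enumerate(rng.normal(85, 5, n))}
        classes = sr.classify_quintiles(scores)
        svals = sorted(scores.values())
        q20 = quantile_type7(svals, 0.2)
        q80 = quantile_type7(svals, 0.8)
        for a, v in scores.items():
            expected = (
                "regular" if v >= q80
                else "irregular" if v <= q20
                else "middle"
            )
            assert classes[a] == expected
        n_regular = sum(c == "regular" for c in classes.values())
        assert n_regular >= n // 5
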