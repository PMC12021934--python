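import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from actiscan import sleep_timing as st


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerate every 30-min window explicitly
# ---------------------------------------------------------------------------

def oracle_onset(is_sleep):
    for s in range(0, 840 - 30 + 1):
        window = is_sleep[s : s + 30]
        if sum(window) >= 15:
            for j in range(s, s + 30):
                if is_sleep[j]:
                    return j
    return None


def oracle_offset(is_sleep):
    for e in range(839, 29 - 1, -1):
        window = is_sleep[e - 29 : e + 1]
        if sum(window) >= 15:
            for j in range(e, e - 30, -1):
                if is_sleep[j]:
                    return j
    return None


def night(sleep_ranges):
    """Boolean night axis with sleep on the given [start, end) index ranges."""
    x = np.zeros(840, dtype=bool)
    for a, b in sleep_ranges:
        x[a:b] = True
    return x


CONTIGUOUS = night([(180, 660)])  # 23:00 through 06:59


class TestDetectors:
    def test_contiguous_bout_onset_is_first_sleep_minute(self):
        assert st.detect_onset(CONTIGUOUS) == 180  # 23:00

    def test_contiguous_bout_offset_is_last_sleep_minute(self):
        # first qualifying backward window is 06:45-07:14 holding exactly 15
        # sleep minutes; the last sleep minute inside is 06:59
        assert st.detect_offset(CONTIGUOUS) == 659

    def test_all_sleep_night(self):
        full = night([(0, 840)])
        assert st.detect_onset(full) == 0
        assert st.detect_offset(full) == 839

    def test_sparse_sleep_below_threshold_is_undetectable(self):
        # 14 isolated minutes, 60 min apart: no 30-min window can reach 15
        x = np.zeros(840, dtype=bool)
        x[np.arange(14) * 60] = True
        assert st.detect_onset(x) is None
        assert st.detect_offset(x) is None

    def test_empty_night(self):
        x = np.zeros(840, dtype=bool)
        assert st.detect_onset(x) is None

    def test_oracle_equivalence_on_random_nights(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            kind = rng.integers(3)
            if kind == 0:  # bout + fragmentation
                a = int(rng.integers(0, 700))
                b = min(840, a + int(rng.integers(60, 600)))
                x = night([(a, b)])
                x &= rng.random(840) > 0.1
            elif kind == 1:  # pure noise
                x = rng.random(840) < rng.uniform(0.0, 0.6)
            else:  # two bouts
                x = night([(int(rng.integers(0, 300)), int(rng.integers(300, 500))),
                           (int(rng.integers(500, 700)), int(rng.integers(700, 840)))])
            assert st.detect_onset(x) == oracle_onset(x.tolist())
            assert st.detect_offset(x) == oracle_offset(x.tolist())

    def test_time_reversal_swaps_roles(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.random(840) < 0.3
            rev = x[::-1]
            onset = st.detect_onset(x)
            assert st.detect_offset(rev) == (None if onset is None else 839 - onset)

    def test_earlier_sleep_never_delays_onset(self):
        x = night([(400, 700)])
        base = st.detect_onset(x)
        x2 = x.copy()
        x2[300:340] = True  # add sleep strictly before current onset
        assert st.detect_onset(x2) <= base

    def test_shift_invariance_of_bout(self):
        for k in (0, 17, 60):
            x = night([(200 + k, 650 + k)])
            rec = st.nightly_sleep_window(x)
            assert rec["onset"] == 200 + k
            assert rec["offset"] == 649 + k
            assert rec["midpoint"] == (200 + k + 649 + k) / 2


class TestNightlyWindow:
    def test_midpoint_is_mean_of_onset_and_offset(self):
        rec = st.nightly_sleep_window(CONTIGUOUS)
        assert rec["onset"] == 180 and rec["offset"] == 659
        assert rec["midpoint"] == pytest.approx((180 + 659) / 2)  # 02:59:30 clock

    def test_undetectable_night_returns_none(self):
        assert st.nightly_sleep_window(np.zeros(840, dtype=bool)) is None


class TestSummaries:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "anchor_date", "onset", "offset", "midpoint"])

    def test_midpoint_of_averaged_onset_offset(self):
        # onsets 23:00 & 23:30 (axis 180, 210); offsets 07:00 & 06:30 (660, 630)
        w = self._windows(
            [
                ("A", pd.Timestamp("2013-01-07"), 180, 660, 420.0),
                ("A", pd.Timestamp("2013-01-08"), 210, 630, 420.0),
            ]
        )
        s = st.summarize_sleep(w)
        assert s["mean_onset"].iloc[0] == pytest.approx(195)  # 23:15
        assert s["mean_offset"].iloc[0] == pytest.approx(645)  # 06:45
        # overall midpoint on the clock: 03:00
        clock = st.axis_to_clock_minutes(s["overall_midpoint"].iloc[0])
        assert float(clock) == pytest.approx(180.0)

    def test_single_night_summary_equals_that_night(self):
        w = self._windows([("A", pd.Timestamp("2013-01-07"), 180, 660, 420.0)])
        s = st.summarize_sleep(w)
        assert s["overall_midpoint"].iloc[0] == 420.0 and s["n_nights"].iloc[0] == 1

    def test_weekend_midpoint_missing_without_friday_or_saturday(self):
        # 2013-01-07 is a Monday
        w = self._windows(
            [("A", pd.Timestamp("2013-01-07") + pd.Timedelta(days=d), 180, 660, 420.0) for d in range(4)]
        )
        s = st.summarize_sleep(w)
        assert np.isnan(s["weekend_midpoint"].iloc[0])

    def test_weekend_midpoint_uses_friday_and_saturday_nights(self):
        w = self._windows(
            [
                ("A", pd.Timestamp("2013-01-07"), 180, 660, 420.0),  # Monday
                ("A", pd.Timestamp("2013-01-11"), 240, 700, 470.0),  # Friday
                ("A", pd.Timestamp("2013-01-12"), 240, 700, 470.0),  # Saturday
            ]
        )
        s = st.summarize_sleep(w)
        assert s["weekend_midpoint"].iloc[0] == pytest.approx(470.0)
        assert s["overall_midpoint"].iloc[0] != s["weekend_midpoint"].iloc[0]

    def test_empty_windows_give_empty_summary(self):
        s = st.summarize_sleep(self._windows([]))
        assert len(s) == 0


class TestClockHelpers:
    def test_axis_to_clock_wraps_midnight(self):
        assert float(st.axis_to_clock_minutes(0)) == 1200.0  # 20:00
        assert float(st.axis_to_clock_minutes(420)) == 180.0  # 03:00

    def test_format_clock_seconds_resolution(self):
        assert st.format_clock(179.5) == "02:59:30"
        assert st.format_clock(0.0) == "00:00:00"


class TestDetectorProperties:
    """Derandomised property checks against the brute-force oracle."""

    @staticmethod
    def _night_from_runs(runs):
        x = np.zeros(840, dtype=bool)
        pos = 0
        state = False
        for r in runs:
            x[pos : pos + r] = state
            pos += r
            state = not state
            if pos >= 840:
                break
        return x

    @given(hst.lists(hst.integers(min_value=1, max_value=300), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_run_length_patterns_match_oracle(self, runs):
        x = self._night_from_runs(runs)
        assert st.detect_onset(x) == oracle_onset(x.tolist())
        assert st.detect_offset(x) == oracle_offset(x.tolist())

    @given(hst.integers(min_value=0, max_value=300), hst.integers(min_value=15, max_value=500))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_onset_offset_bracket_every_bout(self, start, length):
        end = min(840, start + length)
        x = night([(start, end)])
        rec = st.nightly_sleep_window(x)
        if end - start >= 15:
            assert rec["onset"] == start and rec["offset"] == end - 1
        else:
            assert rec is None
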