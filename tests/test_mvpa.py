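"""Moderate sessions, vigorous epochs, daily/weekly totals, hourly histogram."""

import numpy as np
import pandas as pd
import pytest

from chronoactivity.epochs import EPOCHS_PER_DAY, EPOCHS_PER_HOUR, EpochSeries
from chronoactivity.mvpa import (
    build_weekly_profile,
    daily_mvpa_minutes,
    detect_moderate_sessions,
    detect_vigorous_epochs,
    hourly_histogram,
    weekly_mvpa,
)

START = pd.Timestamp("2015-06-01 00:00:00")


def quiet_series(n_epochs=EPOCHS_PER_DAY, fill=50.0, pid="m0"):
    return EpochSeries(pid, START, np.full(n_epochs, fill))


def epoch_index(hour, minute=0, second=0, day=0):
    return day * EPOCHS_PER_DAY + hour * EPOCHS_PER_HOUR + minute * 12 + second // 5


class TestModerateSessions:
    def test_49_of_60_in_band_is_a_session(self):
        series = quiet_series()
        s = epoch_index(10)
        series.vm[s : s + 49] = 200.0
        assert s in detect_moderate_sessions(series)

    def test_exactly_80_percent_is_not_a_session(self):
        series = quiet_series()
        s = epoch_index(10)
        series.vm[s : s + 48] = 200.0
        assert detect_moderate_sessions(series).size == 0

    def test_all_epochs_above_band_no_sessions(self):
        assert detect_moderate_sessions(quiet_series(fill=500.0)).size == 0

    def test_blocks_are_clock_aligned_not_sliding(self):
        series = quiet_series()
        s = epoch_index(10) + 30  # 55 in-band epochs straddling two blocks
        series.vm[s : s + 55] = 200.0
        assert detect_moderate_sessions(series).size == 0

    def test_adding_in_band_epoch_never_destroys_session(self):
        series = quiet_series()
        s = epoch_index(10)
        series.vm[s : s + 49] = 200.0
        before = set(detect_moderate_sessions(series))
        series.vm[s + 55] = 300.0  # one more epoch moves into the band
        after = set(detect_moderate_sessions(series))
        assert before <= after


class TestVigorousEpochs:
    def test_threshold_is_strict(self):
        series = quiet_series(n_epochs=1440)
        series.vm[10] = 400.0
        series.vm[11] = 400.1
        assert detect_vigorous_epochs(series).tolist() == [11]

    def test_empty_series(self):
        series = EpochSeries("e", START, np.empty(0))
        assert detect_vigorous_epochs(series).size == 0


class TestDailyMinutes:
    def test_sessions_plus_standalone_vigorous_arithmetic(self):
        series = quiet_series()
        sessions = [epoch_index(9), epoch_index(12), epoch_index(18)]
        for s in sessions:
            series.vm[s : s + 60] = 200.0
        vig = np.array([epoch_index(14, m) for m in range(24)])
        series.vm[vig] = 500.0
        sess = detect_moderate_sessions(series)
        v = detect_vigorous_epochs(series)
        assert daily_mvpa_minutes(series, sess, v, 0) == pytest.approx(
            3 * 5 + 24 * 5 / 60
        )  # 17 min

    def test_nocturnal_vigorous_contributes_zero(self):
        series = quiet_series()
        vig = np.array([epoch_index(2, m) for m in range(12)])
        series.vm[vig] = 500.0
        v = detect_vigorous_epochs(series)
        assert daily_mvpa_minutes(series, np.empty(0, int), v, 0) == 0.0

    def test_no_mvpa_is_zero(self):
        series = quiet_series()
        assert daily_mvpa_minutes(series, np.empty(0, int), np.empty(0, int), 0) == 0.0

    def test_vigorous_inside_session_not_double_counted(self):
        series = quiet_series()
        s = epoch_index(10)
        series.vm[s : s + 60] = 200.0
        series.vm[s + 5] = 500.0  # 59/60 still in band -> session holds
        sess = detect_moderate_sessions(series)
        v = detect_vigorous_epochs(series)
        assert daily_mvpa_minutes(series, sess, v, 0) == pytest.approx(5.0)


class TestWeeklyExtrapolation:
    def test_four_valid_days_sixty_minutes(self):
        daily = np.array([20.0, 15.0, 10.0, 15.0, 0.0, 0.0, 0.0])
        valid = np.array([1, 1, 1, 1, 0, 0, 0], dtype=bool)
        assert weekly_mvpa(daily, valid) == pytest.approx(105.0)

    def test_seven_valid_days_is_plain_sum(self):
        daily = np.arange(7.0)
        assert weekly_mvpa(daily, np.ones(7, bool)) == pytest.approx(daily.sum())

    def test_zero_valid_days_raises(self):
        with pytest.raises(ValueError, match="no valid days"):
            weekly_mvpa(np.ones(7), np.zeros(7, bool))


class TestHourlyHistogram:
    def test_session_minutes_split_by_midpoint(self):
        series = quiet_series()
        s = epoch_index(10, 57)  # 10:57-11:02
        sessions = np.array([s])
        hist = hourly_histogram(series, sessions, np.empty(0, int))
        assert hist[10] == pytest.approx(3.0)
        assert hist[11] == pytest.approx(2.0)
        assert hist.sum() == pytest.approx(5.0)

    def test_single_hour_activity_single_bin(self):
        series = quiet_series()
        s = epoch_index(13, 10)
        hist = hourly_histogram(series, np.array([s]), np.empty(0, int))
        assert hist[13] == pytest.approx(5.0) and np.count_nonzero(hist) == 1

    def test_conservation_against_daily_totals(self, epoch_cohort):
        """Histogram total equals daily 05-24 totals plus nocturnal MVPA."""
        series_list, _ = epoch_cohort
        for series in series_list[:8]:
            sess = detect_moderate_sessions(series)
            vig = detect_vigorous_epochs(series)
            hist = hourly_histogram(series, sess, vig)
            daily = sum(
                daily_mvpa_minutes(series, sess, vig, d) for d in range(series.n_days)
            )
            nocturnal = hist[:5].sum()
            assert hist.sum() == pytest.approx(daily + nocturnal, abs=1e-9)
            assert hist[5:].sum() == pytest.approx(daily, abs=1e-9)


class TestWeeklyProfile:
    def test_profile_fields_consistent(self, epoch_cohort):
        series_list, _ = epoch_cohort
        profile = build_weekly_profile(series_list[0])
        assert profile.valid_days == 7
        assert profile.total_weekly_mvpa == pytest.approx(
            profile.daily_mvpa.sum()
        )
        assert 0.0 <= profile.nocturnal_activity_fraction <= 1.0

    def test_generated_weekly_median_matches_configured(self):
        from chronoactivity import scenarios
        from chronoactivity.simulate import generate_phenotype_cohort

        config = scenarios.null_config(n=5_000, seed=77)
        cohort, _ = generate_phenotype_cohort(config)
        median = cohort["weekly_mvpa_min"].median()
        assert abs(median - 113.83) / 113.83 < 0.10
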