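"""Determinism, planted structure, and survival laws of the generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from chronoactivity import scenarios
from chronoactivity.mvpa import detect_moderate_sessions, detect_vigorous_epochs
from chronoactivity.simulate import (
    ConfigurationError,
    SimulationConfig,
    generate_epoch_cohort,
    generate_phenotype_cohort,
    generate_survival,
)
from chronoactivity.timing import MIXED


def small_config(**overrides):
    base = dict(
        n_participants=10,
        seed=1,
        archetype_mix=scenarios.timing_group_mix(),
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            small_config(archetype_mix={"morning": 0.5, MIXED: 0.4})

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown archetypes"):
            small_config(archetype_mix={"dawn": 1.0})

    def test_concentration_bounds(self):
        with pytest.raises(ConfigurationError, match="concentration"):
            small_config(concentration=1.2)

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ConfigurationError, match="positive"):
            small_config(baseline_hazard={"all_cause": 0.0})

    def test_epoch_cohort_size_cap(self):
        with pytest.raises(ConfigurationError, match="cap"):
            generate_epoch_cohort(small_config(), 20_000)

    def test_missing_planted_group_is_error(self):
        config = small_config(
            n_participants=200,
            planted_log_hr={"all_cause": {"morning": 0.0, MIXED: 0.1}},
        )
        cohort, _ = generate_phenotype_cohort(config)
        with pytest.raises(ConfigurationError, match="missing groups"):
            generate_survival(cohort, config)


class TestDeterminism:
    def test_epoch_traces_identical_under_same_seed(self):
        config = small_config(n_participants=3)
        series_a, _ = generate_epoch_cohort(config, 3)
        series_b, _ = generate_epoch_cohort(config, 3)
        for a, b in zip(series_a, series_b):
            np.testing.assert_array_equal(a.vm, b.vm)

    def test_phenotype_cohort_identical_under_same_seed(self):
        config = small_config(n_participants=500)
        a, _ = generate_phenotype_cohort(config)
        b, _ = generate_phenotype_cohort(config)
        pd.testing.assert_frame_equal(a, b)

    def test_survival_identical_under_same_seed(self):
        config = small_config(n_participants=500)
        cohort, _ = generate_phenotype_cohort(config)
        pd.testing.assert_frame_equal(
            generate_survival(cohort, config), generate_survival(cohort, config)
        )


class TestEpochLevelStructure:
    def test_degenerate_concentration_all_mvpa_in_window(self):
        config = small_config(
            n_participants=3,
            archetype_mix={"morning": 1.0},
            concentration=1.0,
            nonwear_rate=0.0,
        )
        series_list, _ = generate_epoch_cohort(config, 3)
        for series in series_list:
            hours = series.clock_slots() // 720
            for s in detect_moderate_sessions(series):
                assert 5 <= hours[s] < 11
            for v in detect_vigorous_epochs(series):
                assert 5 <= hours[v] < 11

    def test_mixed_archetype_never_reaches_half(self):
        from chronoactivity.mvpa import build_weekly_profile
        from chronoactivity.timing import assign_group, window_fractions

        config = small_config(
            n_participants=5,
            archetype_mix={MIXED: 1.0},
            concentration=1 / 3,
            nonwear_rate=0.0,
        )
        series_list, _ = generate_epoch_cohort(config, 5)
        for series in series_list:
            profile = build_weekly_profile(series)
            fracs = window_fractions(profile.hourly_mvpa)
            assert fracs.max() < 0.5
            assert assign_group(fracs) == MIXED

    def test_night_is_near_rest_without_outliers(self):
        config = small_config(n_participants=3, nonwear_rate=0.0)
        series_list, _ = generate_epoch_cohort(config, 3)
        for series in series_list:
            hours = series.clock_slots() // 720
            night = series.vm[(hours >= 1) & (hours < 4)]
            day = series.vm[(hours >= 8) & (hours < 22)]
            assert np.median(night) < 10.0 < np.median(day) + 20.0
            assert night.mean() < day.mean()


class TestPhenotypeLevelStructure:
    def test_group_counts_match_mix_within_binomial_bounds(self):
        config = SimulationConfig(
            n_participants=50_000, seed=42, archetype_mix=scenarios.timing_group_mix()
        )
        cohort, _ = generate_phenotype_cohort(config)
        counts = cohort["timing_group"].value_counts()
        n = config.n_participants
        for group, p in scenarios.timing_group_mix().items():
            half_width = 2.576 * np.sqrt(n * p * (1 - p))  # binomial 99% bounds
            assert abs(counts[group] - n * p) < half_width

    def test_fractions_partition_the_day(self):
        config = small_config(n_participants=2_000)
        cohort, _ = generate_phenotype_cohort(config)
        total = (
            cohort[["fraction_morning", "fraction_midday_afternoon", "fraction_evening"]]
            .sum(axis=1)
            .to_numpy()
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_pure_mix_yields_single_group(self):
        config = small_config(n_participants=300, archetype_mix={"morning": 1.0})
        cohort, _ = generate_phenotype_cohort(config)
        assert (cohort["timing_group"] == "morning").all()

    def test_groups_consistent_with_archetypes(self):
        config = small_config(n_participants=5_000)
        cohort, truth = generate_phenotype_cohort(config)
        assert (cohort["timing_group"].to_numpy() == truth.table["archetype"].to_numpy()).all()


class TestSurvivalLaw:
    def test_null_model_event_rates_equal_across_groups(self, null_cohort):
        events = null_cohort["event_cause"] != "none"
        rates = events.groupby(null_cohort["timing_group"]).mean()
        assert rates.max() - rates.min() < 0.012  # sampling error at n=20k

    def test_doubling_baseline_hazard_doubles_events(self):
        config = small_config(
            n_participants=40_000, baseline_hazard={"all_cause": 0.002}
        )
        doubled = dataclasses.replace(
            config, baseline_hazard={"all_cause": 0.004}, seed=config.seed
        )
        cohort, _ = generate_phenotype_cohort(config)
        e1 = (generate_survival(cohort, config)["event_cause"] != "none").mean()
        e2 = (generate_survival(cohort, doubled)["event_cause"] != "none").mean()
        # expected 1-exp(-2h t) vs 1-exp(-h t): ratio ~1.99 in the small-hazard limit
        assert e2 / e1 == pytest.approx(2.0, rel=0.08)

    def test_planted_half_hazard_gives_half_crude_rate(self):
        config = small_config(
            n_participants=60_000,
            archetype_mix={"morning": 0.5, MIXED: 0.5},
            planted_log_hr={"all_cause": {"morning": 0.0, MIXED: float(np.log(0.5))}},
            baseline_hazard={"all_cause": 0.004},
        )
        cohort, _ = generate_phenotype_cohort(config)
        cohort = generate_survival(cohort, config)
        events = cohort["event_cause"] != "none"
        rate = events.groupby(cohort["timing_group"]).mean()
        assert rate[MIXED] / rate["morning"] == pytest.approx(0.5, rel=0.12)

    def test_followup_positive_and_capped(self, null_cohort):
        assert (null_cohort["followup_years"] > 0).all()
        assert (null_cohort["followup_years"] <= 7.0).all()
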