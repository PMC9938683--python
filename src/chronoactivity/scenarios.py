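"""Reference simulation scenarios with published-scale planted truth.

The package cannot ship the controlled-access cohort it emulates, so its
benchmark experiments plant the published UK Biobank-scale quantities as
simulation ground truth: the four timing groups' relative sizes, the
reported fully adjusted (model-3) hazard ratios versus the morning group,
the 7-year event rates, and the weekly-MVPA distribution.  Recovery of
those planted values by the estimation stack is then a checkable claim.
"""

from __future__ import annotations

import numpy as np

from .simulate import SimulationConfig
from .timing import EXPLORATORY_GRID, MIXED

#: Relative sizes of the four timing groups (counts 15,865 / 41,125 /
#: 8,307 / 26,842 of 92,139).
TIMING_GROUP_COUNTS = {
    "morning": 15_865,
    "midday_afternoon": 41_125,
    "evening": 8_307,
    MIXED: 26_842,
}
COHORT_N = 92_139

#: Fully adjusted (model-3) hazard ratios versus the morning group.
MODEL3_HAZARD_RATIOS = {
    "all_cause": {"morning": 1.0, "midday_afternoon": 0.89, "evening": 0.98, MIXED: 0.89},
    "cvd": {"morning": 1.0, "midday_afternoon": 0.72, "evening": 0.87, MIXED: 0.74},
    "cancer": {"morning": 1.0, "midday_afternoon": 0.97, "evening": 1.07, MIXED: 0.96},
}

#: Seven-year cumulative event rates (3088 / 1076 / 1872 of 92,139).
SEVEN_YEAR_EVENT_RATE = {"all_cause": 0.0335, "cvd": 0.0117, "cancer": 0.0203}
FOLLOWUP_YEARS = 7.0

#: Window-discovery experiment: excess hazard planted on every 2-h group
#: inside the morning (05-11) and evening (17-24) windows, null in between.
DISCOVERY_ELEVATED_WINDOWS = ("w05_07", "w07_09", "w09_11", "w17_19", "w19_21", "w21_24")
DISCOVERY_PLANTED_HR = 2.0
TRUE_CHANGE_POINTS = (11, 17)


def timing_group_mix() -> dict:
    return {g: c / COHORT_N for g, c in TIMING_GROUP_COUNTS.items()}


def _solve_baseline(rate_7y: float, mix: dict, hrs: dict) -> float:
    """Reference-group hazard giving the target 7-y cumulative event rate."""
    mean_hr = sum(mix[g] * hrs.get(g, 1.0) for g in mix)
    return rate_7y / (FOLLOWUP_YEARS * mean_hr)


def recovery_config(outcome: str, n: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Planted-HR recovery scenario for one mortality outcome.

    The outcome's model-3 hazard ratios are planted as cause-specific truth
    at the published group mix and 7-year event rate; for cause-specific
    outcomes a null competing other-cause hazard tops mortality up to the
    all-cause rate.
    """
    mix = timing_group_mix()
    hrs = MODEL3_HAZARD_RATIOS[outcome]
    baseline = {outcome: _solve_baseline(SEVEN_YEAR_EVENT_RATE[outcome], mix, hrs)}
    planted = {outcome: {g: float(np.log(h)) for g, h in hrs.items()}}
    if outcome != "all_cause":
        other_rate = SEVEN_YEAR_EVENT_RATE["all_cause"] - SEVEN_YEAR_EVENT_RATE[outcome]
        baseline["other"] = other_rate / FOLLOWUP_YEARS
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        archetype_mix=mix,
        planted_log_hr=planted,
        baseline_hazard=baseline,
        followup_years=FOLLOWUP_YEARS,
    )


def null_config(n: int = 5_000, seed: int = 0) -> SimulationConfig:
    """Global-null cohort: three causes, no planted effects anywhere."""
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        archetype_mix=timing_group_mix(),
        baseline_hazard={
            "cvd": SEVEN_YEAR_EVENT_RATE["cvd"] / FOLLOWUP_YEARS,
            "cancer": SEVEN_YEAR_EVENT_RATE["cancer"] / FOLLOWUP_YEARS,
            "other": (
                SEVEN_YEAR_EVENT_RATE["all_cause"]
                - SEVEN_YEAR_EVENT_RATE["cvd"]
                - SEVEN_YEAR_EVENT_RATE["cancer"]
            )
            / FOLLOWUP_YEARS,
        },
        followup_years=FOLLOWUP_YEARS,
    )


def discovery_config(
    n: int = 50_000, seed: int = 0, planted_hr: float = DISCOVERY_PLANTED_HR
) -> SimulationConfig:
    """2-h-grid scenario with excess hazard inside morning and evening.

    Half the cohort is mixed (the scan's reference); the nine small-window
    groups share the rest equally.  Groups inside 05-11 and 17-24 carry the
    planted hazard ratio versus mixed, the midday-afternoon groups are null.
    """
    grid = EXPLORATORY_GRID
    mix = {MIXED: 0.5}
    share = 0.5 / grid.n_windows
    for lab in grid.labels:
        mix[lab] = share
    hrs = {
        lab: (planted_hr if lab in DISCOVERY_ELEVATED_WINDOWS else 1.0)
        for lab in grid.labels
    }
    hrs[MIXED] = 1.0
    mean_hr = sum(mix[g] * hrs[g] for g in mix)
    baseline = SEVEN_YEAR_EVENT_RATE["all_cause"] / (FOLLOWUP_YEARS * mean_hr)
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        archetype_mix=mix,
        windows=grid,
        cutoff_strict=True,
        planted_log_hr={"all_cause": {g: float(np.log(h)) for g, h in hrs.items()}},
        baseline_hazard={"all_cause": baseline},
        followup_years=FOLLOWUP_YEARS,
    )


def epoch_cohort_config(
    n: int = 200,
    seed: int = 0,
    concentration: float = 0.7,
    nocturnal_outlier_rate: float = 0.0,
) -> SimulationConfig:
    """Epoch-level scenario at the published group mix."""
    return SimulationConfig(
        n_participants=n,
        seed=seed,
        archetype_mix=timing_group_mix(),
        concentration=concentration,
        nocturnal_outlier_rate=nocturnal_outlier_rate,
    )
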