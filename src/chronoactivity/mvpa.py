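"""Moderate-to-vigorous physical activity (MVPA) from epoch series.

MVPA minutes are assembled from two components:

* moderate sessions - disjoint, clock-aligned 5-min blocks in which strictly
  more than 80% of the sixty 5-s epochs have mean acceleration in the closed
  100-400 mg band;
* vigorous epochs - individual 5-s epochs strictly above 400 mg.

Daily totals count only activity between 05:00 and 24:00; activity in the
00:00-05:00 window is tracked separately for the nocturnal-lifestyle filter.
Weekly volume is extrapolated to seven days when fewer days are valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_HOUR,
    EpochSeries,
)

SESSION_MINUTES = 5
SESSION_EPOCHS = 60
#: Closed moderate band and strict vigorous threshold partition intensity
#: at 400 mg: moderate includes it, vigorous excludes it.
MODERATE_RANGE_MG = (100.0, 400.0)
VIGOROUS_THRESHOLD_MG = 400.0
SESSION_MIN_FRACTION = 0.8  # strictly more than 80% of epochs in band
DAY_WINDOW_HOURS = (5, 24)
NOCTURNAL_HOURS = (1, 4)  # activity between 01:00 and 04:00
DEFAULT_VALID_DAY_HOURS = 12.0


@dataclass
class WeeklyActivityProfile:
    """Per-participant MVPA summary over the wear period.

    ``hourly_mvpa`` covers all 24 clock hours (including 00:00-05:00, needed
    by the nocturnal filter) while ``daily_mvpa`` and ``total_weekly_mvpa``
    count the 05:00-24:00 window only.  ``hourly_activity`` is the
    acceleration-weighted activity (sum of VM) per clock hour, the default
    basis of the nocturnal filter.
    """

    participant_id: str
    daily_mvpa: np.ndarray
    hourly_mvpa: np.ndarray
    hourly_activity: np.ndarray
    total_weekly_mvpa: float
    nocturnal_activity_fraction: float
    nocturnal_mvpa_fraction: float
    valid_days: int


def detect_moderate_sessions(
    series: EpochSeries,
    moderate_range: tuple = MODERATE_RANGE_MG,
) -> np.ndarray:
    """Indices (into the series) of the first epoch of each moderate session.

    Sessions are disjoint 5-min blocks aligned to the clock (05:00:00,
    05:05:00, ...), not sliding windows; a block qualifies when strictly more
    than 80% of its 60 epochs lie inside the closed moderate band.
    """
    lo, hi = moderate_range
    n = series.n_epochs
    first = (-series.clock_offset) % SESSION_EPOCHS
    n_blocks = (n - first) // SESSION_EPOCHS
    if n_blocks <= 0:
        return np.empty(0, dtype=np.int64)
    in_band = (series.vm >= lo) & (series.vm <= hi)
    counts = (
        in_band[first : first + n_blocks * SESSION_EPOCHS]
        .reshape(n_blocks, SESSION_EPOCHS)
        .sum(axis=1)
    )
    qualifies = counts > SESSION_MIN_FRACTION * SESSION_EPOCHS
    return first + SESSION_EPOCHS * np.flatnonzero(qualifies)


def detect_vigorous_epochs(
    series: EpochSeries, threshold: float = VIGOROUS_THRESHOLD_MG
) -> np.ndarray:
    """Indices of epochs with mean acceleration strictly above ``threshold``."""
    return np.flatnonzero(series.vm > threshold)


def session_cover_mask(series: EpochSeries, sessions: np.ndarray) -> np.ndarray:
    """Boolean mask of epochs that fall inside a detected moderate session."""
    mask = np.zeros(series.n_epochs, dtype=bool)
    for s in np.asarray(sessions, dtype=np.int64):
        mask[s : s + SESSION_EPOCHS] = True
    return mask


def _standalone_vigorous(series, sessions, vigorous) -> np.ndarray:
    """Vigorous epochs not absorbed by a moderate session (no double count)."""
    vigorous = np.asarray(vigorous, dtype=np.int64)
    if vigorous.size == 0 or len(sessions) == 0:
        return vigorous
    cover = session_cover_mask(series, sessions)
    return vigorous[~cover[vigorous]]


def daily_mvpa_minutes(
    series: EpochSeries,
    sessions: np.ndarray,
    vigorous: np.ndarray,
    day: int,
) -> float:
    """MVPA minutes accumulated between 05:00 and 24:00 on one calendar day.

    Sessions are attributed to the day and time window of their start epoch;
    standalone vigorous epochs each contribute 5 s.  Activity between 00:00
    and 05:00 contributes nothing.
    """
    sessions = np.asarray(sessions, dtype=np.int64)
    days = series.day_indices()
    hours = series.clock_slots() // EPOCHS_PER_HOUR
    lo, hi = DAY_WINDOW_HOURS
    sess = sessions[
        (days[sessions] == day) & (hours[sessions] >= lo) & (hours[sessions] < hi)
    ]
    vig = _standalone_vigorous(series, sessions, vigorous)
    vig = vig[(days[vig] == day) & (hours[vig] >= lo) & (hours[vig] < hi)]
    return SESSION_MINUTES * len(sess) + len(vig) * series.epoch_seconds / 60.0


def weekly_mvpa(daily_minutes: np.ndarray, valid_days: np.ndarray) -> float:
    """Extrapolate daily MVPA on the valid days to a 7-day total.

    ``total = (sum over valid days / number of valid days) * 7``; with seven
    valid days this is the plain sum.
    """
    valid_days = np.asarray(valid_days, dtype=bool)
    n_valid = int(valid_days.sum())
    if n_valid == 0:
        raise ValueError("no valid days; weekly MVPA undefined")
    return float(np.asarray(daily_minutes)[valid_days].sum()) / n_valid * 7.0


def hourly_histogram(
    series: EpochSeries, sessions: np.ndarray, vigorous: np.ndarray
) -> np.ndarray:
    """MVPA minutes per clock hour (24-vector), all days pooled.

    Each session minute is attributed to the clock hour containing its
    midpoint; each standalone vigorous epoch contributes 1/12 min at its own
    midpoint.  The histogram covers the whole 24-h cycle, so its total equals
    the (pre-extrapolation) daily totals plus any 00:00-05:00 MVPA.
    """
    hist = np.zeros(24, dtype=np.float64)
    sessions = np.asarray(sessions, dtype=np.int64)
    slots = series.clock_slots()
    if sessions.size:
        # minute midpoints sit 6, 18, 30, 42, 54 epochs into the block
        mids = (
            slots[sessions][:, None] + (np.arange(SESSION_MINUTES) * 12 + 6)[None, :]
        ) % EPOCHS_PER_DAY
        np.add.at(hist, mids // EPOCHS_PER_HOUR, 1.0)
    vig = _standalone_vigorous(series, sessions, vigorous)
    if vig.size:
        np.add.at(hist, slots[vig] // EPOCHS_PER_HOUR, series.epoch_seconds / 60.0)
    return hist


def build_weekly_profile(
    series: EpochSeries,
    valid_day_min_hours: float = DEFAULT_VALID_DAY_HOURS,
) -> WeeklyActivityProfile:
    """Run the full MVPA summarisation for one (imputed) series.

    A calendar day is valid when it carries at least ``valid_day_min_hours``
    of wear; weekly volume is extrapolated over the valid days.
    """
    sessions = detect_moderate_sessions(series)
    vigorous = detect_vigorous_epochs(series)
    days = series.day_indices()
    n_days = series.n_days
    wear_hours_per_day = (
        np.bincount(days[series.wear], minlength=n_days) * series.epoch_seconds / 3600.0
    )
    valid = wear_hours_per_day >= valid_day_min_hours
    daily = np.array(
        [daily_mvpa_minutes(series, sessions, vigorous, d) for d in range(n_days)]
    )
    total = weekly_mvpa(daily, valid)
    hist = hourly_histogram(series, sessions, vigorous)
    hourly_vm = np.bincount(
        series.clock_slots() // EPOCHS_PER_HOUR, weights=series.vm, minlength=24
    )
    lo, hi = NOCTURNAL_HOURS
    total_vm = hourly_vm.sum()
    total_mvpa = hist.sum()
    noct_vm = hourly_vm[lo:hi].sum() / total_vm if total_vm > 0 else float("nan")
    noct_mvpa = hist[lo:hi].sum() / total_mvpa if total_mvpa > 0 else float("nan")
    return WeeklyActivityProfile(
        participant_id=series.participant_id,
        daily_mvpa=daily,
        hourly_mvpa=hist,
        hourly_activity=hourly_vm,
        total_weekly_mvpa=total,
        nocturnal_activity_fraction=float(noct_vm),
        nocturnal_mvpa_fraction=float(noct_mvpa),
        valid_days=int(valid.sum()),
    )
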