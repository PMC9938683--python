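"""Quality control for 5-second wrist-accelerometer epoch series.

The substrate for the whole pipeline is the per-participant vector-magnitude
(VM) trace in milligravity (mg), one value per 5-s epoch over a nominal
7-day wear period.  This module implements the three epoch-level QC steps
used by large accelerometer cohorts:

* non-wear detection - maximal stationary runs of at least one hour whose
  rolling VM standard deviation stays below 13.0 mg are flagged as the
  device being off;
* non-wear imputation - each non-wear epoch is replaced by the mean of
  wear-time values observed at the same clock slot on the other recorded
  days ("similar time of day" imputation);
* validity assessment - a recording is analysable only if it carries at
  least 72 h of wear and covers every 1-h clock bin of the 24-h cycle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 5
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS
EPOCHS_PER_DAY = 24 * EPOCHS_PER_HOUR

#: Non-wear rule defaults: stationary episodes of >= 1 h with VM standard
#: deviation below 13.0 mg.
NONWEAR_SD_THRESHOLD_MG = 13.0
NONWEAR_MIN_HOURS = 1.0

#: Validity rule defaults: >= 72 h of wear covering all 24 clock-hour bins.
MIN_WEAR_HOURS = 72.0
REQUIRED_HOUR_BINS = 24


class ImputationImpossibleError(ValueError):
    """A clock slot is non-wear on every recorded day and cannot be imputed."""


@dataclass
class EpochSeries:
    """A uniformly spaced 5-s epoch vector-magnitude trace.

    Gaps are represented as non-wear epochs, never as missing rows, so the
    trace is always contiguous from ``start``.
    """

    participant_id: str
    start: pd.Timestamp
    vm: np.ndarray
    wear: np.ndarray = None
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.vm = np.asarray(self.vm, dtype=np.float64)
        if self.vm.ndim != 1:
            raise ValueError("vm must be one-dimensional")
        if self.vm.size and self.vm.min() < 0:
            raise ValueError("vector-magnitude values must be >= 0")
        offset_s = (self.start - self.start.normalize()).total_seconds()
        if offset_s % self.epoch_seconds:
            raise ValueError("start must be aligned to the epoch grid")
        if self.wear is None:
            self.wear = np.ones(self.vm.size, dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
            if self.wear.shape != self.vm.shape:
                raise ValueError("wear mask must align with vm")

    @property
    def n_epochs(self) -> int:
        return self.vm.size

    @property
    def clock_offset(self) -> int:
        """Index of the first epoch within its day (0 .. EPOCHS_PER_DAY-1)."""
        offset_s = (self.start - self.start.normalize()).total_seconds()
        return int(offset_s) // self.epoch_seconds

    def clock_slots(self) -> np.ndarray:
        """Per-epoch clock slot (position within the 24-h cycle)."""
        return (self.clock_offset + np.arange(self.n_epochs)) % EPOCHS_PER_DAY

    def day_indices(self) -> np.ndarray:
        """Per-epoch calendar-day index counted from the day of ``start``."""
        return (self.clock_offset + np.arange(self.n_epochs)) // EPOCHS_PER_DAY

    @property
    def n_days(self) -> int:
        return int(self.day_indices()[-1]) + 1 if self.n_epochs else 0


@dataclass
class QCReport:
    participant_id: str
    wear_hours: float
    hour_bins_covered: int
    valid: bool
    reasons: list = field(default_factory=list)


def detect_nonwear(
    series: EpochSeries,
    sd_threshold: float = NONWEAR_SD_THRESHOLD_MG,
    min_hours: float = NONWEAR_MIN_HOURS,
) -> np.ndarray:
    """Return a boolean wear mask (True = worn).

    An epoch is non-wear when it lies inside at least one window of
    ``min_hours`` whose population standard deviation of VM is strictly
    below ``sd_threshold``; the union of such windows forms the maximal
    stationary runs.  Raw UK-style pipelines apply this rule per axis on
    the raw signal; with only epoch-level VM available, the same 13.0 mg
    threshold is applied to the rolling VM dispersion.
    """
    vm = series.vm.astype(np.float64)
    n = vm.size
    w = int(round(min_hours * EPOCHS_PER_HOUR))
    if n < w:
        logger.warning(
            "series %s shorter than the %s h non-wear window; all wear",
            series.participant_id,
            min_hours,
        )
        return np.ones(n, dtype=bool)
    c1 = np.concatenate(([0.0], np.cumsum(vm)))
    c2 = np.concatenate(([0.0], np.cumsum(vm * vm)))
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    stationary_starts = np.flatnonzero(var < sd_threshold**2)
    delta = np.zeros(n + 1, dtype=np.int64)
    np.add.at(delta, stationary_starts, 1)
    np.add.at(delta, stationary_starts + w, -1)
    nonwear = np.cumsum(delta[:-1]) > 0
    return ~nonwear


def impute_nonwear(series: EpochSeries, wear: np.ndarray = None) -> EpochSeries:
    """Impute non-wear VM from same-clock-slot wear data on other days.

    Each non-wear epoch is replaced by the mean of wear-epoch VM observed at
    the identical 5-s clock slot across the recording (each slot occurs once
    per day, so this is the mean over the other worn days).  Wear epochs are
    untouched.  A slot that is non-wear on every day cannot be imputed and
    raises :class:`ImputationImpossibleError`; such a participant should be
    failing QC instead.
    """
    wear = series.wear if wear is None else np.asarray(wear, dtype=bool)
    if wear.shape != series.vm.shape:
        raise ValueError("wear mask must align with series")
    if wear.all():
        return dataclasses.replace(series, vm=series.vm.copy(), wear=wear.copy())
    slots = series.clock_slots()
    sums = np.bincount(slots[wear], weights=series.vm[wear], minlength=EPOCHS_PER_DAY)
    counts = np.bincount(slots[wear], minlength=EPOCHS_PER_DAY)
    need = ~wear
    bad = np.unique(slots[need][counts[slots[need]] == 0])
    if bad.size:
        times = ", ".join(
            f"{(s * EPOCH_SECONDS) // 3600:02d}:{((s * EPOCH_SECONDS) % 3600) // 60:02d}:{(s * EPOCH_SECONDS) % 60:02d}"
            for s in bad[:5]
        )
        raise ImputationImpossibleError(
            f"participant {series.participant_id}: {bad.size} clock slot(s) "
            f"non-wear on every day (first: {times}); cannot impute"
        )
    vm = series.vm.copy()
    vm[need] = sums[slots[need]] / counts[slots[need]]
    return dataclasses.replace(series, vm=vm, wear=wear.copy())


def qc_validity(series: EpochSeries, wear: np.ndarray = None) -> QCReport:
    """Assess analysability from the wear mask alone.

    Valid iff wear time is at least 72 h and every 1-h clock bin of the
    24-h cycle holds at least one wear epoch.
    """
    wear = series.wear if wear is None else np.asarray(wear, dtype=bool)
    wear_hours = float(wear.sum()) * series.epoch_seconds / 3600.0
    hours = series.clock_slots() // EPOCHS_PER_HOUR
    covered = int(np.unique(hours[wear]).size) if wear.any() else 0
    reasons = []
    if wear_hours < MIN_WEAR_HOURS:
        reasons.append(f"wear < {MIN_WEAR_HOURS:.0f} h")
    if covered < REQUIRED_HOUR_BINS:
        reasons.append("hour bin uncovered")
    return QCReport(
        participant_id=series.participant_id,
        wear_hours=wear_hours,
        hour_bins_covered=covered,
        valid=not reasons,
        reasons=reasons,
    )
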