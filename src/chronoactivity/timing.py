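"""MVPA timing phenotype: window fractions, group assignment, nocturnal filter.

The day window 05:00-24:00 is partitioned into ordered timing windows
(default morning 05-11, midday-afternoon 11-17, evening 17-24).  A
participant whose dominant window holds at least the cutoff fraction
(default 50%) of their 05:00-24:00 MVPA belongs to that window's group;
everyone else is "mixed".  Participants with a high nocturnal activity share
(>10% of activity between 01:00 and 04:00) are excluded upstream as
non-diurnal.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIXED = "mixed"
DEFAULT_CUTOFF = 0.50
SENSITIVITY_CUTOFFS = (0.50, 0.55, 0.60, 0.65, 0.70)
NOCTURNAL_THRESHOLD = 0.10


class ZeroMVPAError(ValueError):
    """Window fractions are undefined when 05:00-24:00 MVPA is zero."""


@dataclass(frozen=True)
class TimingWindows:
    """Ordered clock-hour boundaries partitioning 05:00-24:00.

    ``boundaries = (5, 11, 17, 24)`` defines morning [05,11),
    midday-afternoon [11,17) and evening [17,24).
    """

    boundaries: tuple = (5, 11, 17, 24)
    labels: tuple = None

    def __post_init__(self):
        b = tuple(self.boundaries)
        if list(b) != sorted(set(b)):
            raise ValueError("boundaries must be strictly increasing")
        if b[0] < 5 or b[-1] != 24:
            raise ValueError("windows must partition 05:00-24:00")
        object.__setattr__(self, "boundaries", b)
        if self.labels is None:
            if b == (5, 11, 17, 24):
                labels = ("morning", "midday_afternoon", "evening")
            else:
                labels = tuple(
                    f"w{a:02d}_{z:02d}" for a, z in zip(b[:-1], b[1:])
                )
            object.__setattr__(self, "labels", labels)
        elif len(self.labels) != len(b) - 1:
            raise ValueError("one label per window required")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries) - 1

    def spans(self):
        return list(zip(self.boundaries[:-1], self.boundaries[1:]))

    def groups(self) -> tuple:
        """All assignable group labels, mixed last."""
        return self.labels + (MIXED,)


DEFAULT_WINDOWS = TimingWindows()
#: 2-h exploratory grid (3-h only for the 21:00-24:00 period).
EXPLORATORY_GRID = TimingWindows((5, 7, 9, 11, 13, 15, 17, 19, 21, 24))


def window_fractions(
    hourly_mvpa: np.ndarray, windows: TimingWindows = DEFAULT_WINDOWS
) -> np.ndarray:
    """Fraction of 05:00-24:00 MVPA falling in each timing window."""
    hourly = np.asarray(hourly_mvpa, dtype=np.float64)
    if hourly.shape[-1] != 24:
        raise ValueError("hourly histogram must have 24 bins")
    denom = hourly[..., 5:24].sum(axis=-1)
    if np.any(denom <= 0):
        raise ZeroMVPAError(
            "zero MVPA in 05:00-24:00; fractions undefined "
            "(route participant to the zero-MVPA stratum)"
        )
    parts = np.stack(
        [hourly[..., a:z].sum(axis=-1) for a, z in windows.spans()], axis=-1
    )
    return parts / denom[..., None]


def assign_group(
    fractions: np.ndarray,
    windows: TimingWindows = DEFAULT_WINDOWS,
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> str:
    """Assign the timing group from window fractions.

    The group is the unique window whose fraction reaches the cutoff
    (``>=`` by default, ``>`` when ``strict``, as in the exploratory 2-h
    scan); otherwise mixed.  A tie at the cutoff (possible only at 0.50)
    falls to mixed, which is by definition the no-dominant-window category.
    """
    f = np.asarray(fractions, dtype=np.float64)
    if f.size != windows.n_windows:
        raise ValueError("one fraction per window required")
    winners = f > cutoff if strict else f >= cutoff
    n_win = int(winners.sum())
    if n_win == 1:
        return windows.labels[int(np.argmax(winners))]
    if n_win > 1:
        logger.info("tie at cutoff %.2f; assigning mixed", cutoff)
    return MIXED


def assign_groups(
    fractions: np.ndarray,
    windows: TimingWindows = DEFAULT_WINDOWS,
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> np.ndarray:
    """Vectorised :func:`assign_group` over an (n, k) fraction matrix."""
    f = np.asarray(fractions, dtype=np.float64)
    winners = f > cutoff if strict else f >= cutoff
    n_win = winners.sum(axis=1)
    labels = np.array(windows.labels, dtype=object)
    out = np.full(f.shape[0], MIXED, dtype=object)
    unique = n_win == 1
    out[unique] = labels[np.argmax(winners[unique], axis=1)]
    return out


def nocturnal_filter(
    nocturnal_fraction: float, threshold: float = NOCTURNAL_THRESHOLD
) -> tuple:
    """Keep/exclude decision for the diurnal-lifestyle criterion.

    Excluded iff the 01:00-04:00 activity share strictly exceeds the
    threshold (a share of exactly 10% is kept).  An undefined share (no
    recorded activity at all) is excluded with reason "no activity".
    """
    if nocturnal_fraction is None or np.isnan(nocturnal_fraction):
        return False, "no activity"
    if nocturnal_fraction > threshold:
        return False, f"nocturnal activity share {nocturnal_fraction:.3f} > {threshold}"
    return True, ""


def phenotype_table(
    hourly: np.ndarray,
    windows: TimingWindows = DEFAULT_WINDOWS,
    cutoff: float = DEFAULT_CUTOFF,
    strict: bool = False,
) -> pd.DataFrame:
    """Fractions and group for an (n, 24) hourly-MVPA matrix."""
    fracs = window_fractions(hourly, windows)
    groups = assign_groups(fracs, windows, cutoff, strict)
    out = pd.DataFrame(
        fracs, columns=[f"fraction_{lab}" for lab in windows.labels]
    )
    out["timing_group"] = groups
    return out
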