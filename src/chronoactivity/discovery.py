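"""Outcome-based discovery of timing-window boundaries.

The three analysis windows (05-11, 11-17, 17-24) are not imposed a priori:
they emerge from an exploratory scan in which participants are grouped by
the 2-h window holding over 50% of their MVPA (3-h for 21:00-24:00), each
small-window group's hazard is estimated against the mixed group, and the
boundaries where the elevated-risk flag flips between consecutive windows
are read off as change points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import build_design, MODEL_COVARIATES, _event_indicator, _fit_cox
from .timing import EXPLORATORY_GRID, MIXED, TimingWindows, assign_groups, window_fractions


@dataclass
class WindowScanResult:
    grid: TimingWindows
    outcome: str
    table: pd.DataFrame  # window, n, events, hr, ci_low, ci_high, p, elevated
    change_points: list = field(default_factory=list)


def assign_small_window_groups(
    cohort: pd.DataFrame,
    grid: TimingWindows = EXPLORATORY_GRID,
    cutoff: float = 0.5,
) -> np.ndarray:
    """Group labels over the exploratory grid (strict >50% rule).

    Participants whose dominant small window holds over half of their
    05:00-24:00 MVPA get that window's label; the remainder are mixed.
    """
    hourly = cohort[[f"hourly_mvpa_{h:02d}" for h in range(24)]].to_numpy(dtype=float)
    fracs = window_fractions(hourly, grid)
    return assign_groups(fracs, grid, cutoff, strict=True)


def scan_windows(
    cohort: pd.DataFrame,
    outcome: str,
    grid: TimingWindows = EXPLORATORY_GRID,
    model_level: int = 0,
    elevated_rule: str = "point",
    ci_alpha: float = 0.05,
    labels: np.ndarray = None,
) -> WindowScanResult:
    """One Cox fit per small-window group against the mixed reference.

    ``elevated_rule='point'`` flags a window when its point HR exceeds 1
    (the qualitative reading of "higher risk"); ``'ci'`` demands the lower
    ``1-ci_alpha`` confidence bound to exceed 1, the conservative variant
    used when planted-signal recovery must ignore estimation noise.
    Windows with zero events are flagged unstable and excluded from the
    change-point logic.
    """
    if elevated_rule not in ("point", "ci"):
        raise ValueError("elevated_rule must be 'point' or 'ci'")
    if labels is None:
        labels = assign_small_window_groups(cohort, grid)
    labels = np.asarray(labels, dtype=object)
    event = _event_indicator(cohort, outcome)
    time = cohort["followup_years"].to_numpy(dtype=float)
    covars = build_design(cohort, MODEL_COVARIATES[model_level])
    z = float(-stats.norm.ppf(ci_alpha / 2.0))

    mixed_mask = labels == MIXED
    if not mixed_mask.any():
        raise ValueError("no mixed-group participants to serve as reference")
    rows = []
    for lab in grid.labels:
        in_group = labels == lab
        sel = in_group | mixed_mask
        n_events_group = int(event[in_group].sum())
        row = {
            "window": lab,
            "n": int(in_group.sum()),
            "events": n_events_group,
            "person_years": float(time[in_group].sum()),
        }
        if in_group.sum() == 0 or n_events_group == 0:
            row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       elevated=None, unstable=True)
            rows.append(row)
            continue
        df = covars.loc[sel].copy()
        df["x_window"] = in_group[sel].astype(float)
        df["__time"] = time[sel]
        df["__event"] = event[sel].astype(int)
        cph = _fit_cox(df)
        coef = float(cph.params_.loc["x_window"])
        se = float(cph.standard_errors_.loc["x_window"])
        s = cph.summary.loc["x_window"]
        elevated = (
            coef > 0.0 if elevated_rule == "point" else coef - z * se > 0.0
        )
        row.update(
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z * se)),
            ci_high=float(np.exp(coef + z * se)),
            p=float(s["p"]),
            elevated=bool(elevated),
            unstable=False,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    result = WindowScanResult(grid=grid, outcome=outcome, table=table)
    result.change_points = identify_change_points(result)
    return result


def identify_change_points(scan: WindowScanResult) -> list:
    """Grid boundaries where the elevated flag flips between windows.

    Unstable windows (no events) are skipped; the change point between two
    flanking stable windows with differing flags is placed at the start
    boundary of the later one.  All-equal flags yield an empty list.
    """
    grid = scan.grid
    flags = scan.table["elevated"].tolist()
    starts = grid.boundaries[:-1]
    stable = [(starts[i], flags[i]) for i in range(len(flags)) if flags[i] is not None]
    points = []
    for (h_prev, f_prev), (h_next, f_next) in zip(stable[:-1], stable[1:]):
        if bool(f_prev) != bool(f_next):
            points.append(h_next)
    return points


def consistent_change_points(scans) -> list:
    """Optional cross-outcome intersection of detected change points."""
    sets = [set(identify_change_points(s)) for s in scans]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
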