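"""Synthetic accelerometer cohorts with known ground truth.

Restricted-access cohort data cannot ship with the package, so every
downstream stage is exercised on simulated data whose truth is planted:

* **epoch level** (small n) - full 7-day, 5-s vector-magnitude traces with
  diurnal structure, archetype-driven MVPA placement, inserted non-wear
  episodes and optional nocturnal outliers; used to test the phenotyping
  chain end to end;
* **phenotype level** (survival-scale n) - participants drawn directly at
  the level of hourly MVPA allocations, covariates and exclusion flags,
  skipping epoch simulation; used for planted-hazard recovery experiments;
* **survival** - cause-specific exponential event times under proportional
  hazards with configurable group, MVPA-volume and covariate effects, and
  administrative censoring at the follow-up horizon.

Two-tier generation is deliberate: 7 days x 17,280 epochs x 50,000
participants is not desk scale, while the phenotype-level shortcut keeps
recovery experiments to minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .epochs import EPOCHS_PER_DAY, EPOCHS_PER_HOUR, EpochSeries
from .mvpa import SESSION_EPOCHS, SESSION_MINUTES
from .timing import DEFAULT_WINDOWS, MIXED, TimingWindows, assign_groups, window_fractions


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


#: Marginal covariate distributions emulating a UK middle-aged accelerometer
#: cohort (means/frequencies match the study-population scale this package
#: models).  Values are (kind, *parameters).
DEFAULT_COVARIATE_PARAMS: dict = {
    "age": ("normal", 62.38, 7.84),
    "sex": ("categorical", ("female", "male"), (0.5649, 0.4351)),
    "ethnicity": ("categorical", ("white", "other"), (0.9694, 0.0306)),
    "deprivation": ("normal", -2.45, 2.69),
    "region": ("categorical", ("england", "wales", "scotland"), (0.8977, 0.0374, 0.0649)),
    "education": (
        "categorical",
        ("degree", "other_qualification", "no_qualification"),
        (0.4379, 0.4788, 0.0833),
    ),
    "wear_season": (
        "categorical",
        ("spring", "summer", "autumn", "winter"),
        (0.2257, 0.2612, 0.2994, 0.2137),
    ),
    "smoking": ("categorical", ("never", "previous", "current"), (0.5747, 0.3623, 0.0630)),
    "alcohol": (
        "categorical",
        ("not_current", "two_or_less_weekly", "three_or_more_weekly"),
        (0.0597, 0.4628, 0.4775),
    ),
    "diet_score": ("binomial", 5, 0.538),
    "sleep_duration": ("categorical", ("lt7h", "7to8h", "gt8h"), (0.3446, 0.4581, 0.1973)),
    "sleep_midpoint": (
        "categorical",
        ("before_0230", "0230_to_0330", "after_0330"),
        (0.2586, 0.4670, 0.2744),
    ),
    "obesity": ("bernoulli", 0.1946),
    "diabetes": ("bernoulli", 0.0463),
    "longstanding_illness": ("bernoulli", 0.2940),
    "depression": ("bernoulli", 0.0887),
    "cvd_history": ("bernoulli", 0.2459),
    "cancer_history": ("bernoulli", 0.1457),
}

#: Weekly MVPA volume (min/week) is log-normal; the default median and shape
#: reproduce a median of 113.83 min/week with an IQR of 158.67.
DEFAULT_WEEKLY_MVPA_MEDIAN = 113.83
DEFAULT_WEEKLY_MVPA_SIGMA = 0.9639

MAX_EPOCH_PARTICIPANTS = 10_000
SIMULATED_DAYS = 7


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with a mandatory seed.

    ``archetype_mix`` assigns probabilities to the window labels of
    ``windows`` plus ``"mixed"``.  ``concentration`` is the target share of
    a pure archetype's MVPA placed inside its own window.  Planted effects
    are log hazard ratios versus the reference timing group (morning in the
    default windows); ``baseline_hazard`` is the reference events/person-year
    rate per cause.
    """

    n_participants: int
    seed: int
    archetype_mix: Mapping[str, float]
    windows: TimingWindows = DEFAULT_WINDOWS
    concentration: float = 0.7
    cutoff: float = 0.5
    cutoff_strict: bool = False
    weekly_mvpa_median: float = DEFAULT_WEEKLY_MVPA_MEDIAN
    weekly_mvpa_sigma: float = DEFAULT_WEEKLY_MVPA_SIGMA
    nonwear_rate: float = 1.0
    nocturnal_outlier_rate: float = 0.0
    planted_log_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mvpa_log_hr_per_unit: Mapping[str, float] = field(default_factory=dict)
    covariate_log_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"all_cause": 0.0048}
    )
    followup_years: float = 7.0
    covariate_params: Mapping = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    withdrawal_rate: float = 0.0
    hour_gap_rate: float = 0.0
    invalid_accel_rate: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        valid_groups = set(self.windows.groups())
        unknown = set(self.archetype_mix) - valid_groups
        if unknown:
            raise ConfigurationError(f"unknown archetypes in mix: {sorted(unknown)}")
        probs = np.array(list(self.archetype_mix.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
            raise ConfigurationError("archetype_mix must be non-negative and sum to 1")
        if not 0.0 <= self.concentration <= 1.0:
            raise ConfigurationError("concentration must lie in [0, 1]")
        if any(h <= 0 for h in self.baseline_hazard.values()):
            raise ConfigurationError("baseline hazards must be positive")
        if self.followup_years <= 0:
            raise ConfigurationError("followup_years must be positive")

    def archetypes(self) -> list:
        return list(self.archetype_mix)

    def mix_probs(self) -> np.ndarray:
        return np.array([self.archetype_mix[a] for a in self.archetypes()], dtype=float)


@dataclass
class GroundTruth:
    """Row-aligned truth for a generated cohort."""

    table: pd.DataFrame  # participant_id, archetype, extras
    config: SimulationConfig


# ---------------------------------------------------------------------------
# phenotype-level generation
# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int, params: Mapping) -> pd.DataFrame:
    cols = {}
    for name, spec in params.items():
        kind = spec[0]
        if kind == "normal":
            cols[name] = rng.normal(spec[1], spec[2], n)
        elif kind == "categorical":
            labels, probs = spec[1], np.asarray(spec[2], dtype=float)
            cols[name] = rng.choice(np.array(labels, dtype=object), size=n, p=probs / probs.sum())
        elif kind == "binomial":
            cols[name] = rng.binomial(spec[1], spec[2], n)
        elif kind == "bernoulli":
            cols[name] = rng.random(n) < spec[1]
        else:
            raise ConfigurationError(f"unknown covariate kind {kind!r} for {name!r}")
    return pd.DataFrame(cols)


def _hour_masks(windows: TimingWindows):
    day_hours = np.arange(5, 24)
    masks = [(day_hours >= a) & (day_hours < z) for a, z in windows.spans()]
    return day_hours, masks


def _allocate_hourly(
    rng: np.random.Generator,
    archetypes: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Hourly MVPA weights (n, 24) consistent with each drawn archetype.

    Pure archetypes place a dominant fraction (drawn at or above the cutoff,
    centred on ``concentration``) in their own window; mixed rows are
    resampled until no window reaches the cutoff, so assignment at the
    configured cutoff recovers the archetype by construction.
    """
    n = archetypes.size
    windows = config.windows
    day_hours, masks = _hour_masks(windows)
    weights = rng.gamma(1.5, size=(n, day_hours.size))

    for w_idx, label in enumerate(windows.labels):
        rows = np.flatnonzero(archetypes == label)
        if rows.size == 0:
            continue
        lo = config.cutoff + (0.01 if config.cutoff_strict else 0.0)
        hi = max(min(0.97, 2.0 * config.concentration - config.cutoff), lo + 0.02)
        dom = rng.uniform(lo, hi, rows.size)
        m = masks[w_idx]
        w_in = weights[np.ix_(rows, np.flatnonzero(m))]
        w_out = weights[np.ix_(rows, np.flatnonzero(~m))]
        w_in = w_in / w_in.sum(axis=1, keepdims=True) * dom[:, None]
        w_out = w_out / w_out.sum(axis=1, keepdims=True) * (1.0 - dom)[:, None]
        block = np.empty((rows.size, day_hours.size))
        block[:, np.flatnonzero(m)] = w_in
        block[:, np.flatnonzero(~m)] = w_out
        weights[rows] = block

    mixed_rows = np.flatnonzero(archetypes == MIXED)
    if mixed_rows.size:
        sub = weights[mixed_rows]
        sub = sub / sub.sum(axis=1, keepdims=True)
        for _ in range(200):
            shares = np.stack([sub[:, m].sum(axis=1) for m in masks], axis=1)
            bad = (shares >= config.cutoff - 1e-12).any(axis=1)
            if not bad.any():
                break
            redraw = rng.gamma(1.5, size=(int(bad.sum()), day_hours.size))
            sub[bad] = redraw / redraw.sum(axis=1, keepdims=True)
        weights[mixed_rows] = sub

    pure = archetypes != MIXED
    weights[pure] = weights[pure] / weights[pure].sum(axis=1, keepdims=True)
    out = np.zeros((n, 24))
    out[:, 5:24] = weights
    return out


def generate_phenotype_cohort(config: SimulationConfig):
    """Draw an analysis-scale cohort directly at the phenotype level.

    Returns ``(cohort, truth)`` where the cohort holds hourly MVPA minutes,
    window fractions, the assigned timing group, covariates and exclusion
    flags, and the truth table echoes the drawn archetypes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    archetypes = rng.choice(
        np.array(config.archetypes(), dtype=object), size=n, p=config.mix_probs()
    )
    hourly_weights = _allocate_hourly(rng, archetypes, config)
    weekly = rng.lognormal(np.log(config.weekly_mvpa_median), config.weekly_mvpa_sigma, n)
    hourly_mvpa = hourly_weights * weekly[:, None]

    fracs = window_fractions(hourly_mvpa, config.windows)
    groups = assign_groups(fracs, config.windows, config.cutoff, config.cutoff_strict)

    nocturnal = rng.uniform(0.0, 0.08, n)
    outlier = rng.random(n) < config.nocturnal_outlier_rate
    nocturnal[outlier] = rng.uniform(0.105, 0.35, int(outlier.sum()))

    cohort = pd.DataFrame(
        {
            "participant_id": [f"p{i:06d}" for i in range(n)],
            "timing_group": groups,
            "weekly_mvpa_min": weekly,
            "nocturnal_fraction": nocturnal,
            "withdrawn": rng.random(n) < config.withdrawal_rate,
            "hour_coverage_ok": ~(rng.random(n) < config.hour_gap_rate),
            "valid_accel": ~(rng.random(n) < config.invalid_accel_rate),
        }
    )
    for j, lab in enumerate(config.windows.labels):
        cohort[f"fraction_{lab}"] = fracs[:, j]
        cohort[f"mvpa_{lab}_min"] = fracs[:, j] * weekly
    for h in range(24):
        cohort[f"hourly_mvpa_{h:02d}"] = hourly_mvpa[:, h]
    cohort = pd.concat(
        [cohort, _draw_covariates(rng, n, config.covariate_params)], axis=1
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "participant_id": cohort["participant_id"],
                "archetype": archetypes,
                "nocturnal_outlier": outlier,
            }
        ),
        config=config,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# survival generation
# ---------------------------------------------------------------------------


def _linear_predictor(cohort: pd.DataFrame, config: SimulationConfig, cause: str):
    n = len(cohort)
    lp = np.zeros(n)
    mapping = config.planted_log_hr.get(cause, {})
    groups = cohort["timing_group"].to_numpy()
    if mapping:
        present = pd.unique(groups)
        missing = [g for g in present if g not in mapping]
        if missing:
            raise ConfigurationError(
                f"planted_log_hr[{cause!r}] missing groups {missing}; "
                "list every group explicitly (zeros included)"
            )
        lp += np.array([mapping[g] for g in groups], dtype=float)
    beta_mvpa = config.mvpa_log_hr_per_unit.get(cause, 0.0)
    if beta_mvpa:
        lp += beta_mvpa * np.log1p(cohort["weekly_mvpa_min"].to_numpy(dtype=float))
    for col, beta in config.covariate_log_hr.get(cause, {}).items():
        lp += beta * cohort[col].to_numpy(dtype=float)
    return lp


def generate_survival(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Attach cause-specific exponential event times under planted hazards.

    For each cause the individual hazard is
    ``baseline_hazard[cause] * exp(planted group effect + MVPA effect +
    covariate effects)``; the observed time is the minimum over causes and
    the administrative censoring horizon, and the event label is the
    earliest cause (or ``"none"`` when censored).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 7919])
    causes = list(config.baseline_hazard)
    n = len(cohort)
    times = np.empty((n, len(causes)))
    for k, cause in enumerate(causes):
        rate = config.baseline_hazard[cause] * np.exp(
            _linear_predictor(cohort, config, cause)
        )
        times[:, k] = rng.exponential(1.0 / rate)
    first = times.argmin(axis=1)
    t_event = times.min(axis=1)
    censored = t_event >= config.followup_years
    out = cohort.copy()
    out["followup_years"] = np.where(censored, config.followup_years, t_event)
    out["event_cause"] = np.where(
        censored, "none", np.array(causes, dtype=object)[first]
    )
    return out


# ---------------------------------------------------------------------------
# epoch-level generation
# ---------------------------------------------------------------------------

# Baseline VM is a bounded rest/burst mixture: strictly below the 100 mg
# moderate band (so baseline noise can never create MVPA) yet with per-epoch
# dispersion far above the 13 mg non-wear threshold - and, crucially, with
# across-day slot-mean dispersion still above it, so slot-mean imputation
# does not manufacture new stationary runs.
_DAY_REST_SCALE = 5.0  # Exp scale, mg
_DAY_BURST_RANGE = (85.0, 99.0)
_DAY_BURST_PROB = 0.30
_NIGHT_REST_SCALE = 4.0
_NIGHT_BURST_RANGE = (50.0, 250.0)
_NIGHT_BURST_PROB = 0.08
_NIGHT_OUTLIER_BURST_PROB = 0.60
_NIGHT_HOURS = (0, 5)
_NOCTURNAL_OUTLIER_HOURS = (1, 4)
_MODERATE_SHARE = 0.85  # share of weekly MVPA delivered as moderate sessions
_SESSION_VM_RANGE = (105.0, 395.0)
_SESSION_OFF_RANGE = (40.0, 90.0)
_VIGOROUS_VM_RANGE = (405.0, 800.0)
DEFAULT_EPOCH_START = pd.Timestamp("2015-06-01 00:00:00")


def _mixture(rng, size, rest_scale, burst_range, burst_prob, clip=None):
    vm = rng.exponential(rest_scale, size)
    burst = rng.random(size) < burst_prob
    vm[burst] = rng.uniform(*burst_range, int(burst.sum()))
    return np.minimum(vm, clip) if clip is not None else vm


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``."""
    shares = np.asarray(shares, dtype=float)
    raw = shares / shares.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _window_allocation(
    config: SimulationConfig, archetype: str, total: int
) -> np.ndarray:
    """Split ``total`` placements across timing windows for one archetype."""
    windows = config.windows
    widths = np.array([z - a for a, z in windows.spans()], dtype=float)
    if archetype == MIXED:
        return _largest_remainder(total, np.ones(windows.n_windows))
    w_idx = windows.labels.index(archetype)
    n_in = int(round(config.concentration * total))
    out = np.zeros(windows.n_windows, dtype=int)
    out[w_idx] = n_in
    rest = total - n_in
    if rest:
        others = np.flatnonzero(np.arange(windows.n_windows) != w_idx)
        out[others] = _largest_remainder(rest, widths[others])
    return out


def _simulate_trace(
    rng: np.random.Generator,
    config: SimulationConfig,
    archetype: str,
    weekly_target: float,
    nocturnal_outlier: bool,
):
    n = SIMULATED_DAYS * EPOCHS_PER_DAY
    vm = np.empty(n, dtype=np.float64)
    hours = (np.arange(n) % EPOCHS_PER_DAY) // EPOCHS_PER_HOUR
    night = (hours >= _NIGHT_HOURS[0]) & (hours < _NIGHT_HOURS[1])
    vm[~night] = _mixture(
        rng, int((~night).sum()), _DAY_REST_SCALE, _DAY_BURST_RANGE, _DAY_BURST_PROB,
        clip=99.0,
    )
    vm[night] = _mixture(
        rng, int(night.sum()), _NIGHT_REST_SCALE, _NIGHT_BURST_RANGE, _NIGHT_BURST_PROB
    )
    if nocturnal_outlier:
        lo, hi = _NOCTURNAL_OUTLIER_HOURS
        noct = (hours >= lo) & (hours < hi)
        vm[noct] = _mixture(
            rng, int(noct.sum()), _NIGHT_REST_SCALE, _NIGHT_BURST_RANGE,
            _NIGHT_OUTLIER_BURST_PROB,
        )

    # --- moderate sessions -------------------------------------------------
    n_sessions = int(round(_MODERATE_SHARE * weekly_target / SESSION_MINUTES))
    session_alloc = _window_allocation(config, archetype, n_sessions)
    used_blocks = set()
    session_starts = []
    for w_idx, (a, z) in enumerate(config.windows.spans()):
        blocks = [
            d * EPOCHS_PER_DAY + h * EPOCHS_PER_HOUR + b * SESSION_EPOCHS
            for d in range(SIMULATED_DAYS)
            for h in range(a, z)
            for b in range(EPOCHS_PER_HOUR // SESSION_EPOCHS)
        ]
        take = min(session_alloc[w_idx], len(blocks))
        chosen = rng.choice(len(blocks), size=take, replace=False)
        for c in chosen:
            start = blocks[c]
            if start in used_blocks:
                continue
            used_blocks.add(start)
            session_starts.append(start)
            n_in = 54 + int(rng.integers(0, 6))  # 54..59 of 60 in band (>80%)
            content = np.empty(SESSION_EPOCHS)
            content[:n_in] = rng.uniform(*_SESSION_VM_RANGE, n_in)
            content[n_in:] = rng.uniform(*_SESSION_OFF_RANGE, SESSION_EPOCHS - n_in)
            rng.shuffle(content)
            vm[start : start + SESSION_EPOCHS] = content

    # --- vigorous epochs ---------------------------------------------------
    n_vig = int(round((1.0 - _MODERATE_SHARE) * weekly_target * 12))
    vig_alloc = _window_allocation(config, archetype, n_vig)
    covered = np.zeros(n, dtype=bool)
    for s in session_starts:
        covered[s : s + SESSION_EPOCHS] = True
    for w_idx, (a, z) in enumerate(config.windows.spans()):
        in_window = (hours >= a) & (hours < z) & ~covered
        pool = np.flatnonzero(in_window)
        take = min(vig_alloc[w_idx], pool.size)
        idx = rng.choice(pool, size=take, replace=False)
        vm[idx] = rng.uniform(*_VIGOROUS_VM_RANGE, take)

    # --- non-wear episodes -------------------------------------------------
    n_episodes = rng.poisson(config.nonwear_rate)
    episodes = []
    for _ in range(n_episodes):
        dur = int(rng.uniform(1.0, 3.0) * EPOCHS_PER_HOUR)
        start = int(rng.integers(0, n - dur))
        vm[start : start + dur] = 0.0
        episodes.append((start, dur))
    return vm, episodes


def generate_epoch_cohort(config: SimulationConfig, n_small: int):
    """Generate ``n_small`` full 7-day epoch traces plus ground truth.

    Epoch-level generation is meant for phenotyping tests, not full
    cohorts; ``n_small`` is capped at 10,000.
    """
    config.validate()
    if n_small > MAX_EPOCH_PARTICIPANTS:
        raise ConfigurationError(
            f"n_small={n_small} exceeds the epoch-level cap of {MAX_EPOCH_PARTICIPANTS}"
        )
    master = np.random.default_rng(config.seed)
    archetypes = master.choice(
        np.array(config.archetypes(), dtype=object), size=n_small, p=config.mix_probs()
    )
    weekly = master.lognormal(
        np.log(config.weekly_mvpa_median), config.weekly_mvpa_sigma, n_small
    )
    outlier = master.random(n_small) < config.nocturnal_outlier_rate
    children = np.random.SeedSequence(config.seed).spawn(n_small)
    series_list = []
    rows = []
    for i in range(n_small):
        rng = np.random.default_rng(children[i])
        vm, episodes = _simulate_trace(
            rng, config, archetypes[i], weekly[i], bool(outlier[i])
        )
        pid = f"e{i:05d}"
        series_list.append(
            EpochSeries(participant_id=pid, start=DEFAULT_EPOCH_START, vm=vm)
        )
        rows.append(
            {
                "participant_id": pid,
                "archetype": archetypes[i],
                "weekly_mvpa_target": weekly[i],
                "nocturnal_outlier": bool(outlier[i]),
                "n_nonwear_episodes": len(episodes),
            }
        )
    truth = GroundTruth(table=pd.DataFrame(rows), config=config)
    return series_list, truth
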