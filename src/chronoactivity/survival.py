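"""Survival analysis of MVPA-timing phenotypes.

Cox proportional-hazards models at three nested adjustment levels
(1: age + sex; 2: + sociodemographics, lifestyle, diet; 3: + sleep duration,
sleep midpoint and total MVPA volume), restricted-cubic-spline dose-response
curves with overall and non-linearity likelihood-ratio tests, G-computation
standardized cumulative-risk curves, Fine-Gray subdistribution hazards for
competing risks, Benjamini-Hochberg FDR correction, and multiplicative /
additive (RERI, AP, SI) interaction plus subgroup analyses.

Cox partial-likelihood machinery is delegated to lifelines (Efron tie
handling); the Fine-Gray estimator is built here as an inverse-probability-
of-censoring-weighted Cox fit on the expanded subdistribution risk set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .splines import DEFAULT_N_KNOTS, OrthogonalSplineBasis, default_knots
from .timing import MIXED

logger = logging.getLogger(__name__)

CENSORED = "none"
ALL_CAUSE = "all_cause"
GROUP_ORDER = ("morning", "midday_afternoon", "evening", MIXED)
FAVORABLE_GROUPS = ("midday_afternoon", MIXED)
WHO_MVPA_MIN_PER_WEEK = 150.0
MIN_EVENTS_PER_PARAM = 10

CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "ethnicity": ("white", "other"),
    "region": ("england", "wales", "scotland"),
    "education": ("degree", "other_qualification", "no_qualification"),
    "wear_season": ("spring", "summer", "autumn", "winter"),
    "smoking": ("never", "previous", "current"),
    "alcohol": ("not_current", "two_or_less_weekly", "three_or_more_weekly"),
    "sleep_duration": ("lt7h", "7to8h", "gt8h"),
    "sleep_midpoint": ("before_0230", "0230_to_0330", "after_0330"),
}

MODEL_COVARIATES = {
    0: [],
    1: ["age", "sex"],
    2: [
        "age", "sex", "ethnicity", "deprivation", "region", "education",
        "wear_season", "diet_score", "smoking", "alcohol",
    ],
    3: [
        "age", "sex", "ethnicity", "deprivation", "region", "education",
        "wear_season", "diet_score", "smoking", "alcohol",
        "sleep_duration", "sleep_midpoint", "mvpa_log",
    ],
}


def _suppress_lifelines_warnings():
    return warnings.catch_warnings()


def build_design(cohort: pd.DataFrame, covariates, drop=()) -> pd.DataFrame:
    """Numeric design matrix for the requested covariates.

    Categorical covariates are expanded to treatment dummies against their
    first (most common) level; ``mvpa_log`` is derived as log(1 + weekly
    MVPA min/week), the transformed total-volume adjustment.
    """
    cols = {}
    for cov in covariates:
        if cov in drop:
            continue
        if cov == "mvpa_log":
            cols["mvpa_log"] = np.log1p(cohort["weekly_mvpa_min"].to_numpy(dtype=float))
        elif cov in CATEGORICAL_LEVELS:
            values = cohort[cov].astype(str)
            for level in CATEGORICAL_LEVELS[cov][1:]:
                cols[f"{cov}__{level}"] = (values == level).to_numpy(dtype=float)
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def _event_indicator(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    causes = cohort["event_cause"].to_numpy()
    if outcome == ALL_CAUSE and ALL_CAUSE not in set(causes):
        return causes != CENSORED
    return causes == outcome


def _fit_cox(df: pd.DataFrame, precision: float = 1e-10) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df,
            duration_col="__time",
            event_col="__event",
            fit_options={"precision": precision},
        )
    return cph


@dataclass
class TimingCoxFit:
    """Tidy result of one timing-group Cox model."""

    outcome: str
    model_level: int
    reference: str
    table: pd.DataFrame  # one row per group incl. reference
    log_likelihood: float
    n: int
    fitter: CoxPHFitter = field(repr=False, default=None)


def _group_dummies(cohort, reference, groups):
    dummies = {}
    g = cohort["timing_group"].astype(str)
    for grp in groups:
        if grp == reference:
            continue
        dummies[f"group__{grp}"] = (g == grp).to_numpy(dtype=float)
    return pd.DataFrame(dummies, index=cohort.index)


def fit_timing_cox(
    cohort: pd.DataFrame,
    outcome: str,
    model_level: int = 3,
    reference: str = "morning",
    groups=None,
) -> TimingCoxFit:
    """Hazard ratios of the timing groups versus the reference group.

    Fits the partial likelihood with the model-level covariate set and
    returns per-group HRs with 95% CIs and p-values, plus events and
    person-years per group.  Empty groups are dropped from the contrast
    list; thin event counts (fewer than ten events per parameter) are
    tolerated with a logged warning.
    """
    if groups is None:
        present = set(cohort["timing_group"].astype(str))
        groups = [g for g in GROUP_ORDER if g in present]
        groups += sorted(present - set(groups))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} absent from cohort")
    event = _event_indicator(cohort, outcome)
    time = cohort["followup_years"].to_numpy(dtype=float)

    gvals_all = cohort["timing_group"].astype(str).to_numpy()
    estimable = [
        g
        for g in groups
        if g == reference or event[gvals_all == g].sum() > 0
    ]
    dropped = [g for g in groups if g not in estimable]
    if dropped:
        logger.warning(
            "%s: contrasts dropped for zero-event groups %s", outcome, dropped
        )
    X = pd.concat(
        [
            _group_dummies(cohort, reference, estimable),
            build_design(cohort, MODEL_COVARIATES[model_level]),
        ],
        axis=1,
    )
    n_params = X.shape[1]
    if event.sum() < MIN_EVENTS_PER_PARAM * n_params:
        logger.warning(
            "%s: %d events for %d parameters (< %d per parameter)",
            outcome, int(event.sum()), n_params, MIN_EVENTS_PER_PARAM,
        )
    df = X.copy()
    df["__time"] = time
    df["__event"] = event.astype(int)
    cph = _fit_cox(df)

    rows = []
    gvals = cohort["timing_group"].astype(str).to_numpy()
    for grp in groups:
        sel = gvals == grp
        row = {
            "group": grp,
            "n": int(sel.sum()),
            "events": int(event[sel].sum()),
            "person_years": float(time[sel].sum()),
        }
        if grp == reference:
            row.update(hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        elif grp in dropped:
            row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        else:
            name = f"group__{grp}"
            s = cph.summary.loc[name]
            row.update(
                hr=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p=float(s["p"]),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    return TimingCoxFit(
        outcome=outcome,
        model_level=model_level,
        reference=reference,
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(cohort),
        fitter=cph,
    )


def timing_table(
    cohort: pd.DataFrame,
    outcomes=(ALL_CAUSE, "cvd", "cancer"),
    model_levels=(1, 2, 3),
    reference: str = "morning",
) -> pd.DataFrame:
    """Stacked timing-group results across outcomes and adjustment levels.

    FDR adjustment is applied within each outcome's fully adjusted
    (model-3) contrasts - the multiple-testing family used in the main
    results table.
    """
    frames = []
    for outcome in outcomes:
        for level in model_levels:
            fit = fit_timing_cox(cohort, outcome, level, reference)
            tab = fit.table.copy()
            tab.insert(0, "model", level)
            tab.insert(0, "outcome", outcome)
            frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["p_fdr"] = np.nan
    top = max(model_levels)
    for outcome in outcomes:
        sel = (out["outcome"] == outcome) & (out["model"] == top) & out["p"].notna()
        out.loc[sel, "p_fdr"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    return out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dose-response splines
# ---------------------------------------------------------------------------


@dataclass
class SplineResult:
    exposure: str
    outcome: str
    curve: pd.DataFrame  # grid, hr, ci_low, ci_high
    p_overall: float
    p_nonlinear: float
    knots: np.ndarray
    reference_value: float
    log_likelihood: float


def _lrt(ll_full, ll_reduced, df):
    chi2 = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(stats.chi2.sf(chi2, df))


def dose_response_spline(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    model_level: int = 3,
    n_knots: int = DEFAULT_N_KNOTS,
    drop=(),
    extra_covariates: pd.DataFrame = None,
    upper_quantile: float = 0.99,
    reference_value: float = None,
    grid_size: int = 60,
) -> SplineResult:
    """Restricted-cubic-spline exposure curve inside the Cox model.

    The exposure is winsorized at ``upper_quantile``; ``p_overall`` is the
    LRT of all spline terms against the covariates-only model and
    ``p_nonlinear`` the LRT of the nonlinear terms against linearity.  The
    curve is normalized to HR = 1 at ``reference_value`` (default: the
    exposure median).
    """
    x = cohort[exposure].to_numpy(dtype=float)
    if np.ptp(x) <= 0:
        raise ValueError(f"degenerate exposure {exposure!r}: no variation")
    cap = np.quantile(x, upper_quantile)
    x = np.minimum(x, cap)
    knots = default_knots(x, n_knots)
    ortho = OrthogonalSplineBasis(x, knots)
    basis = ortho.design
    spline_cols = [f"{exposure}__s{j}" for j in range(basis.shape[1])]

    covars = build_design(cohort, MODEL_COVARIATES[model_level], drop=drop)
    if extra_covariates is not None:
        covars = pd.concat([covars, extra_covariates], axis=1)
    event = _event_indicator(cohort, outcome)
    time = cohort["followup_years"].to_numpy(dtype=float)

    def fit(extra):
        df = pd.concat([extra, covars], axis=1) if extra is not None else covars.copy()
        df = df.copy()
        df["__time"] = time
        df["__event"] = event.astype(int)
        return _fit_cox(df)

    full = fit(pd.DataFrame(basis, columns=spline_cols, index=cohort.index))
    reduced = fit(None)
    linear = fit(
        pd.DataFrame(basis[:, :1], columns=spline_cols[:1], index=cohort.index)
    )
    p_overall = _lrt(full.log_likelihood_, reduced.log_likelihood_, basis.shape[1])
    p_nonlinear = _lrt(full.log_likelihood_, linear.log_likelihood_, basis.shape[1] - 1)

    ref = float(np.median(x)) if reference_value is None else float(reference_value)
    grid = np.linspace(x.min(), x.max(), grid_size)
    B = ortho.transform(grid) - ortho.transform(np.full(grid_size, ref))
    beta = full.params_.loc[spline_cols].to_numpy()
    V = full.variance_matrix_.loc[spline_cols, spline_cols].to_numpy()
    log_hr = B @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V, B), 0.0))
    curve = pd.DataFrame(
        {
            "grid": grid,
            "hr": np.exp(log_hr),
            "ci_low": np.exp(log_hr - 1.959964 * se),
            "ci_high": np.exp(log_hr + 1.959964 * se),
        }
    )
    return SplineResult(
        exposure=exposure,
        outcome=outcome,
        curve=curve,
        p_overall=p_overall,
        p_nonlinear=p_nonlinear,
        knots=knots,
        reference_value=ref,
        log_likelihood=float(full.log_likelihood_),
    )


def window_mvpa_model(
    cohort: pd.DataFrame,
    window: str,
    outcome: str,
    window_labels=("morning", "midday_afternoon", "evening"),
    **kwargs,
) -> SplineResult:
    """Spline for one window's MVPA minutes, mutually adjusted.

    The other two windows' volumes enter as covariates; the total-volume
    term is dropped (it is collinear with the three window volumes).
    """
    others = [w for w in window_labels if w != window]
    extra = pd.DataFrame(
        {f"mvpa_{w}_min": cohort[f"mvpa_{w}_min"].to_numpy(dtype=float) for w in others},
        index=cohort.index,
    )
    corr = np.corrcoef(
        cohort[[f"mvpa_{w}_min" for w in window_labels]].to_numpy(), rowvar=False
    )
    if np.abs(corr[np.triu_indices(3, 1)]).max() > 0.95:
        logger.warning("window MVPA volumes correlate > 0.95; estimates unstable")
    return dose_response_spline(
        cohort,
        f"mvpa_{window}_min",
        outcome,
        drop=("mvpa_log",),
        extra_covariates=extra,
        **kwargs,
    )


def fraction_dose_response(
    cohort: pd.DataFrame, window: str, outcome: str, **kwargs
) -> SplineResult:
    """Spline for a window's MVPA fraction, adjusted for total MVPA volume."""
    return dose_response_spline(
        cohort, f"fraction_{window}", outcome, upper_quantile=1.0, **kwargs
    )


# ---------------------------------------------------------------------------
# standardized risk curves (G-computation)
# ---------------------------------------------------------------------------


def standardized_risk_curves(
    cohort: pd.DataFrame,
    outcome: str,
    model_level: int = 3,
    reference: str = "morning",
    times: np.ndarray = None,
    max_rows: int = 4000,
) -> pd.DataFrame:
    """Per-group standardized cumulative incidence by G-computation.

    For each timing group, every participant's covariates are kept while the
    group indicator is set to that group; the model-predicted cumulative
    incidence is averaged over the (sub)cohort covariate distribution.
    """
    fit = fit_timing_cox(cohort, outcome, model_level, reference)
    groups = list(fit.table["group"])
    if times is None:
        times = np.linspace(0.0, float(cohort["followup_years"].max()), 29)
    step = max(len(cohort) // max_rows, 1)
    sub = cohort.iloc[::step]
    base = pd.concat(
        [
            _group_dummies(sub, reference, groups),
            build_design(sub, MODEL_COVARIATES[model_level]),
        ],
        axis=1,
    )
    out = {"time": times}
    group_cols = [c for c in base.columns if c.startswith("group__")]
    for grp in groups:
        X = base.copy()
        X[group_cols] = 0.0
        if grp != reference:
            X[f"group__{grp}"] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surv = fit.fitter.predict_survival_function(X, times=times)
        out[grp] = 1.0 - surv.mean(axis=1).to_numpy()
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazards
# ---------------------------------------------------------------------------


def _censoring_survival(time, censored):
    km = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km.fit(time, event_observed=censored)
    return km


def finegray_expand(
    time: np.ndarray, cause_event: np.ndarray, competing_event: np.ndarray
) -> pd.DataFrame:
    """Counting-process expansion of the subdistribution risk set.

    Subjects with a competing event remain at risk for the cause of interest
    after their event time, down-weighted by the inverse probability of
    remaining uncensored, G(t-)/G(s-), evaluated at the cause-specific event
    times t beyond their competing-event time s.
    """
    time = np.asarray(time, dtype=float)
    cause_event = np.asarray(cause_event, dtype=bool)
    competing_event = np.asarray(competing_event, dtype=bool)
    censored = ~cause_event & ~competing_event
    km = _censoring_survival(time, censored)
    event_times = np.unique(time[cause_event])

    ids = np.arange(time.size)
    rows = [
        pd.DataFrame(
            {
                "id": ids,
                "start": 0.0,
                "stop": time,
                "event": cause_event.astype(int),
                "weight": 1.0,
            }
        )
    ]
    comp_ids = ids[competing_event]
    if comp_ids.size and event_times.size:
        eps = 1e-9
        g_at = km.survival_function_at_times(event_times - eps).to_numpy()
        for i in comp_ids:
            s = time[i]
            later = np.flatnonzero(event_times > s)
            if later.size == 0:
                continue
            g_s = float(km.survival_function_at_times([s - eps]).iloc[0])
            stops = event_times[later]
            starts = np.concatenate(([s], stops[:-1]))
            w = g_at[later] / g_s if g_s > 0 else np.ones(later.size)
            rows.append(
                pd.DataFrame(
                    {
                        "id": i,
                        "start": starts,
                        "stop": stops,
                        "event": 0,
                        "weight": w,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def fine_gray(
    cohort: pd.DataFrame,
    cause: str,
    model_level: int = 3,
    reference: str = "morning",
    groups=None,
) -> TimingCoxFit:
    """Subdistribution hazard ratios for the timing groups.

    Other-cause death acts as the competing risk.  With single-cause data
    the expansion is the ordinary risk set and the estimator reduces to the
    cause-specific Cox model (noted in the returned table attrs).
    """
    if groups is None:
        present = set(cohort["timing_group"].astype(str))
        groups = [g for g in GROUP_ORDER if g in present]
    causes = cohort["event_cause"].to_numpy()
    cause_event = causes == cause
    competing_event = (causes != cause) & (causes != CENSORED)
    single_cause = not competing_event.any()

    expanded = finegray_expand(
        cohort["followup_years"].to_numpy(dtype=float), cause_event, competing_event
    )
    X = pd.concat(
        [
            _group_dummies(cohort, reference, groups),
            build_design(cohort, MODEL_COVARIATES[model_level]),
        ],
        axis=1,
    ).reset_index(drop=True)
    df = pd.concat(
        [expanded, X.iloc[expanded["id"].to_numpy()].reset_index(drop=True)], axis=1
    )
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(
            df,
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="event",
            weights_col="weight",
            fit_options={"precision": 1e-10},
        )
    rows = []
    gvals = cohort["timing_group"].astype(str).to_numpy()
    for grp in groups:
        sel = gvals == grp
        row = {
            "group": grp,
            "n": int(sel.sum()),
            "events": int(cause_event[sel].sum()),
            "person_years": float(cohort.loc[sel, "followup_years"].sum()),
        }
        if grp == reference:
            row.update(hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
        else:
            s = ctv.summary.loc[f"group__{grp}"]
            row.update(
                hr=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p=float(s["p"]),
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["single_cause"] = single_cause
    if single_cause:
        logger.info("no competing events: Fine-Gray reduces to the Cox model")
    return TimingCoxFit(
        outcome=cause,
        model_level=model_level,
        reference=reference,
        table=table,
        log_likelihood=float(ctv.log_likelihood_),
        n=len(cohort),
        fitter=ctv,
    )


# ---------------------------------------------------------------------------
# interaction and subgroup analyses
# ---------------------------------------------------------------------------


@dataclass
class InteractionResult:
    outcome: str
    modifier: str
    hr10: float
    hr01: float
    hr11: float
    reri: float
    reri_ci: tuple
    ap: float
    ap_ci: tuple
    si: float
    si_ci: tuple
    multiplicative_p: float
    table: pd.DataFrame = None


def reri_from_hrs(hr10: float, hr01: float, hr11: float):
    """Additive-interaction measures from the three non-reference HRs.

    RERI = HR11 - HR10 - HR01 + 1; AP = RERI / HR11;
    SI = (HR11 - 1) / ((HR10 - 1) + (HR01 - 1)), defined only when the
    denominator is nonzero.
    """
    reri = hr11 - hr10 - hr01 + 1.0
    ap = reri / hr11
    denom = (hr10 - 1.0) + (hr01 - 1.0)
    si = (hr11 - 1.0) / denom if denom != 0 else np.nan
    return reri, ap, si


def add_modifier_columns(cohort: pd.DataFrame, age_split: float = 65.0) -> pd.DataFrame:
    """Binary effect-modifier columns used by interaction/subgroup analyses."""
    out = cohort.copy()
    out["elderly"] = (out["age"] >= age_split).astype(int)
    out["male"] = (out["sex"].astype(str) == "male").astype(int)
    out["meets_who_mvpa"] = (
        out["weekly_mvpa_min"] >= WHO_MVPA_MIN_PER_WEEK
    ).astype(int)
    for col, src in (
        ("has_cvd", "cvd_history"),
        ("obese", "obesity"),
    ):
        if src in out.columns:
            out[col] = out[src].astype(int)
    return out


_MODIFIER_DROPS = {
    "elderly": ("age",),
    "male": ("sex",),
    "meets_who_mvpa": ("mvpa_log",),
}


def interaction_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    modifier: str,
    model_level: int = 3,
    favorable=FAVORABLE_GROUPS,
) -> InteractionResult:
    """Multiplicative and additive interaction of timing with a modifier.

    The four timing groups are dichotomized into favorable
    (midday-afternoon / mixed) versus unfavorable (morning / evening); the
    exposure indicator is *unfavorable* timing.  The Cox model holds both
    main effects plus the product term; the multiplicative p-value is the
    product term's, while RERI/AP/SI come from the three non-reference HRs
    with delta-method CIs.
    """
    x1 = (~cohort["timing_group"].astype(str).isin(favorable)).to_numpy(dtype=float)
    x2 = cohort[modifier].to_numpy(dtype=float)
    if not set(np.unique(x2)) <= {0.0, 1.0}:
        raise ValueError(f"modifier {modifier!r} must be binary 0/1")
    for a, b in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        if not ((x1 == a) & (x2 == b)).any():
            raise ValueError(f"empty interaction cell (timing={a}, {modifier}={b})")
    drop = _MODIFIER_DROPS.get(modifier, (modifier,))
    X = build_design(cohort, MODEL_COVARIATES[model_level], drop=drop)
    df = X.copy()
    df["x_unfav"] = x1
    df["x_mod"] = x2
    df["x_product"] = x1 * x2
    df["__time"] = cohort["followup_years"].to_numpy(dtype=float)
    df["__event"] = _event_indicator(cohort, outcome).astype(int)
    cph = _fit_cox(df)

    names = ["x_unfav", "x_mod", "x_product"]
    b = cph.params_.loc[names].to_numpy()
    V = cph.variance_matrix_.loc[names, names].to_numpy()
    h10, h01 = np.exp(b[0]), np.exp(b[1])
    h11 = np.exp(b.sum())
    reri, ap, si = reri_from_hrs(h10, h01, h11)

    grad_reri = np.array([h11 - h10, h11 - h01, h11])
    se_reri = float(np.sqrt(grad_reri @ V @ grad_reri))
    # AP = 1 - (h10 + h01 - 1)/h11 ; d/db of log terms via chain rule
    grad_ap = np.array(
        [
            (h01 - 1.0) / h11,
            (h10 - 1.0) / h11,
            (h10 + h01 - 1.0) / h11,
        ]
    )
    se_ap = float(np.sqrt(grad_ap @ V @ grad_ap))
    denom = (h10 - 1.0) + (h01 - 1.0)
    if denom != 0 and h11 > 1.0 and denom > 0:
        # CI on log(SI) (standard for the synergy index)
        grad_logsi = np.array(
            [
                h11 / (h11 - 1.0) - h10 / denom,
                h11 / (h11 - 1.0) - h01 / denom,
                h11 / (h11 - 1.0),
            ]
        )
        se_logsi = float(np.sqrt(grad_logsi @ V @ grad_logsi))
        si_ci = (si * np.exp(-1.959964 * se_logsi), si * np.exp(1.959964 * se_logsi))
    else:
        si_ci = (np.nan, np.nan)

    strata = pd.DataFrame(
        {
            "stratum": ["00", "10", "01", "11"],
            "hr": [1.0, h10, h01, h11],
        }
    )
    return InteractionResult(
        outcome=outcome,
        modifier=modifier,
        hr10=h10,
        hr01=h01,
        hr11=h11,
        reri=reri,
        reri_ci=(reri - 1.959964 * se_reri, reri + 1.959964 * se_reri),
        ap=ap,
        ap_ci=(ap - 1.959964 * se_ap, ap + 1.959964 * se_ap),
        si=si,
        si_ci=si_ci,
        multiplicative_p=float(cph.summary.loc["x_product", "p"]),
        table=strata,
    )


def subgroup_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    stratifier: str,
    model_level: int = 3,
    favorable=FAVORABLE_GROUPS,
) -> pd.DataFrame:
    """Favorable-timing HR fitted separately inside each modifier stratum."""
    drop = _MODIFIER_DROPS.get(stratifier, (stratifier,))
    rows = []
    for value in sorted(pd.unique(cohort[stratifier])):
        sub = cohort[cohort[stratifier] == value]
        x = sub["timing_group"].astype(str).isin(favorable).to_numpy(dtype=float)
        event = _event_indicator(sub, outcome)
        X = build_design(sub, MODEL_COVARIATES[model_level], drop=drop)
        n_params = X.shape[1] + 1
        if event.sum() < MIN_EVENTS_PER_PARAM * n_params:
            logger.warning(
                "stratum %s=%s: %d events for %d parameters",
                stratifier, value, int(event.sum()), n_params,
            )
        df = X.copy()
        df["x_favorable"] = x
        df["__time"] = sub["followup_years"].to_numpy(dtype=float)
        df["__event"] = event.astype(int)
        cph = _fit_cox(df)
        s = cph.summary.loc["x_favorable"]
        rows.append(
            {
                "stratum": value,
                "n": len(sub),
                "events": int(event.sum()),
                "hr": float(s["exp(coef)"]),
                "ci_low": float(s["exp(coef) lower 95%"]),
                "ci_high": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
            }
        )
    return pd.DataFrame(rows)
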