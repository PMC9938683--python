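"""Replicated simulation experiments over the reference scenarios.

These runners power both the test suite and the reproduction script:
each draws fresh cohorts from a seed sequence, executes the estimation
stack, and returns tidy per-replicate results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scenarios
from .discovery import scan_windows
from .simulate import generate_phenotype_cohort, generate_survival
from .survival import fdr_adjust, fit_timing_cox
from .timing import MIXED


def _child_seeds(seed: int, n: int) -> list:
    """Independent 31-bit seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_timing_recovery(
    outcome: str,
    n: int = 50_000,
    replicates: int = 1,
    seed: int = 0,
    model_level: int = 3,
) -> pd.DataFrame:
    """Replicate the planted model-3 HR recovery experiment.

    Returns one row per (replicate, contrast) with the recovered HR, its
    CI, and the planted truth.
    """
    planted = scenarios.MODEL3_HAZARD_RATIOS[outcome]
    rows = []
    for rep, s in enumerate(_child_seeds(seed, replicates)):
        config = scenarios.recovery_config(outcome, n=n, seed=s)
        cohort, _ = generate_phenotype_cohort(config)
        cohort = generate_survival(cohort, config)
        fit = fit_timing_cox(cohort, outcome, model_level=model_level)
        for _, r in fit.table.iterrows():
            if r["group"] == fit.reference:
                continue
            rows.append(
                {
                    "replicate": rep,
                    "outcome": outcome,
                    "group": r["group"],
                    "hr": r["hr"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "events": r["events"],
                    "planted_hr": planted[r["group"]],
                }
            )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean recovered HR per contrast across replicates."""
    out = (
        results.assign(log_hr=np.log(results["hr"]))
        .groupby(["outcome", "group"], sort=False)
        .agg(
            mean_log_hr=("log_hr", "mean"),
            n_replicates=("replicate", "nunique"),
            planted_hr=("planted_hr", "first"),
        )
        .reset_index()
    )
    out["recovered_hr"] = np.exp(out["mean_log_hr"])
    return out


def run_change_point_experiment(
    replicates: int = 20,
    n: int = 50_000,
    seed: int = 0,
    planted_hr: float = scenarios.DISCOVERY_PLANTED_HR,
    elevated_rule: str = "ci",
    ci_alpha: float = 0.01,
) -> list:
    """Detected change-point tuples over replicated discovery cohorts."""
    detected = []
    for s in _child_seeds(seed, replicates):
        config = scenarios.discovery_config(n=n, seed=s, planted_hr=planted_hr)
        cohort, _ = generate_phenotype_cohort(config)
        cohort = generate_survival(cohort, config)
        scan = scan_windows(
            cohort,
            "all_cause",
            grid=config.windows,
            model_level=0,
            elevated_rule=elevated_rule,
            ci_alpha=ci_alpha,
            labels=cohort["timing_group"].to_numpy(),
        )
        detected.append(tuple(scan.change_points))
    return detected


def modal_change_points(detected: list) -> tuple:
    """Most frequent detected change-point pair across replicates."""
    pairs = [d for d in detected if len(d) == 2]
    if not pairs:
        raise ValueError("no replicate produced exactly two change points")
    values, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
    return tuple(int(v) for v in values[counts.argmax()])


def run_null_fdr_experiment(
    replicates: int = 200,
    n: int = 5_000,
    seed: int = 0,
    model_level: int = 1,
    alpha: float = 0.05,
) -> float:
    """Fraction of FDR-significant contrasts under the global null.

    Each replicate tests twelve null timing contrasts: for each of the
    three mortality outcomes, the three group contrasts versus morning
    plus the dichotomized favorable-versus-unfavorable contrast, with BH
    applied within each outcome's family of four.
    """
    outcomes = ("all_cause", "cvd", "cancer")
    n_sig = 0
    n_total = 0
    for s in _child_seeds(seed, replicates):
        config = scenarios.null_config(n=n, seed=s)
        cohort, _ = generate_phenotype_cohort(config)
        cohort = generate_survival(cohort, config)
        for outcome in outcomes:
            fit = fit_timing_cox(cohort, outcome, model_level=model_level)
            p = list(fit.table["p"].dropna().to_numpy())
            p.append(_favorable_contrast_p(cohort, outcome, model_level))
            adj = fdr_adjust(np.array(p))
            n_sig += int((adj < alpha).sum())
            n_total += len(p)
    return n_sig / n_total


def _favorable_contrast_p(cohort, outcome, model_level) -> float:
    """p-value of the favorable (midday-afternoon/mixed) timing contrast."""
    from .survival import FAVORABLE_GROUPS, MODEL_COVARIATES, _event_indicator, _fit_cox, build_design

    df = build_design(cohort, MODEL_COVARIATES[model_level])
    df["x_favorable"] = (
        cohort["timing_group"].astype(str).isin(FAVORABLE_GROUPS).to_numpy(dtype=float)
    )
    df["__time"] = cohort["followup_years"].to_numpy(dtype=float)
    df["__event"] = _event_indicator(cohort, outcome).astype(int)
    return float(_fit_cox(df).summary.loc["x_favorable", "p"])
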