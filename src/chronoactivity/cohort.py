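"""Analysis-ready cohort assembly: exclusions, diet score, imputation.

Exclusion criteria are applied sequentially in a frozen order - consent
withdrawal, incomplete hourly coverage, high nocturnal activity, then
unreliable/invalid accelerometry - and every removal is booked once, at the
first failing step, in an exclusion ledger whose counts sum exactly to the
difference between initial and final n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timing import NOCTURNAL_THRESHOLD

DIET_CRITERIA = (
    "diet_vegetable",  # >= 4 tablespoons of vegetables per day
    "diet_fruit",  # >= 3 pieces of fruit per day
    "diet_fish",  # fish >= twice per week
    "diet_red_meat",  # unprocessed red meat <= twice per week
    "diet_processed_meat",  # processed meat <= twice per week
)

EXCLUSION_STEPS = (
    "withdrawn",
    "hour_coverage",
    "nocturnal_activity",
    "invalid_accelerometry",
)


@dataclass
class ExclusionLedger:
    initial_n: int
    removed: dict
    final_n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "final_n", "removed": self.final_n})
        return pd.DataFrame(rows)

    def check(self) -> bool:
        return sum(self.removed.values()) == self.initial_n - self.final_n


def healthy_diet_score(diet_flags: pd.DataFrame) -> pd.Series:
    """Count of satisfied healthy-diet criteria (0-5).

    Expects the five boolean columns of :data:`DIET_CRITERIA`; a row with
    any missing flag gets a missing score, to be imputed downstream.
    """
    missing = [c for c in DIET_CRITERIA if c not in diet_flags.columns]
    if missing:
        raise ValueError(f"missing diet criterion columns: {missing}")
    flags = diet_flags[list(DIET_CRITERIA)]
    score = flags.astype(float).sum(axis=1)
    score[flags.isna().any(axis=1)] = np.nan
    return score


def apply_exclusions(
    cohort: pd.DataFrame, nocturnal_threshold: float = NOCTURNAL_THRESHOLD
):
    """Sequentially apply the exclusion criteria and book a ledger.

    Expects the flag columns ``withdrawn``, ``hour_coverage_ok``,
    ``nocturnal_fraction`` and ``valid_accel``; a participant failing
    several criteria is counted once, at the first failing step.
    """
    initial = len(cohort)
    remaining = cohort
    removed = {}

    fails = {
        "withdrawn": lambda df: df["withdrawn"].astype(bool),
        "hour_coverage": lambda df: ~df["hour_coverage_ok"].astype(bool),
        "nocturnal_activity": lambda df: df["nocturnal_fraction"].to_numpy(dtype=float)
        > nocturnal_threshold,
        "invalid_accelerometry": lambda df: ~df["valid_accel"].astype(bool),
    }
    for step in EXCLUSION_STEPS:
        mask = np.asarray(fails[step](remaining))
        removed[step] = int(mask.sum())
        remaining = remaining.loc[~mask]
    ledger = ExclusionLedger(initial_n=initial, removed=removed, final_n=len(remaining))
    assert ledger.check()
    return remaining.reset_index(drop=True), ledger


def impute_covariates(
    cohort: pd.DataFrame, seed: int, method: str = "stochastic"
) -> pd.DataFrame:
    """Single seeded covariate imputation (or complete-case filtering).

    ``stochastic``: missing categorical values are drawn from the observed
    class frequencies; missing continuous values are predicted by ordinary
    least squares on the complete numeric covariates with resampled
    residual noise (falling back to a mean/SD draw when no complete
    predictors exist).  Deterministic given the seed.  ``complete_case``
    drops any row with a missing covariate, mirroring the no-imputation
    sensitivity analysis.
    """
    if method == "complete_case":
        return cohort.dropna().reset_index(drop=True)
    if method != "stochastic":
        raise ValueError("method must be 'stochastic' or 'complete_case'")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    with_na = [c for c in out.columns if out[c].isna().any()]
    for col in with_na:
        miss = out[col].isna()
        if miss.all():
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if float(miss.mean()) >= 0.5:
            raise ValueError(f"column {col!r} is >=50% missing; cannot impute")
        observed = out.loc[~miss, col]
        if pd.api.types.is_float_dtype(observed) and observed.nunique() > 10:
            predictors = [
                c
                for c in out.columns
                if c != col
                and pd.api.types.is_numeric_dtype(out[c])
                and not out[c].isna().any()
            ]
            if predictors:
                X_obs = out.loc[~miss, predictors].to_numpy(dtype=float)
                X_mis = out.loc[miss, predictors].to_numpy(dtype=float)
                X_obs = np.column_stack([np.ones(len(X_obs)), X_obs])
                X_mis = np.column_stack([np.ones(len(X_mis)), X_mis])
                beta, *_ = np.linalg.lstsq(X_obs, observed.to_numpy(dtype=float), rcond=None)
                resid = observed.to_numpy(dtype=float) - X_obs @ beta
                sigma = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
                out.loc[miss, col] = X_mis @ beta + rng.normal(0.0, sigma, int(miss.sum()))
            else:
                out.loc[miss, col] = rng.normal(
                    float(observed.mean()), float(observed.std(ddof=1)), int(miss.sum())
                )
        else:
            freq = observed.value_counts(normalize=True)
            draws = rng.choice(freq.index.to_numpy(), size=int(miss.sum()), p=freq.to_numpy())
            out.loc[miss, col] = draws
            out[col] = out[col].astype(cohort[col].dtype, errors="ignore")
    return out
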