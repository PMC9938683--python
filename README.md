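# chronoactivity

Tools for studying **when** during the day people accumulate
moderate-to-vigorous physical activity (MVPA), and whether that timing is
associated with mortality. The package re-implements, as a tested and fully
synthetic-data-driven pipeline, the analysis design used in large
wrist-accelerometer cohort studies (UK Biobank scale): 5-s epoch
vector-magnitude traces are quality-controlled, summarised into MVPA
minutes, phenotyped into four timing groups, and the groups are related to
all-cause and cause-specific mortality with Cox models, splines, competing
risks and interaction analyses.

Because the cohort data such studies use are controlled-access, the package
ships a first-class synthetic-data generator with planted ground truth
(timing archetypes, group sizes, hazard ratios, event rates) so that every
stage — and the pipeline end to end — is exercisable and testable at desk
scale.

## What it computes

- **Epoch QC** (`epochs`): non-wear = maximal stationary runs ≥ 1 h with
  rolling vector-magnitude SD < 13.0 mg; non-wear values imputed from
  wear-time data at the same clock slot on other days; a recording is valid
  with ≥ 72 h of wear covering all 24 clock-hour bins.
- **MVPA** (`mvpa`): moderate sessions = clock-aligned 5-min blocks with
  > 80% of epochs in 100–400 mg; vigorous epochs = single epochs > 400 mg;
  daily minutes summed over 05:00–24:00 and extrapolated to 7 days.
- **Timing phenotype** (`timing`): window fractions over morning
  (05–11), midday-afternoon (11–17), evening (17–24); a participant whose
  dominant window holds ≥ 50% (configurable 50–70%) of MVPA joins that
  group, everyone else is *mixed*; participants with > 10% of activity in
  01:00–04:00 are excluded as non-diurnal.
- **Window discovery** (`discovery`): the three windows themselves are
  reproduced by an outcome-based scan — 2-h timing groups (3-h for
  21:00–24:00) fitted against the mixed group, with change points read off
  where the elevated-risk flag flips (11:00 and 17:00 under the planted
  truth).
- **Cohort assembly** (`cohort`): sequential exclusions with an exact
  ledger, the 0–5 healthy-diet score, seeded single imputation plus a
  complete-case mode.
- **Survival analysis** (`survival`): Cox models at three nested
  adjustment levels (model 1: age, sex; model 2: + sociodemographics,
  lifestyle, diet; model 3: + sleep duration, sleep midpoint, total MVPA
  volume); restricted-cubic-spline dose-response with likelihood-ratio
  `P_overall` / `P_nonlinear`; G-computation standardized risk curves;
  an in-package Fine-Gray subdistribution-hazard estimator (IPCW-weighted
  Cox, cross-checked against `cmprsk::crr`); Benjamini–Hochberg FDR; and
  multiplicative plus additive interaction (RERI, AP, SI with delta-method
  CIs) and subgroup analyses.
- **Simulation** (`simulate`, `scenarios`, `experiments`): two-tier
  generation — full 7-day epoch traces for phenotyping tests, and
  phenotype-level cohorts with exponential cause-specific hazards for
  survival experiments at n = 50,000.

## Worked example

Plant the published fully adjusted all-cause hazard ratios (0.89 / 0.98 /
0.89 for midday-afternoon / evening / mixed versus morning) in a 50,000-
participant cohort and recover them with the model-3 Cox fit:

```python
from chronoactivity import scenarios
from chronoactivity.simulate import generate_phenotype_cohort, generate_survival
from chronoactivity.survival import timing_table

config = scenarios.recovery_config("all_cause", n=50_000, seed=1)
cohort, truth = generate_phenotype_cohort(config)
cohort = generate_survival(cohort, config)
table = timing_table(cohort, outcomes=("all_cause",), model_levels=(3,))
print(table[["group", "events", "person_years", "hr",
             "ci_low", "ci_high", "p", "p_fdr"]])
```

which prints (this exact output at seed 1):

```
           group  events  person_years    hr  ci_low  ci_high     p  p_fdr
         morning     313     59277.353 1.000     NaN      NaN   NaN    NaN
midday_afternoon     751    153212.072 0.926   0.812    1.057 0.256  0.285
         evening     182     31055.964 1.105   0.920    1.326 0.285  0.285
           mixed     409    100553.167 0.768   0.663    0.890 0.000  0.001
```

Each row is one timing group: its event count, person-years, hazard ratio
versus the morning group with 95% CI, and raw/FDR-adjusted p-values. A
single replicate carries Monte-Carlo noise of roughly ±10% on each hazard
ratio at these event counts (the planted values sit inside every CI);
averaging replicates, as the reproduction script does, pins the recovered
values down to ~2%.

The numbered scripts under `analysis/` run the full narrative — simulate
(01), epoch-level phenotyping (02), window discovery (03), survival models
(04), interaction/subgroups (05) — each writing tidy tables under
`results/`.

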