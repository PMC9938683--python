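# Methods

This note documents the models, rules and numerical choices behind
`chronoactivity`, and what the synthetic-data experiments do and do not
demonstrate.

## The phenotyping chain

**Input.** Per-participant vector-magnitude (VM) acceleration in
milligravity (mg), one value per 5-s epoch, nominally 7 days. Gaps are
represented as non-wear epochs, never as missing rows.

**Non-wear.** Device-off time is inferred as maximal stationary runs: any
epoch covered by at least one 1-h window whose VM standard deviation is
below 13.0 mg is non-wear. Raw-signal pipelines apply this rule per axis;
with only epoch-level VM available the same threshold is applied to the
rolling VM dispersion — the threshold is retained for traceability, and
both the window length and threshold are arguments. The implementation is
an O(n) cumulative-sum scan; a brute-force O(n·w) scan over every window is
kept in the test suite as the oracle.

**Imputation.** Each non-wear epoch is replaced by the mean of wear-time VM
at the identical 5-s clock slot on the other recorded days ("similar time
of day"). Identical-slot imputation is the strictest reading; hour-level
pooling would also be defensible but is not the default. A slot that is
non-wear on every day raises an explicit error naming the slot — such a
recording should be failing quality control instead.

**Validity.** A recording is analysable with ≥ 72 h of wear covering all
24 clock-hour bins. Exclusions are applied in a frozen order — withdrawal,
hourly coverage, nocturnal activity, invalid accelerometry — with each
participant booked once at the first failing step, so the exclusion ledger
sums exactly.

**MVPA.** Moderate activity is sessionized: disjoint, clock-aligned 5-min
blocks in which strictly more than 80% of the sixty epochs lie in the
closed band 100–400 mg. Blocks are aligned (05:00:00, 05:05:00, ...), not
sliding: the source field is sessionized the same way and disjoint blocks
cannot double-count time. Vigorous activity is any epoch strictly above
400 mg; the closed moderate band and strict vigorous threshold partition
intensity at exactly 400 mg. Vigorous epochs inside a detected session are
not counted again. Daily MVPA minutes sum sessions (5 min each, attributed
to the day and window of their start epoch) and standalone vigorous epochs
(5 s each) over 05:00–24:00 only; weekly volume is
`(sum over valid days / valid days) × 7`, where a valid day carries at
least 12 h of wear (a package choice; the 72-h QC floor already guarantees
at least three such days).

**Timing phenotype.** Hour-of-day MVPA minutes (each session minute
attributed to the clock hour of its midpoint; vigorous epochs contributing
1/12 min) are pooled over the whole wear period, and window fractions are
computed from the pooled histogram rather than per-day-then-averaged —
robust to sparse days and matching a "total daily MVPA" reading. The group
is the unique window holding at least the cutoff (default 50%; sensitivity
cutoffs 55–70%) of 05:00–24:00 MVPA, else *mixed*; a tie at the cutoff
(possible only at 50%) falls to mixed, the no-dominant-window category by
definition. Zero-MVPA participants are routed to an explicit stratum, never
silently labelled mixed.

**Nocturnal filter.** Participants with more than 10% of activity between
01:00 and 04:00 are excluded as non-diurnal. "Activity" here is
acceleration-weighted (the VM sum per clock hour), not MVPA minutes:
night-time MVPA is typically zero, which would defang the filter; an
MVPA-based variant is computed alongside for sensitivity. The threshold is
strict (a share of exactly 10% is kept).

## Window discovery

The three analysis windows are reproduced by an outcome-based scan. 2-h
groups (3-h for 21:00–24:00, keeping that sparse late-evening group
fittable) are assigned by the strict >50% rule; each group is fitted
against the mixed reference; windows with zero events are flagged unstable
and skipped. A window is *elevated* when its point hazard ratio exceeds 1 —
the qualitative reading of "higher risk" — with a CI-based variant
(lower 1−α bound > 1) available by configuration. Change points are the
grid boundaries where the elevated flag flips between consecutive stable
windows. No formal change-point test is attempted: the flip rule is this
package's explicit operationalization of boundaries being "observed".

The planted-recovery experiment (and its test) uses the CI variant at
α = 0.01: under the point rule a truly null window's flag is a coin flip,
so exact recovery of {11:00, 17:00} in ≥ 90% of replicates — or a clean
"null cohort ⇒ no change points" behaviour — is impossible by construction.

## Survival models

**Cox levels.** Model 1 adjusts for age and sex; model 2 adds ethnicity,
deprivation, region, education, wear season, diet score, smoking and
alcohol; model 3 adds sleep duration, sleep midpoint and total MVPA volume
(entered as log(1 + min/week)). The covariate sets are strictly nested and
the nesting is tested via the partial likelihoods. Ties are handled by the
Efron approximation (lifelines' default). Groups with zero events of the
outcome are dropped from the contrast list rather than left to diverge.
The events-per-parameter rule of thumb (≥ 10) is enforced as a logged
warning, not a hard error.

**Splines.** Dose-response curves use a restricted (natural) cubic spline
with 4 knots at the (5, 35, 65, 95)% exposure quantiles, exposure
winsorized at the 99th percentile. The basis block is orthonormalized
in-sample (a QR transform with triangular mixing, so the leading column
still spans the linear term): the raw truncated-power columns are nearly
collinear for skewed exposures and can stall the Newton iterations without
changing the model span. Degrees of freedom are fixed rather than chosen
by cross-validation so that `P_overall` (all spline terms, LRT df = 3) and
`P_nonlinear` (nonlinear terms versus linearity, df = 2) are exact
likelihood-ratio tests; the knot count is configurable. Curves are
normalized to HR = 1 at the exposure median with delta-method bands.
Window-specific volume models adjust mutually for the other two windows
(dropping the collinear total-volume term, with a logged collinearity
guard at r > 0.95); fraction models adjust for total volume.

**Standardized risk.** Cumulative-incidence curves per timing group are
G-computed: every participant's covariates are retained, the group
indicator alone is switched, and the model-predicted cumulative incidence
is averaged over the cohort covariate distribution (direct standardization
to the full cohort).

**Competing risks.** The Fine-Gray subdistribution hazard is estimated
in-package: subjects with a competing event remain in the risk set beyond
their event time, down-weighted by G(t−)/G(s−) with G the Kaplan–Meier
censoring survivor, and the weighted counting-process data are fitted with
a time-varying Cox routine. With no competing events the expansion is the
ordinary risk set and the estimator reduces to the cause-specific Cox
model (verified to 1e-6); on competing-risk data it matches
`cmprsk::crr` to ~1e-3 in the test suite.

**Multiplicity.** Benjamini–Hochberg FDR is applied within each outcome's
fully adjusted contrast family, mirroring the main results table's
footnote scope.

**Interaction.** The four groups are dichotomized into favorable
(midday-afternoon, mixed) versus unfavorable (morning, evening); the
exposure indicator is unfavorable timing. The Cox model carries both main
effects and their product; the product-term p-value is the multiplicative
test, and the additive measures follow the standard Rothman definitions —
RERI = HR11 − HR10 − HR01 + 1, AP = RERI/HR11,
SI = (HR11 − 1)/((HR10 − 1) + (HR01 − 1)) — with delta-method CIs (log
scale for SI), the only defensible reconstruction where the original
analysis delegates to a package whose CI method is unstated. Modifiers are
binary (age ≥ 65, male sex, MVPA ≥ 150 min/week per the WHO guideline
threshold, CVD history, obesity); the covariate duplicating the modifier is
dropped from the adjustment set. Subgroup analyses fit the favorable
contrast within each stratum.

## The synthetic-data generator

**What it emulates.** 7-day, 5-s VM traces with diurnal structure;
archetype-driven MVPA placement; non-wear episodes; nocturnal outliers;
a phenotype-level shortcut for survival-scale cohorts; exponential
cause-specific hazards with planted group effects and administrative
censoring at 7.0 years (the study's median follow-up) — the simplest model
satisfying proportional hazards exactly. Covariate effects default to zero
so that timing-group recovery is isolated; effects can be planted per
cause on any numeric column. Weekly MVPA is log-normal with median
113.83 min/week and σ = 0.9639, derived analytically from the published
median and IQR (158.67). Covariate marginals match the published baseline
table frequencies; covariates are drawn independently of the timing group,
so adjusted and unadjusted planted effects coincide.

**Epoch-level design.** No distributional description of within-window
placement exists in the source analysis, so the archetype templates are
invented and deliberately simple: a target share (the *concentration*,
default 0.7) of a participant's sessions is allocated to the archetype
window by largest-remainder rounding, the remainder spread over the other
windows by width (mixed archetypes are balanced across windows), sessions
landing on uniformly drawn clock-aligned blocks. Baseline (non-MVPA) VM is
a bounded rest/burst mixture — daytime 70% Exp(5 mg) + 30% U(85, 99) mg,
night 92% Exp(4 mg) + 8% U(50, 250) mg — chosen so that three properties
hold *by construction*: baseline noise can never satisfy the moderate or
vigorous rules (day values are capped below 100 mg); per-epoch dispersion
stays far above the 13 mg non-wear threshold, so worn time is never
misflagged; and the across-day slot-mean dispersion also stays above the
threshold, so slot-mean imputation cannot manufacture new stationary runs
(this is what makes detect → impute → re-detect a fixed point). Nocturnal
outliers raise the night burst rate to 60%, pushing the 01:00–04:00
activity share above 10% without creating detectable night MVPA. Non-wear
episodes (Poisson-many per participant, 1–3 h, constant zero signal) may
clobber planted sessions; the concentration margin keeps archetype
recovery ≥ 95% regardless.

**Phenotype-level design.** Timing archetypes are drawn at the published
group-mix proportions; a pure archetype's dominant-window fraction is drawn
uniformly between the cutoff and ≈ 2·concentration − cutoff, and mixed
rows are resampled until every window sits below the cutoff — "fractions
consistent with group" is therefore a structural invariant, not a sampling
accident. Survival times are exponential per cause with the reference-group
rate solved from the target 7-year cumulative event rate given the group
mix and planted hazard ratios (all-cause ≈ 3.35%, CVD ≈ 1.17%,
cancer ≈ 2.03%; cause-specific scenarios add a null competing cause
topping mortality up to the all-cause rate).

**What passing tests do not show.** The generator's traces are far cleaner
than real accelerometry: no posture artefacts, no partial wear days beyond
the inserted episodes, no seasonal or day-of-week structure, no
correlation between covariates and activity timing, no measurement error
in the covariates, and proportional hazards hold exactly. Recovery of
planted parameters therefore validates the *estimators and plumbing*, not
the substantive epidemiology; confounding control, in particular, is only
exercised mechanically.

## Reference experiments and problem sizes

The reproduction script and the acceptance-style tests use: n = 50,000
cohorts for hazard-ratio recovery (24 replicates for CVD, 16 for
all-cause, recovered HRs averaged on the log scale — at these event counts
a single replicate leaves ~10% Monte-Carlo noise on a hazard ratio, the
averages ~2%); 20 replicates for the window-discovery experiment (planted
HR 2.0 on the six elevated 2-h groups, CI rule at α = 0.01); 200 epoch
participants for oracle equivalence; 200 null replicates at n = 5,000 for
FDR calibration, testing twelve null contrasts per replicate (three group
contrasts plus the favorable/unfavorable contrast, per outcome). These
sizes keep each experiment to minutes on one CPU while leaving planted
effects many standard errors from their decision boundaries.

## Known limitations

- Single seeded imputation (plus a complete-case mode) stands in for
  chained-equations multiple imputation; pooling across imputations is not
  implemented. The imputation model uses all complete numeric covariates.
- The spline degrees of freedom are fixed, not selected; no penalized/GCV
  machinery.
- Proportional-hazards diagnostics are limited to what lifelines exposes;
  no left truncation or time-varying exposures.
- Local clock time only; daylight-saving transitions and shift-work
  sensitivity exist as flag pass-throughs, not simulated phenomena.
- The Fine-Gray expansion is O(competing events × event times) rows, fine
  at test scale but not optimized for very large cohorts.
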