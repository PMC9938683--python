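"""Cox estimation, splines, Fine-Gray, FDR, interaction and subgroups."""

import dataclasses
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chronoactivity import scenarios
from chronoactivity.simulate import (
    SimulationConfig,
    generate_phenotype_cohort,
    generate_survival,
)
from chronoactivity.survival import (
    dose_response_spline,
    fdr_adjust,
    fine_gray,
    finegray_expand,
    fit_timing_cox,
    interaction_analysis,
    reri_from_hrs,
    standardized_risk_curves,
    subgroup_analysis,
    timing_table,
)
from chronoactivity.timing import MIXED


class TestTimingCox:
    def test_null_cohort_recovers_unit_hazards(self, null_cohort):
        fit = fit_timing_cox(null_cohort, "all_cause", model_level=1)
        contrasts = fit.table[fit.table["group"] != "morning"]
        assert np.abs(np.log(contrasts["hr"])).max() < 0.3
        assert ((contrasts["ci_low"] <= 1.0) & (1.0 <= contrasts["ci_high"])).all()

    def test_events_and_person_years_partition(self, null_cohort):
        fit = fit_timing_cox(null_cohort, "cvd", model_level=1)
        assert fit.table["events"].sum() == (null_cohort["event_cause"] == "cvd").sum()
        assert fit.table["person_years"].sum() == pytest.approx(
            null_cohort["followup_years"].sum()
        )

    def test_rank_invariance_to_monotone_time_transform(self, null_cohort):
        sub = null_cohort.head(5_000)
        doubled = sub.copy()
        doubled["followup_years"] = 2.0 * doubled["followup_years"]
        a = fit_timing_cox(sub, "all_cause", model_level=1).table
        b = fit_timing_cox(doubled, "all_cause", model_level=1).table
        np.testing.assert_allclose(a["hr"], b["hr"], rtol=1e-6)

    def test_nested_models_increase_log_likelihood(self, cvd_recovery_cohort):
        ll = {
            level: fit_timing_cox(
                cvd_recovery_cohort, "cvd", model_level=level
            ).log_likelihood
            for level in (1, 3)
        }
        assert ll[3] >= ll[1]

    def test_missing_reference_group_is_an_error(self, null_cohort):
        sub = null_cohort[null_cohort["timing_group"] != "morning"]
        with pytest.raises(ValueError, match="reference"):
            fit_timing_cox(sub, "all_cause", model_level=1)

    def test_timing_table_applies_fdr_to_model3_family(self, cvd_recovery_cohort):
        table = timing_table(
            cvd_recovery_cohort, outcomes=("cvd",), model_levels=(1, 3)
        )
        m3 = table[(table["model"] == 3) & table["p"].notna()]
        m1 = table[(table["model"] == 1) & table["p"].notna()]
        assert m3["p_fdr"].notna().all() and m1["p_fdr"].isna().all()
        assert (m3["p_fdr"] >= m3["p"] - 1e-12).all()


class TestFDR:
    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.3]), [0.3])

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        p = np.array(pvals)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSplines:
    def test_linear_truth_linear_curve(self):
        config = scenarios.null_config(n=20_000, seed=3)
        cohort, _ = generate_phenotype_cohort(config)
        cohort["mvpa_log_c"] = np.log1p(cohort["weekly_mvpa_min"]) - np.log1p(113.83)
        config = dataclasses.replace(
            config, covariate_log_hr={"cancer": {"mvpa_log_c": -0.35}}
        )
        cohort = generate_survival(cohort, config)
        cohort["mvpa_log"] = np.log1p(cohort["weekly_mvpa_min"])
        res = dose_response_spline(cohort, "mvpa_log", "cancer", model_level=1)
        assert res.p_overall < 1e-4
        assert res.p_nonlinear > 0.01
        assert res.curve["hr"].iloc[0] > res.curve["hr"].iloc[-1]  # decreasing

    def test_plateau_truth_detected_as_nonlinear(self):
        config = scenarios.null_config(n=25_000, seed=9)
        cohort, _ = generate_phenotype_cohort(config)
        cohort["plateau_lp"] = -1.2 * (
            np.minimum(cohort["weekly_mvpa_min"], 150.0) / 150.0 - 0.6
        )
        config = dataclasses.replace(
            config, covariate_log_hr={"cancer": {"plateau_lp": 1.0}}
        )
        cohort = generate_survival(cohort, config)
        res = dose_response_spline(cohort, "weekly_mvpa_min", "cancer", model_level=1)
        assert res.p_overall < 1e-6 and res.p_nonlinear < 0.01
        hr = res.curve.set_index("grid")["hr"]
        below = hr.iloc[0] / np.interp(150.0, hr.index, hr.to_numpy())
        beyond = np.interp(150.0, hr.index, hr.to_numpy()) / hr.iloc[-1]
        assert below > beyond  # steep decline below ~150, flatter beyond

    def test_null_exposure_p_values_are_calibrated(self):
        pvals = []
        for seed in range(20):
            config = scenarios.null_config(n=3_000, seed=1000 + seed)
            cohort, _ = generate_phenotype_cohort(config)
            cohort = generate_survival(cohort, config)
            res = dose_response_spline(
                cohort, "weekly_mvpa_min", "cancer", model_level=0
            )
            pvals.append(res.p_overall)
        assert np.mean(np.array(pvals) < 0.05) <= 0.25

    def test_degenerate_exposure_is_an_error(self, null_cohort):
        df = null_cohort.head(1000).copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            dose_response_spline(df, "flat", "all_cause", model_level=0)

    def test_curve_is_unity_at_reference(self, null_cohort):
        res = dose_response_spline(
            null_cohort, "weekly_mvpa_min", "all_cause", model_level=0
        )
        at_ref = np.interp(
            res.reference_value, res.curve["grid"], res.curve["hr"]
        )
        assert at_ref == pytest.approx(1.0, abs=0.02)


class TestStandardizedRiskCurves:
    def test_curves_start_at_zero_and_are_nondecreasing(self, cvd_recovery_cohort):
        curves = standardized_risk_curves(cvd_recovery_cohort, "cvd", model_level=1)
        for group in ("morning", "midday_afternoon", "evening", MIXED):
            risks = curves[group].to_numpy()
            assert risks[0] == pytest.approx(0.0, abs=1e-9)
            assert (np.diff(risks) >= -1e-12).all()

    def test_planted_protective_group_lies_below_reference(self, cvd_recovery_cohort):
        curves = standardized_risk_curves(cvd_recovery_cohort, "cvd", model_level=1)
        assert curves["midday_afternoon"].iloc[-1] < curves["morning"].iloc[-1]

    def test_null_cohort_curves_overlap(self, null_cohort):
        curves = standardized_risk_curves(null_cohort, "all_cause", model_level=1)
        finals = curves.iloc[-1].drop("time")
        assert finals.max() - finals.min() < 0.012


class TestFineGray:
    def test_null_planted_unit_subdistribution_hazards(self, null_cohort):
        fg = fine_gray(null_cohort.head(10_000), "cvd", model_level=1)
        contrasts = fg.table[fg.table["group"] != "morning"]
        assert np.abs(np.log(contrasts["hr"])).max() < 0.45

    def test_strong_competing_risk_attenuates_subdistribution_hr(self):
        config = SimulationConfig(
            n_participants=20_000,
            seed=31,
            archetype_mix=scenarios.timing_group_mix(),
            planted_log_hr={
                "cvd": {g: 0.0 for g in scenarios.TIMING_GROUP_COUNTS},
                "other": {
                    "morning": 0.0,
                    "midday_afternoon": 0.0,
                    "evening": float(np.log(3.0)),
                    MIXED: 0.0,
                },
            },
            baseline_hazard={"cvd": 0.002, "other": 0.006},
        )
        cohort, _ = generate_phenotype_cohort(config)
        cohort = generate_survival(cohort, config)
        cox = fit_timing_cox(cohort, "cvd", model_level=0).table.set_index("group")
        fg = fine_gray(cohort, "cvd", model_level=0).table.set_index("group")
        # evening loses subdistribution risk to its excess competing hazard
        assert fg.loc["evening", "hr"] < cox.loc["evening", "hr"]

    def test_matches_r_cmprsk_reference(self):
        rng = np.random.default_rng(42)
        n = 600
        x = rng.binomial(1, 0.5, n).astype(float)
        z = rng.normal(0, 1, n)
        t1 = rng.exponential(1.0 / (0.02 * np.exp(0.6 * x + 0.3 * z)))
        t2 = rng.exponential(1.0 / (0.015 * np.exp(-0.2 * x)))
        c = np.minimum(rng.exponential(1.0 / 0.05), 7.0)
        t = np.minimum(np.minimum(t1, t2), c)
        status = np.where(t == c, 0, np.where(t1 < t2, 1, 2))

        expanded = finegray_expand(t, status == 1, status == 2)
        X = pd.DataFrame({"x": x, "z": z})
        df = pd.concat(
            [expanded, X.iloc[expanded["id"]].reset_index(drop=True)], axis=1
        )
        from lifelines import CoxTimeVaryingFitter
        import warnings

        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                df, id_col="id", start_col="start", stop_col="stop",
                event_col="event", weights_col="weight",
                fit_options={"precision": 1e-10},
            )
        with tempfile.TemporaryDirectory() as d:
            pd.DataFrame({"t": t, "status": status, "x": x, "z": z}).to_csv(
                f"{d}/dat.csv", index=False
            )
            rcode = (
                f'd <- read.csv("{d}/dat.csv"); suppressMessages(library(cmprsk)); '
                "f <- crr(d$t, d$status, cbind(d$x, d$z), failcode=1, cencode=0); "
                'cat(f$coef, sep="\\n")'
            )
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
            )
        ref = [float(v) for v in out.stdout.strip().splitlines()[-2:]]
        np.testing.assert_allclose(
            [ctv.params_["x"], ctv.params_["z"]], ref, atol=1e-3
        )


class TestInteraction:
    def test_reri_arithmetic_identities(self):
        assert reri_from_hrs(2.0, 2.0, 4.0) == (1.0, 0.25, 1.5)
        reri, ap, _ = reri_from_hrs(1.0, 1.0, 1.0)
        assert reri == 0.0 and ap == 0.0

    def test_result_satisfies_identities_exactly(self, cvd_recovery_cohort):
        res = interaction_analysis(cvd_recovery_cohort, "cvd", "male", model_level=1)
        expected = reri_from_hrs(res.hr10, res.hr01, res.hr11)
        assert res.reri == pytest.approx(expected[0], abs=1e-12)
        assert res.ap == pytest.approx(expected[1], abs=1e-12)

    def test_exact_additivity_gives_null_reri(self):
        rng = np.random.default_rng(17)
        n = 30_000
        x1 = rng.binomial(1, 0.5, n)
        x2 = rng.binomial(1, 0.3, n)
        rate = 0.004 * (1.0 + 1.0 * x1 + 1.0 * x2)  # HR11 = HR10 + HR01 - 1
        t = rng.exponential(1.0 / rate)
        cohort = pd.DataFrame(
            {
                "timing_group": np.where(x1 == 1, "morning", MIXED),
                "modifier": x2,
                "followup_years": np.minimum(t, 7.0),
                "event_cause": np.where(t < 7.0, "all_cause", "none"),
            }
        )
        res = interaction_analysis(cohort, "all_cause", "modifier", model_level=0)
        assert res.reri_ci[0] <= 0.0 <= res.reri_ci[1]
        assert abs(res.reri) < 0.5

    def test_empty_cell_is_an_error(self, null_cohort):
        df = null_cohort.head(2000).copy()
        df["never"] = 0
        with pytest.raises(ValueError, match="binary|empty"):
            interaction_analysis(df, "all_cause", "never", model_level=0)


class TestSubgroups:
    def test_planted_stratum_specific_effect_recovered(self):
        config = scenarios.null_config(n=40_000, seed=23)
        cohort, _ = generate_phenotype_cohort(config)
        favorable = cohort["timing_group"].isin(["midday_afternoon", MIXED])
        obese = cohort["obesity"].astype(int)
        cohort["stratum_lp"] = favorable.to_numpy() * obese.to_numpy() * float(
            np.log(0.5)
        )
        config = dataclasses.replace(
            config,
            covariate_log_hr={"cancer": {"stratum_lp": 1.0}},
            baseline_hazard={"cancer": 0.006},
        )
        cohort = generate_survival(cohort, config)
        cohort["obese"] = obese
        table = subgroup_analysis(cohort, "cancer", "obese", model_level=1).set_index(
            "stratum"
        )
        assert table.loc[1, "hr"] < 0.7 < table.loc[0, "ci_high"]
        assert table.loc[0, "ci_low"] <= 1.0 <= table.loc[0, "ci_high"]

        # pooled log-HR lies between the stratum estimates (approximate
        # collapsibility for shared-covariate models)
        x = cohort["timing_group"].isin(["midday_afternoon", MIXED]).astype(float)
        pooled_cohort = cohort.assign(x_favorable=x)
        pooled = subgroup_analysis(
            pooled_cohort.assign(all_one=1), "cancer", "all_one", model_level=1
        )
        lo = np.log(table["hr"]).min() - 0.1
        hi = np.log(table["hr"]).max() + 0.1
        assert lo <= np.log(pooled["hr"].iloc[0]) <= hi
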