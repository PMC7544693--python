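"""Continuum model: milestone inversion with bootstrap CIs, transition
tables, group comparison and the education-stratified pipeline."""

import numpy as np
import pandas as pd
import pytest

from adprogress import (
    HIGHER_EDUCATION_EQUATION,
    LOWER_EDUCATION_EQUATION,
    PUBLISHED_EQUATIONS,
    TOTAL_EQUATION,
    QuadraticLogModel,
    compare_groups_at_milestone,
    fit_continuum,
    milestone_times,
    stitch,
    stratified_pipeline,
    transition_times,
)
from tests.conftest import simulate_cohort

COV3 = np.diag([1e-3, 1e-7, 1e-11])


class TestMilestoneTimes:
    @pytest.mark.parametrize("name", sorted(PUBLISHED_EQUATIONS))
    def test_times_increase_and_durations_telescope(self, name):
        mt = milestone_times(PUBLISHED_EQUATIONS[name], B=200, seed=0)
        t = mt.table["time_months"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert mt.durations["duration"].sum() == pytest.approx(
            t[-1] - t[0], abs=1e-9)
        assert (mt.durations["duration"] > 0).all()

    def test_published_lower_education_segments(self):
        mt = milestone_times(LOWER_EDUCATION_EQUATION, [2.5, 4.5], B=200, seed=0)
        assert mt.table["time_months"].iloc[0] == pytest.approx(137.1, abs=0.1)
        assert mt.table["time_months"].iloc[1] == pytest.approx(180.0, abs=0.1)
        assert mt.durations["duration"].iloc[0] == pytest.approx(42.9, abs=0.1)

    def test_degenerate_covariance_gives_point_intervals(self):
        mt = milestone_times(TOTAL_EQUATION, [2.5, 18.0], B=500, seed=1)
        for _, row in mt.table.iterrows():
            assert row["ci_lo"] == row["time_months"] == row["ci_hi"]

    def test_milestone_below_origin_flagged_not_dropped(self):
        mt = milestone_times(TOTAL_EQUATION, [0.0, 2.5], B=200, seed=0)
        assert len(mt.table) == 2
        assert mt.table["note"].iloc[0] != ""
        assert mt.table["time_months"].iloc[0] == 0.0

    def test_bootstrap_intervals_contract_with_covariance(self):
        wide = QuadraticLogModel.from_coefficients(
            -0.06, 0.004275, 2.4e-5, fixed_cov=COV3)
        narrow = QuadraticLogModel.from_coefficients(
            -0.06, 0.004275, 2.4e-5, fixed_cov=COV3 / 16)
        w = milestone_times(wide, [4.5], B=4000, seed=5)
        n = milestone_times(narrow, [4.5], B=4000, seed=5)
        width = lambda mt: mt.table["ci_hi"].iloc[0] - mt.table["ci_lo"].iloc[0]
        assert width(n) < width(w)
        assert width(n) > 0

    def test_percentile_bounds_stabilize_with_draws(self):
        m = QuadraticLogModel.from_coefficients(
            -0.06, 0.004275, 2.4e-5, fixed_cov=COV3)
        los = {B: [milestone_times(m, [4.5], B=B, seed=s).table["ci_lo"].iloc[0]
                   for s in range(6)] for B in (400, 25600)}
        assert np.var(los[25600]) < np.var(los[400])

    def test_delta_method_agrees_with_bootstrap(self):
        m = QuadraticLogModel.from_coefficients(
            -0.06, 0.004275, 2.4e-5, fixed_cov=COV3 / 4)
        boot = milestone_times(m, [4.5], B=20000, seed=3)
        delta = milestone_times(m, [4.5], method="delta")
        assert boot.table["ci_lo"].iloc[0] == pytest.approx(
            delta.table["ci_lo"].iloc[0], rel=0.05)
        assert boot.table["ci_hi"].iloc[0] == pytest.approx(
            delta.table["ci_hi"].iloc[0], rel=0.05)


class TestContinuumFit:
    def test_refit_on_own_noiseless_curve_is_exact(self):
        grid = np.linspace(0, 260, 40)
        frames = []
        for pid in range(4):  # several identical noiseless "patients"
            frames.append(pd.DataFrame({
                "patient_id": f"p{pid}", "cohort": "ALL",
                "time_months": grid,
                "cdrsb": np.clip(TOTAL_EQUATION.predict(grid), 0, 18),
                "education_years": 12}))
        cont = fit_continuum(pd.concat(frames, ignore_index=True))
        np.testing.assert_allclose(cont.model.coefficients,
                                   TOTAL_EQUATION.coefficients, atol=1e-6)

    def test_origin_score_of_published_curve(self):
        # the continuum origin is not score 0: exp(beta0) - 0.5 ~ 0.44
        assert TOTAL_EQUATION.origin_score == pytest.approx(
            np.exp(-0.06008) - 0.5, abs=1e-12)
        assert TOTAL_EQUATION.origin_score == pytest.approx(0.44, abs=0.005)

    def test_first_cohort_offset_must_be_zero(self):
        with pytest.raises(ValueError, match="offset"):
            fit_continuum(
                pd.DataFrame({"patient_id": ["a"] * 5 + ["b"] * 5,
                              "cohort": "SCI",
                              "time_months": [0, 10, 20, 30, 40] * 2,
                              "cdrsb": [1, 1.5, 2, 2.5, 3,
                                        1, 2, 2.5, 3, 3.5],
                              "education_years": 12}),
                offsets={"SCI": 5.0})


class TestTransitionTimes:
    def test_single_cohort_gives_empty_table(self, three_latent_cohorts):
        st = stitch(three_latent_cohorts[:1])
        table = transition_times(st, B=200, seed=0)
        assert len(table) == 0

    def test_known_latent_offsets_recovered(self, three_latent_cohorts):
        st = stitch(three_latent_cohorts)
        table = transition_times(st, B=400, seed=0)
        assert list(table["pair"]) == ["SCI->AMCI", "AMCI->ADD"]
        assert table["months"].iloc[0] == pytest.approx(110, abs=12)
        assert table["months"].iloc[1] == pytest.approx(60, abs=12)
        # cumulative time telescopes exactly
        assert table["cumulative_months"].iloc[1] == pytest.approx(
            table["months"].sum(), abs=1e-9)
        # bootstrap interval brackets the point estimate
        assert table["months_lo"].iloc[0] < table["months"].iloc[0] \
            < table["months_hi"].iloc[0]


class TestGroupComparison:
    def test_identical_models_have_zero_difference(self):
        m = QuadraticLogModel.from_coefficients(-0.06, 0.004, 2e-5,
                                                fixed_cov=COV3)
        cmp = compare_groups_at_milestone(m, m, 4.5, B=2000, seed=0)
        assert cmp.difference == pytest.approx(0.0, abs=1e-9)
        assert cmp.ci_overlap

    def test_education_gap_at_first_breakpoint(self):
        cmp = compare_groups_at_milestone(
            LOWER_EDUCATION_EQUATION, HIGHER_EDUCATION_EQUATION, 2.5,
            B=200, seed=0)
        assert cmp.difference == pytest.approx(37.7, abs=0.2)

    def test_distinct_point_models_do_not_overlap(self):
        cmp = compare_groups_at_milestone(
            LOWER_EDUCATION_EQUATION, HIGHER_EDUCATION_EQUATION, 2.5,
            B=200, seed=0)
        assert not cmp.ci_overlap  # zero-covariance models give point CIs


class TestStratifiedPipeline:
    def test_empty_stratum_is_named_error(self, three_latent_cohorts):
        rec = pd.concat([r for _, r in three_latent_cohorts], ignore_index=True)
        with pytest.raises(ValueError, match="lower"):
            stratified_pipeline(rec, education_cutoff_years=0, B=100)

    def test_identical_strata_give_similar_continua(self, fig_process):
        """Exchangeability: when both education strata are generated from
        the same process, the stratified fits agree within simulation
        error."""
        rng = np.random.default_rng(55)
        frames = []
        for label, entry in (("SCI", 0.0), ("AMCI", 110.0), ("ADD", 170.0)):
            for edu in (8, 16):
                c = simulate_cohort(fig_process, 55, rng, entry_low=entry,
                                    entry_high=entry, interval_mean=22.0,
                                    label=label, education_years=edu)
                c["patient_id"] = c["patient_id"] + f"-e{edu}"
                frames.append(c)
        rec = pd.concat(frames, ignore_index=True)
        res = stratified_pipeline(rec, B=200, seed=2)
        assert set(res) == {"total", "lower", "higher"}
        t_lo = res["lower"].milestones.table.set_index("milestone")
        t_hi = res["higher"].milestones.table.set_index("milestone")
        assert t_lo.loc[4.5, "time_months"] == pytest.approx(
            t_hi.loc[4.5, "time_months"], abs=20)

    def test_faster_lower_stratum_reaches_breakpoint_earlier(self):
        """Sign check against the generating truth: strata simulated from
        the published education-specific curves (lower education declines
        faster early) must order the fitted times to CDR-SB 2.5 the same
        way."""
        from adprogress import TrueProcess
        rng = np.random.default_rng(91)
        frames = []
        for stratum, eq, edu in (("lower", LOWER_EDUCATION_EQUATION, 8),
                                 ("higher", HIGHER_EDUCATION_EQUATION, 16)):
            proc = TrueProcess(eq.beta0, eq.beta1, eq.beta2,
                               sigma_b=0.20, sigma_e=0.15)
            for label, entry in (("SCI", 0.0), ("AMCI", 110.0), ("ADD", 170.0)):
                c = simulate_cohort(proc, 50, rng, entry_low=entry,
                                    entry_high=entry, interval_mean=22.0,
                                    label=label, education_years=edu)
                c["patient_id"] = c["patient_id"] + f"-{stratum}"
                frames.append(c)
        res = stratified_pipeline(pd.concat(frames, ignore_index=True),
                                  B=200, seed=4)
        t = {s: res[s].milestones.table.set_index("milestone")
             .loc[2.5, "time_months"] for s in ("lower", "higher")}
        assert t["lower"] < t["higher"]

    def test_pipeline_counts_partition_patients(self, fig_process):
        rng = np.random.default_rng(56)
        frames = []
        for label, entry in (("SCI", 0.0), ("AMCI", 110.0), ("ADD", 170.0)):
            for edu in (8, 16):
                c = simulate_cohort(fig_process, 40, rng, entry_low=entry,
                                    entry_high=entry, interval_mean=22.0,
                                    label=label, education_years=edu)
                c["patient_id"] = c["patient_id"] + f"-e{edu}"
                frames.append(c)
        rec = pd.concat(frames, ignore_index=True)
        res = stratified_pipeline(rec, B=100, seed=0)
        assert res["lower"].n_patients + res["higher"].n_patients \
            == res["total"].n_patients
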