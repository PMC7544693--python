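"""Trajectory model: transform round-trip, information criteria, ML fit
correctness (incl. an independent lme4 oracle), residuals and the
outlier pass."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adprogress import test_quadratic_term as choose_time_specification
from adprogress import (
    TrueProcess,
    back_transform,
    fit_lmm,
    information_criteria,
    log_transform,
    remove_outliers_and_refit,
    studentized_residuals,
)
from tests.conftest import simulate_cohort


class TestLogTransform:
    def test_analytic_endpoints(self):
        assert log_transform(0.0) == pytest.approx(np.log(0.5))
        assert log_transform(18.0) == pytest.approx(np.log(18.5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 18.0))
    def test_round_trip_identity(self, x):
        assert back_transform(log_transform(x)) == pytest.approx(x, abs=1e-12)

    def test_negative_score_is_domain_error(self):
        with pytest.raises(ValueError):
            log_transform(-0.5)


class TestInformationCriteria:
    def test_hand_computed_example(self):
        aic, bic, aicc = information_criteria(0.0, 5, 100)
        assert aic == pytest.approx(10.0)
        assert bic == pytest.approx(5 * np.log(100))
        assert aicc == pytest.approx(10.0 + 60.0 / 94.0)

    def test_zero_parameters_collapse(self):
        aic, bic, aicc = information_criteria(-7.0, 0, 50)
        assert aic == bic == aicc == 14.0

    def test_aicc_approaches_aic_for_large_n(self):
        gaps = [information_criteria(0.0, 4, n)[2] - information_criteria(0.0, 4, n)[0]
                for n in (20, 200, 2000)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            information_criteria(0.0, 5, 6)


class TestFitLmm:
    def test_noiseless_data_recovers_exact_coefficients(self):
        proc = TrueProcess(-0.06008, 0.004275, 0.000024)
        rec = simulate_cohort(proc, 8, np.random.default_rng(1),
                              entry_low=0, entry_high=150, round_to_grid=False)
        # entries vary per patient, but with zero noise every observation
        # still lies on one polynomial in latent time; fit on the latent
        # clock to compare against the generating curve
        rec = rec.assign(time_months=rec["latent_time"])
        m = fit_lmm(rec, include_quadratic=True)
        assert m.beta0 == pytest.approx(proc.beta0, abs=1e-6)
        assert m.beta1 == pytest.approx(proc.beta1, abs=1e-6)
        assert m.beta2 == pytest.approx(proc.beta2, abs=1e-6)
        assert m.sigma_b == 0.0

    def test_row_permutation_invariance(self, noisy_cohort):
        m1 = fit_lmm(noisy_cohort)
        shuffled = noisy_cohort.sample(frac=1.0, random_state=3)
        m2 = fit_lmm(shuffled)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-9)
        assert m1.loglik == pytest.approx(m2.loglik, rel=1e-9)

    def test_patient_relabeling_invariance(self, noisy_cohort):
        m1 = fit_lmm(noisy_cohort)
        relabeled = noisy_cohort.assign(
            patient_id="x" + noisy_cohort["patient_id"].astype(str))
        m2 = fit_lmm(relabeled)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, rtol=1e-9)

    def test_all_times_equal_is_singular(self):
        rec = pd.DataFrame({"patient_id": ["a"] * 2 + ["b"] * 2,
                            "cohort": "SCI", "time_months": 5.0,
                            "cdrsb": [1.0, 2.0, 1.5, 2.5]})
        with pytest.raises(ValueError, match="singular"):
            fit_lmm(rec)

    def test_matches_lme4_oracle(self, fig_process):
        """Independent cross-check of the ML mixed-model fit against
        R lme4 on a 30-patient fixture."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        rec = simulate_cohort(fig_process, 30, rng, entry_low=0, entry_high=120,
                              n_visits_range=(5, 5), interval_mean=18,
                              round_to_grid=False)
        m = fit_lmm(rec, include_quadratic=True)
        csv = "/tmp/adprogress_lme4_fixture.csv"
        rec.assign(y=log_transform(rec["cdrsb"].to_numpy())).to_csv(csv, index=False)
        out = subprocess.run(
            ["Rscript", "-e",
             "suppressMessages(library(lme4));"
             f"d <- read.csv('{csv}');"
             "f <- lmer(y ~ time_months + I(time_months^2) + (1|patient_id),"
             "          data=d, REML=FALSE);"
             "cat(fixef(f), sqrt(unlist(VarCorr(f))), sigma(f), logLik(f), sep='\\n')"],
            capture_output=True, text=True, check=True)
        b0, b1, b2, sb, se, ll = (float(x) for x in out.stdout.split())
        np.testing.assert_allclose(m.coefficients, [b0, b1, b2], rtol=1e-4)
        assert m.sigma_b == pytest.approx(sb, rel=1e-3)
        assert m.sigma_e == pytest.approx(se, rel=1e-3)
        assert m.loglik == pytest.approx(ll, abs=1e-3)


class TestQuadraticTermChoice:
    def test_pvalue_in_unit_interval_and_strong_curvature_retained(self, fig_process):
        rec = simulate_cohort(fig_process, 150, np.random.default_rng(8),
                              entry_low=0, entry_high=160, round_to_grid=False)
        rec = rec.assign(time_months=rec["latent_time"])
        p, chosen = choose_time_specification(rec)
        assert 0.0 <= p <= 1.0
        assert chosen.has_quadratic  # curvature of the published magnitude

    def test_linear_truth_usually_dropped(self):
        proc = TrueProcess(-0.06, 0.0055, 0.0, sigma_b=0.15, sigma_e=0.10)
        rec = simulate_cohort(proc, 80, np.random.default_rng(12),
                              entry_low=0, entry_high=0, round_to_grid=False)
        p, chosen = choose_time_specification(rec)
        assert not chosen.has_quadratic
        assert p > 0.05


class TestResidualsAndOutliers:
    def test_zero_noise_residuals_vanish(self):
        proc = TrueProcess(-0.06, 0.005, 1e-5)
        rec = simulate_cohort(proc, 6, np.random.default_rng(4),
                              entry_low=0, entry_high=0, round_to_grid=False)
        m = fit_lmm(rec)
        r = studentized_residuals(m, rec)
        assert len(r) == len(rec)
        # conditional residuals of an exact fit are numerically zero
        y = log_transform(rec["cdrsb"].to_numpy())
        fitted = m.predict_log(rec["time_months"].to_numpy())
        assert np.abs(y - fitted).max() < 1e-9

    def test_displaced_observation_flags_above_three(self, noisy_cohort):
        rec = noisy_cohort.copy().reset_index(drop=True)
        m0 = fit_lmm(rec)
        i = 17
        rec.loc[i, "cdrsb"] = back_transform(
            log_transform(rec.loc[i, "cdrsb"]) + 10 * m0.sigma_e)
        m = fit_lmm(rec)
        r = studentized_residuals(m, rec)
        assert abs(r.iloc[i]) > 3

    def test_residual_mean_near_zero_when_well_specified(self, noisy_cohort):
        m = fit_lmm(noisy_cohort)
        r = studentized_residuals(m, noisy_cohort).to_numpy()
        assert abs(r.mean()) < 3.0 / np.sqrt(len(r))

    def test_infinite_threshold_removes_nothing(self, noisy_cohort):
        m, report = remove_outliers_and_refit(noisy_cohort, threshold=np.inf)
        assert report.removed_obs_ids == ()
        assert report.ic_before == report.ic_after

    def test_gross_errors_removed_and_ics_improve(self, fig_process):
        rng = np.random.default_rng(99)
        rec = simulate_cohort(fig_process, 80, rng, entry_low=0, entry_high=140,
                              round_to_grid=False).reset_index(drop=True)
        hit = rng.choice(len(rec), size=max(len(rec) // 100, 3), replace=False)
        y = log_transform(rec["cdrsb"].to_numpy())
        y[hit] += 8 * fig_process.sigma_e
        rec["cdrsb"] = np.clip(back_transform(y), 0, 18)
        m, report = remove_outliers_and_refit(rec, threshold=3.0)
        assert len(report.removed_obs_ids) > 0
        assert all(a < b for a, b in zip(report.ic_after, report.ic_before))
        assert report.ic_after[2] >= report.ic_after[0]  # AICC >= AIC

    def test_flagged_set_matches_threshold_rule(self, noisy_cohort):
        before = fit_lmm(noisy_cohort)
        resid = studentized_residuals(before, noisy_cohort)
        _, report = remove_outliers_and_refit(noisy_cohort, threshold=2.0)
        assert set(report.removed_obs_ids) == \
            set(resid.index[np.abs(resid.to_numpy()) > 2.0])
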