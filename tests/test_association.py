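"""Ordinal and binary logistic association models and probability curves."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from n3grs import (
    AssociationFit,
    SeparationError,
    fit_binary,
    fit_ordinal,
    predict_curves,
    proportional_odds_diagnostic,
    subgroup_maf_tests,
)
from n3grs.genotypes import GenotypeMatrix, compare_maf
from n3grs.simulate import study_like_preset, simulate_genotypes

from conftest import covariates_frame, make_panel


def _two_by_two_cohort(r_high, ar_high, r_low, ar_low):
    labels = (["R"] * r_high + ["AR"] * ar_high + ["R"] * r_low + ["AR"] * ar_low)
    grs = [1.0] * (r_high + ar_high) + [0.0] * (r_low + ar_low)
    return labels, grs


class TestBinary:
    def test_saturated_2x2_equals_sample_odds_ratio(self):
        labels, grs = _two_by_two_cohort(10, 20, 20, 10)
        fit = fit_binary(labels, grs)
        assert fit.or_grs == pytest.approx(4.0, abs=1e-6)
        assert fit.beta_grs == pytest.approx(np.log(4.0), abs=1e-6)

    @pytest.mark.parametrize(
        "cells",
        [c for c in itertools.product([1, 3, 7, 20], repeat=4)][::11],
    )
    def test_grouped_fit_matches_closed_form_log_odds_ratio(self, cells):
        r_high, ar_high, r_low, ar_low = cells
        labels, grs = _two_by_two_cohort(*cells)
        fit = fit_binary(labels, grs)
        oracle = np.log((ar_high / r_high) / (ar_low / r_low))
        assert fit.beta_grs == pytest.approx(oracle, abs=1e-6)

    def test_mean_fitted_probability_equals_observed_frequency(self, preset_cohort):
        # exact ML score-equation identity for the intercept-containing logit
        truth = preset_cohort["truth"]
        mask = (truth.class_EPA != "NR").to_numpy()
        labels = truth.class_EPA[mask]
        grs = truth.grs_true[mask].to_numpy()
        cov = covariates_frame(preset_cohort["profiles"])[mask].reset_index(drop=True)
        fit = fit_binary(labels, grs, cov)
        sex01 = (cov["sex"] == "M").astype(float)  # reference level is "F"
        X = np.column_stack([np.ones(mask.sum()), grs, cov.age, sex01, cov.bmi])
        fitted = expit(X @ fit.params)
        assert abs(fitted.mean() - (labels == "AR").mean()) < 1e-9

    def test_rejects_nr_labels(self):
        with pytest.raises(ValueError, match="NR"):
            fit_binary(["R", "NR", "AR"], [0, 1, 2])

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_binary(["R"] * 10, np.arange(10))

    def test_rejects_constant_grs(self):
        with pytest.raises(ValueError, match="constant"):
            fit_binary(["R", "AR"] * 5, [3.0] * 10)

    def test_complete_separation_raises(self):
        labels = ["R"] * 20 + ["AR"] * 20
        grs = list(range(20)) + list(range(30, 50))
        with pytest.raises(SeparationError):
            fit_binary(labels, grs)

    def test_wald_type_i_error_calibrated(self):
        """Null rejection rate of the GRS Wald test ≈ 5% (2,000 sims, n=500)."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            grs = rng.binomial(10, 0.3, 500).astype(float)
            labels = np.where(rng.random(500) < 0.5, "AR", "R")
            fit = fit_binary(labels, grs)
            rejections += fit.wald_p < 0.05
        assert 0.035 <= rejections / n_sims <= 0.065


class TestOrdinal:
    def test_two_category_model_reduces_to_binary(self, preset_cohort):
        truth = preset_cohort["truth"]
        mask = (truth.class_EPA != "NR").to_numpy()
        labels = truth.class_EPA[mask]
        grs = truth.grs_true[mask].to_numpy()
        cov = covariates_frame(preset_cohort["profiles"])[mask].reset_index(drop=True)
        f_ord = fit_ordinal(labels, grs, cov, class_order=("R", "AR"))
        f_bin = fit_binary(labels, grs, cov)
        assert f_ord.beta_grs == pytest.approx(f_bin.beta_grs, abs=1e-6)
        assert f_ord.se_beta == pytest.approx(f_bin.se_beta, rel=1e-4)

    def test_reversed_class_order_negates_slope(self, preset_cohort):
        truth = preset_cohort["truth"]
        cov = covariates_frame(preset_cohort["profiles"])
        f = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        f_rev = fit_ordinal(
            truth.class_EPA, truth.grs_true, cov, class_order=("AR", "NR", "R")
        )
        assert f_rev.beta_grs == pytest.approx(-f.beta_grs, abs=1e-6)

    def test_average_probabilities_track_class_frequencies(self, preset_cohort):
        # approximate for the proportional-odds model (exact only for binary);
        # agreement at consistency level on n=800
        truth = preset_cohort["truth"]
        profiles = preset_cohort["profiles"]
        cov = covariates_frame(profiles)
        fit = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        sex01 = (cov["sex"] == "M").astype(float)
        X = np.column_stack([truth.grs_true, cov.age, sex01, cov.bmi])
        eta = X @ fit.params[:4]
        c1, c2 = fit.cutpoints
        avg = {
            "R": expit(c1 - eta).mean(),
            "NR": (expit(c2 - eta) - expit(c1 - eta)).mean(),
            "AR": (1 - expit(c2 - eta)).mean(),
        }
        obs = truth.class_EPA.value_counts(normalize=True)
        for cls in ("R", "NR", "AR"):
            assert abs(avg[cls] - obs[cls]) < 5e-3

    def test_cutpoints_strictly_increasing_and_or_consistent(self, preset_cohort):
        truth = preset_cohort["truth"]
        cov = covariates_frame(preset_cohort["profiles"])
        fit = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        assert fit.cutpoints[0] < fit.cutpoints[1]
        assert fit.or_grs == pytest.approx(np.exp(fit.beta_grs), rel=1e-12)
        assert 0 < fit.wald_p <= 1

    def test_missing_class_instructs_binary(self):
        with pytest.raises(ValueError, match="binary"):
            fit_ordinal(["R", "AR", "R", "AR"], [0, 1, 2, 3])


class TestCurves:
    @staticmethod
    def _null_ordinal_fit(marginals=(0.45, 0.45, 0.10)):
        """Hand-built zero-slope fit whose cutpoints encode the marginals."""
        c1 = logit(marginals[0])
        c2 = logit(marginals[0] + marginals[1])
        raw = np.array([c1, np.log(c2 - c1)])
        return AssociationFit(
            model_kind="ordinal", beta_grs=0.0, or_grs=1.0, se_beta=0.1,
            wald_p=1.0, covariate_coefficients={}, cutpoints=np.array([c1, c2]),
            n_obs=100, converged=True, class_labels=("R", "NR", "AR"),
            n_per_class={"R": 45, "NR": 45, "AR": 10}, log_likelihood=0.0,
            params=np.array([0.0, raw[0], raw[1]]),
            cov_params=np.eye(3) * 1e-4, exog_names=["grs"],
            covariate_means={}, grs_range=(0.0, 10.0), threshold_raw=raw,
        )

    def test_null_fit_gives_flat_curves_at_marginals(self):
        fit = self._null_ordinal_fit()
        curve = predict_curves(fit, np.arange(0, 11))
        for cls, expected in zip(("R", "NR", "AR"), (0.45, 0.45, 0.10)):
            np.testing.assert_allclose(
                curve.probabilities[cls], expected, atol=1e-12
            )

    def test_probabilities_sum_to_one(self, preset_cohort):
        truth = preset_cohort["truth"]
        cov = covariates_frame(preset_cohort["profiles"])
        fit = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        curve = predict_curves(fit, np.arange(-4, 14))
        total = sum(curve.probabilities[c] for c in curve.categories)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        for c in curve.categories:
            assert np.all(curve.ci_low[c] >= 0) and np.all(curve.ci_high[c] <= 1)
            assert np.all(curve.ci_low[c] <= curve.probabilities[c])
            assert np.all(curve.probabilities[c] <= curve.ci_high[c])

    def test_responder_probability_falls_with_rising_risk_score(self, preset_cohort):
        truth = preset_cohort["truth"]
        cov = covariates_frame(preset_cohort["profiles"])
        fit = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        assert fit.beta_grs > 0  # higher score → adverse-ward
        curve = predict_curves(fit, np.arange(-4, 14))
        assert np.all(np.diff(curve.probabilities["R"]) < 0)
        assert np.all(np.diff(curve.probabilities["AR"]) > 0)

    def test_extrapolation_flagged(self, preset_cohort):
        truth = preset_cohort["truth"]
        cov = covariates_frame(preset_cohort["profiles"])
        fit = fit_ordinal(truth.class_EPA, truth.grs_true, cov)
        inside = predict_curves(fit, [fit.grs_range[0], fit.grs_range[1]])
        outside = predict_curves(fit, [fit.grs_range[1] + 5])
        assert not inside.extrapolated and outside.extrapolated

    def test_binary_curve_probabilities_complementary(self, preset_cohort):
        truth = preset_cohort["truth"]
        mask = (truth.class_EPA != "NR").to_numpy()
        cov = covariates_frame(preset_cohort["profiles"])[mask].reset_index(drop=True)
        fit = fit_binary(truth.class_EPA[mask], truth.grs_true[mask].to_numpy(), cov)
        curve = predict_curves(fit, np.arange(-4, 14))
        np.testing.assert_allclose(
            curve.probabilities["R"] + curve.probabilities["AR"], 1.0, atol=1e-12
        )


class TestSubgroupMaf:
    def _matrix_and_labels(self):
        rng = np.random.default_rng(9)
        panel = make_panel(4)
        n = 80
        dosage = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        # plant a frequency-differentiated SNP (rs3) between R and AR halves
        dosage[: n // 2, 2] = rng.binomial(2, 0.05, n // 2)
        dosage[n // 2 :, 2] = rng.binomial(2, 0.6, n // 2)
        m = GenotypeMatrix([f"P{i}" for i in range(n)], panel.snp_ids, dosage)
        from n3grs.response import ResponderLabel

        labels = [
            ResponderLabel(f"P{i}", "EPA", -0.5 if i < n // 2 else 0.5,
                           "R" if i < n // 2 else "AR")
            for i in range(n)
        ]
        return m, panel, labels

    def test_planted_snp_attains_smallest_p(self):
        m, panel, labels = self._matrix_and_labels()
        comps = subgroup_maf_tests(m, panel, labels, ("R", "AR"), "EPA")
        ps = {c.snp_id: c.p_value for c in comps}
        assert min(ps, key=ps.get) == "rs3"
        assert ps["rs3"] < 1e-6

    def test_matches_two_by_two_oracle(self):
        m, panel, labels = self._matrix_and_labels()
        comps = {c.snp_id: c for c in
                 subgroup_maf_tests(m, panel, labels, ("R", "AR"), "EPA")}
        col = m.column("rs1")
        a, b = col[:40], col[40:]
        oracle = compare_maf((int(a.sum()), 80), (int(b.sum()), 80))
        assert comps["rs1"].chi_squared == pytest.approx(oracle.chi_squared, rel=1e-12)

    def test_identical_subgroups_give_p_one(self):
        m, panel, labels = self._matrix_and_labels()
        # duplicate cohort: compare a subgroup against an identical copy
        from n3grs.response import ResponderLabel

        twin = [
            ResponderLabel(p, "EPA", -0.5, "R") for p in m.participant_ids[:40]
        ] + [
            ResponderLabel(p, "EPA", 0.5, "AR") for p in m.participant_ids[:40]
        ]
        # same participants in both groups is impossible; instead give both
        # halves identical genotype rows
        dosage = np.vstack([m.dosage[:40], m.dosage[:40]])
        m2 = GenotypeMatrix([f"Q{i}" for i in range(80)], m.snp_ids, dosage)
        lab2 = [
            ResponderLabel(f"Q{i}", "EPA", -0.5 if i < 40 else 0.5,
                           "R" if i < 40 else "AR")
            for i in range(80)
        ]
        for c in subgroup_maf_tests(m2, panel, lab2, ("R", "AR"), "EPA"):
            assert c.p_value == pytest.approx(1.0)

    def test_empty_subgroup_names_pair(self):
        m, panel, labels = self._matrix_and_labels()
        with pytest.raises(ValueError, match="NR.*R-vs-NR|'NR'"):
            subgroup_maf_tests(m, panel, labels, ("R", "NR"), "EPA")


def test_proportional_odds_diagnostic_reports_similar_slopes(preset_cohort):
    truth = preset_cohort["truth"]
    cov = covariates_frame(preset_cohort["profiles"])
    diag = proportional_odds_diagnostic(truth.class_EPA, truth.grs_true, cov)
    assert len(diag["slopes_per_split"]) == 2
    # data were generated under proportional odds: no strong violation signal
    assert diag["p_value"] > 0.01
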