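"""Logistic MLE, likelihood-ratio tests, contingency tests, dose limits."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dosestrat import (PatientDose, build_covariate_table,
                       chi2_cluster_covariates, dose_limit_flags, fisher_or,
                       fit_logistic_mle, lrt_nested, lrt_nested_linear)

from conftest import uniform_curve


def _design(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"p{i}" for i in range(n)], dtype=float)


def _from_2x2(a, b, c, d):
    """Design/outcome arrays realizing 2x2 counts (x=1: a pos, b neg;
    x=0: c pos, d neg)."""
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    return _design(x=x), y


class TestFitLogisticMle:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logistic_mle(_design(x=np.zeros(100)).iloc[:, :0], y)
        assert fit.params["const"] == pytest.approx(np.log(0.25 / 0.75), abs=1e-6)

    def test_single_predictor_equals_cross_product_ratio(self):
        design, y = _from_2x2(40, 10, 20, 30)
        fit = fit_logistic_mle(design, y)
        assert fit.params["x"] == pytest.approx(np.log(6.0), abs=1e-6)
        assert fit.params["const"] == pytest.approx(np.log(20 / 30), abs=1e-6)

    def test_duplicated_column_dropped_identical_fit(self):
        design, y = _from_2x2(40, 10, 20, 30)
        dup = design.copy()
        dup["x2"] = dup["x"]
        fit0 = fit_logistic_mle(design, y)
        fit1 = fit_logistic_mle(dup, y)
        assert fit1.dropped == ("x2",)
        assert fit1.llf == pytest.approx(fit0.llf, abs=1e-9)
        assert fit1.params["x"] == pytest.approx(fit0.params["x"], abs=1e-9)

    def test_separation_falls_back_to_ridge(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()   # perfectly separated
        fit = fit_logistic_mle(_design(x=x), y)
        assert fit.ridge
        assert np.isfinite(fit.llf)


class TestLrtNested:
    def test_all_zero_added_column_is_pure_penalty(self):
        design, y = _from_2x2(40, 10, 20, 30)
        ext = design.copy()
        ext["z"] = 0.0
        base = fit_logistic_mle(design, y)
        extended = fit_logistic_mle(ext, y)
        res = lrt_nested(base, extended)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.delta_aic == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1

    def test_informative_column_detected(self):
        rng = np.random.default_rng(0)
        n = 400
        z = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.5).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + 1.5 * z)))
        y = (rng.random(n) < p).astype(float)
        base = fit_logistic_mle(_design(x=x), y)
        ext = fit_logistic_mle(_design(x=x, z=z), y)
        res = lrt_nested(base, ext)
        assert res.p_value < 1e-4
        assert res.odds_ratio == pytest.approx(np.exp(ext.params["z"]))
        assert res.delta_bic < -6  # strong evidence convention

    def test_statistic_invariant_to_affine_recoding_of_base(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(size=n)
        z = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x + z - 0.5)))).astype(float)
        r1 = lrt_nested(fit_logistic_mle(_design(x=x), y),
                        fit_logistic_mle(_design(x=x, z=z), y))
        x2 = 2.0 * x + 3.0
        r2 = lrt_nested(fit_logistic_mle(_design(x=x2), y),
                        fit_logistic_mle(_design(x=x2, z=z), y))
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-6)

    def test_aic_bic_recomputed_from_parts(self):
        design, y = _from_2x2(40, 10, 20, 30)
        fit = fit_logistic_mle(design, y)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf, abs=1e-12)
        assert fit.bic == pytest.approx(fit.k * np.log(fit.n) - 2 * fit.llf,
                                        abs=1e-12)

    def test_non_nested_rejected(self):
        d1, y = _from_2x2(40, 10, 20, 30)
        d2 = d1.rename(columns={"x": "w"})
        with pytest.raises(ValueError):
            lrt_nested(fit_logistic_mle(d1, y), fit_logistic_mle(d2, y))

    def test_linear_variant_f_test(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 2.0 + 0.5 * x + 1.0 * z + rng.normal(0, 1, n)
        res = lrt_nested_linear(_design(x=x), _design(x=x, z=z), y)
        assert res.p_value < 1e-6 and res.delta_aic < 0


class TestContingency:
    def test_chi2_closed_form_2x2(self):
        # counts (30, 10; 10, 30): chi2 = n (ad-bc)^2 / (r1 r2 c1 c2) = 20
        member = pd.Series([1] * 40 + [0] * 40)
        cov = pd.DataFrame({"c": [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30})
        res = chi2_cluster_covariates(member, cov)
        assert res.loc["c", "statistic"] == pytest.approx(20.0, abs=1e-9)
        assert res.loc["c", "p_value"] == pytest.approx(
            scipy.stats.chi2.sf(20.0, 1), abs=1e-12)

    def test_identical_covariate_is_extreme(self):
        member = pd.Series([0] * 30 + [1] * 30 + [2] * 30)
        cov = pd.DataFrame({"c": member.to_numpy()})
        res = chi2_cluster_covariates(member, cov)
        assert res.loc["c", "p_value"] < 1e-30

    def test_constant_covariate_undefined(self):
        member = pd.Series([0, 1] * 10)
        res = chi2_cluster_covariates(member, pd.DataFrame({"c": [1] * 20}))
        assert np.isnan(res.loc["c", "statistic"])


class TestFisherOr:
    def test_symmetric_table_is_unity(self):
        odds, p = fisher_or([[10, 10], [10, 10]])
        assert odds == 1.0 and p == 1.0

    def test_cross_product_ratio(self):
        odds, _ = fisher_or([[40, 10], [20, 30]])
        assert odds == pytest.approx(6.0, abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        odds, _ = fisher_or([[0, 10], [10, 10]])
        assert odds == pytest.approx((0.5 * 10.5) / (10.5 * 10.5), abs=1e-12)

    def test_empty_margin_undefined(self):
        odds, _ = fisher_or([[0, 0], [10, 10]])
        assert np.isnan(odds)

    def test_agrees_with_logistic_coefficient(self):
        design, y = _from_2x2(40, 10, 20, 30)
        fit = fit_logistic_mle(design, y)
        odds, _ = fisher_or([[40, 10], [20, 30]])
        assert odds == pytest.approx(np.exp(fit.params["x"]), abs=1e-6)


class TestDoseLimits:
    def _patient(self, **doses):
        return PatientDose("p", {roi: uniform_curve(d, roi)
                                 for roi, d in doses.items()})

    def test_parotid_limit_one_or_both(self):
        hot = self._patient(left_parotid=26, right_parotid=10)
        assert dose_limit_flags(hot)["parotid"] is True
        cool = self._patient(left_parotid=21, right_parotid=19)
        assert dose_limit_flags(cool)["parotid"] is False
        both = self._patient(left_parotid=21, right_parotid=22)
        assert dose_limit_flags(both)["parotid"] is True

    def test_zero_dose_everywhere_all_false(self):
        p = self._patient(
            spinal_cord=0, left_parotid=0, right_parotid=0, ipc=0, mpc=0,
            spc=0, mandible=0, larynx=0, brachial_plexus=0, esophagus=0)
        flags = dose_limit_flags(p)
        assert all(v is False for v in flags.values())

    def test_uniform_larynx_over_v50_limit(self):
        p = self._patient(larynx=55)
        assert dose_limit_flags(p)["larynx"] is True   # V50 = 100% > 27

    def test_esophagus_composite(self):
        assert dose_limit_flags(self._patient(esophagus=55))["esophagus"] is True
        assert dose_limit_flags(self._patient(esophagus=20))["esophagus"] is False

    def test_missing_roi_undefined(self):
        flags = dose_limit_flags(self._patient(larynx=30))
        assert flags["spinal_cord"] is None
        assert flags["parotid"] is None


class TestCovariateTable:
    def _clinical(self):
        return pd.DataFrame({
            "t_stage": ["T1", "T3", "T4"],
            "n_stage": ["N0", "N2", "N1"],
            "hpv": ["positive", "negative", "unknown"],
            "subsite": ["BOT", "tonsil", "other"],
            "age": [50, 70, 64],
            "ecog": ["0", "2", "unknown"],
        }, index=["p0", "p1", "p2"])

    def test_indicator_encoding(self):
        cov = build_covariate_table(self._clinical())
        ind = cov.indicators
        assert ind["t34"].tolist() == [0, 1, 1]
        assert ind["n2plus"].tolist() == [0, 1, 0]
        assert ind["hpv_pos"].tolist() == [1, 0, 0]
        assert ind["subsite_bot"].tolist() == [1, 0, 0]
        assert ind["subsite_tonsil"].tolist() == [0, 1, 0]
        assert ind["age_ge65"].tolist() == [0, 1, 0]
        # unknown ECOG is reference level; ecog_1/2 mutually exclusive
        assert ind["ecog_1"].tolist() == [0, 0, 0]
        assert ind["ecog_2"].tolist() == [0, 1, 0]

    def test_parotid_limit_matches_dose_limit_flags(self):
        cohort = [
            PatientDose("p0", {"left_parotid": uniform_curve(26, "left_parotid"),
                               "right_parotid": uniform_curve(10, "right_parotid")}),
            PatientDose("p1", {"left_parotid": uniform_curve(15, "left_parotid"),
                               "right_parotid": uniform_curve(12, "right_parotid")}),
            PatientDose("p2", {"left_parotid": uniform_curve(21, "left_parotid"),
                               "right_parotid": uniform_curve(22, "right_parotid")}),
        ]
        cov = build_covariate_table(self._clinical(), cohort)
        for p in cohort:
            expect = dose_limit_flags(p)["parotid"]
            assert cov.indicators.loc[p.patient_id, "parotid_limit"] == int(expect)
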