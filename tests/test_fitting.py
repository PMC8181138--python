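"""Covariate screening, AFT maximum likelihood, and AIC selection."""

import math

import numpy as np
import pandas as pd
import pytest

import ribrisk as rr
from ribrisk.fitting import _neg_loglik  # grid-search oracle reuses the likelihood


def _truth():
    return rr.reference_parameters("lognormal")


class TestScreenCovariates:
    def test_age_power_and_sex_type1_rates(self):
        """With a real age effect and no sex effect (n=200), the screen
        detects age essentially always and rejects sex at ~ the nominal 5%."""
        n_rep = 500
        age_hits = sex_hits = 0
        cfg = rr.CouponGeneratorConfig(n=200, truth=_truth())
        for rep in range(n_rep):
            df = rr.simulate_coupons(rr.CouponGeneratorConfig(
                n=200, truth=_truth(), seed=10_000 + rep))
            table = rr.screen_covariates(df).set_index("term")
            age_hits += table.loc["age", "p"] < 0.05
            sex_hits += table.loc["sex", "p"] < 0.05
        assert age_hits / n_rep >= 0.99
        assert 0.03 <= sex_hits / n_rep <= 0.08

    def test_zero_variance_age_not_estimable(self):
        df = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=0))
        df["age"] = 50.0
        table = rr.screen_covariates(df).set_index("term")
        assert not np.isfinite(table.loc["age", "F"])
        assert not table.loc["age", "significant"]

    def test_single_sex_omits_sex_terms(self, caplog):
        df = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=0))
        df["sex"] = "F"
        with caplog.at_level("WARNING"):
            table = rr.screen_covariates(df)
        assert set(table["term"]) == {"age"}
        assert any("sex" in r.message for r in caplog.records)

    def test_constant_response_errors(self):
        df = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=0))
        df["failure_strain"] = 0.02
        with pytest.raises(ValueError, match="degenerate"):
            rr.screen_covariates(df)

    def test_recommended_covariates_picks_significant_main_effects(self, coupons58):
        table = rr.screen_covariates(coupons58)
        recs = rr.recommended_covariates(table)
        assert "age" in recs  # the generator has a true age effect


class TestFitAFT:
    def test_two_point_lognormal_closed_form(self):
        """Two strains s*e^{-d}, s*e^{d} with no covariates: the normal MLE
        on logs gives beta0 = ln s, sigma = d exactly."""
        s, d = 0.02, 0.3
        df = pd.DataFrame({
            "subject_id": ["a", "b"],
            "age": [50.0, 50.0],
            "sex": ["F", "M"],
            "failure_strain": [s * math.exp(-d), s * math.exp(d)],
        })
        fit = rr.fit_aft(df, "lognormal", covariates=())
        assert fit.coef["intercept"] == pytest.approx(math.log(s), abs=1e-7)
        assert fit.sigma == pytest.approx(d, abs=1e-6)

    def test_exact_lognormal_equals_closed_form_regression(self, coupons58):
        """For exact data the log-normal MLE is weighted least squares of
        ln(strain) on age with sigma^2 = RSS/n (denominator n)."""
        fit = rr.fit_aft(coupons58, "lognormal", ("age",))
        X = np.column_stack([np.ones(len(coupons58)), coupons58["age"]])
        y = np.log(coupons58["failure_strain"].to_numpy())
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma = math.sqrt(np.mean((y - X @ beta) ** 2))
        assert fit.coef["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coef["age"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.sigma == pytest.approx(sigma, abs=1e-8)

    def test_mle_within_wald_intervals_and_grid_search_oracle(self, coupons58, fit58):
        """The fitted (beta0, beta1, ln sigma) lie inside their own 95% Wald
        intervals around the generating truth, and a coarse grid search of
        the likelihood confirms the optimizer's solution."""
        truth = _truth()
        se = np.sqrt(np.diag(fit58.covariance))
        theta_hat = np.array([fit58.coef["intercept"], fit58.coef["age"],
                              math.log(fit58.sigma)])
        theta_true = np.array([truth.beta0, truth.beta1, math.log(truth.sigma)])
        assert np.all(np.abs(theta_hat - theta_true) < 1.96 * se)

        # coarse grid around the MLE: no grid point beats the optimum
        X = np.column_stack([np.ones(len(coupons58)), coupons58["age"]])
        logt = np.log(coupons58["failure_strain"].to_numpy())
        from scipy.stats import norm as norm_dist
        args = (X, logt, np.full(len(logt), np.nan),
                np.zeros(len(logt), dtype=int), norm_dist)
        best = _neg_loglik(theta_hat, *args)
        for db0 in np.linspace(-3, 3, 7) * se[0]:
            for db1 in np.linspace(-3, 3, 7) * se[1]:
                for dls in np.linspace(-3, 3, 7) * se[2]:
                    cand = theta_hat + np.array([db0, db1, dls])
                    assert _neg_loglik(cand, *args) >= best - 1e-9

    @pytest.mark.parametrize("family", [f.value for f in rr.Family])
    def test_cross_check_against_lifelines(self, coupons58, family):
        """Dual-route check: our MLE against the independent lifelines AFT
        fitters (log-likelihood includes the same Jacobian convention)."""
        lifelines = pytest.importorskip("lifelines")
        cls = {
            "lognormal": lifelines.LogNormalAFTFitter,
            "weibull": lifelines.WeibullAFTFitter,
            "loglogistic": lifelines.LogLogisticAFTFitter,
        }[family]
        ldf = pd.DataFrame({"T": coupons58["failure_strain"], "E": 1,
                            "age": coupons58["age"]})
        theirs = cls().fit(ldf, duration_col="T", event_col="E")
        mine = rr.fit_aft(coupons58, family, ("age",))
        assert mine.loglik == pytest.approx(theirs.log_likelihood_, abs=1e-4)
        assert mine.aic == pytest.approx(theirs.AIC_, abs=1e-3)

    def test_right_censored_fit_cross_check(self):
        """Right-censored likelihood terms agree with lifelines."""
        lifelines = pytest.importorskip("lifelines")
        df = rr.simulate_coupons(rr.CouponGeneratorConfig(
            seed=5, right_censor_at=0.022))
        assert (df["censor"] == "right").sum() > 5
        mine = rr.fit_aft(df, "lognormal", ("age",))
        ldf = pd.DataFrame({"T": df["failure_strain"],
                            "E": (df["censor"] == "exact").astype(int),
                            "age": df["age"]})
        theirs = lifelines.LogNormalAFTFitter().fit(ldf, duration_col="T", event_col="E")
        assert mine.loglik == pytest.approx(theirs.log_likelihood_, abs=1e-4)

    def test_censoring_shifts_estimate(self):
        exact = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=5))
        censored = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=5, right_censor_at=0.022))
        f_exact = rr.fit_aft(exact, "lognormal", ("age",))
        f_cens = rr.fit_aft(censored, "lognormal", ("age",))
        # same data before censoring: estimates close but not identical
        assert f_cens.coef["intercept"] != f_exact.coef["intercept"]
        assert abs(f_cens.coef["age"] - f_exact.coef["age"]) < 0.01

    def test_aic_definition_and_covariance_psd(self, fit58):
        assert fit58.aic == pytest.approx(2 * fit58.k - 2 * fit58.loglik, abs=1e-10)
        eig = np.linalg.eigvalsh(fit58.covariance)
        assert np.all(eig > -1e-12)

    def test_degenerate_scale_errors(self):
        df = pd.DataFrame({
            "subject_id": list("abcd"),
            "age": [30.0, 40.0, 50.0, 60.0],
            "sex": ["F"] * 4,
            "failure_strain": [0.02] * 4,
        })
        with pytest.raises(ValueError):
            rr.fit_aft(df, "lognormal", covariates=())

    def test_too_few_observations(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "age": [30.0, 60.0],
                           "sex": ["F", "M"], "failure_strain": [0.02, 0.03]})
        with pytest.raises(ValueError, match="observations"):
            rr.fit_aft(df, "lognormal", ("age",))

    def test_params_property_requires_age_only(self, coupons58):
        fit = rr.fit_aft(coupons58, "lognormal", ("age", "sex"))
        with pytest.raises(ValueError, match="covariates"):
            _ = fit.params
        p = rr.fit_aft(coupons58, "lognormal", ("age",)).params
        assert p.family is rr.Family.LOGNORMAL and p.alpha > 0


class TestAICSelection:
    def test_reference_deltas(self):
        ranking = rr.aic_deltas({
            "lognormal": -399.30, "weibull": -389.50, "loglogistic": -397.09,
        })
        assert ranking.recommended is rr.Family.LOGNORMAL
        assert ranking.delta("weibull") == pytest.approx(9.80, abs=1e-10)
        assert ranking.delta("loglogistic") == pytest.approx(2.21, abs=1e-10)
        assert ranking.delta("lognormal") == 0.0

    def test_single_fit_trivial(self, fit58):
        ranking = rr.compare_aic([fit58])
        assert ranking.recommended is fit58.family
        assert ranking.delta(fit58.family) == 0.0

    def test_tie_break_family_order(self):
        ranking = rr.aic_deltas({"weibull": -100.0, "lognormal": -100.0})
        assert ranking.recommended is rr.Family.LOGNORMAL
        ranking2 = rr.aic_deltas({"weibull": -100.0, "loglogistic": -100.0})
        assert ranking2.recommended is rr.Family.LOGLOGISTIC

    def test_mixed_datasets_rejected(self, coupons58, fit58):
        other = rr.simulate_coupons(rr.CouponGeneratorConfig(seed=99))
        fit_other = rr.fit_aft(other, "weibull", ("age",))
        with pytest.raises(ValueError, match="identical data"):
            rr.compare_aic([fit58, fit_other])

    def test_aic_deltas_invariant_to_strain_rescaling(self, coupons58):
        """A unit change multiplies every strain by a constant; the log shift
        is absorbed into beta0 and AIC differences are unchanged."""
        fits = rr.fit_all_families(coupons58)
        ranking = rr.compare_aic(fits.values())
        scaled = coupons58.copy()
        scaled["failure_strain"] = scaled["failure_strain"] * 3.7
        fits_s = rr.fit_all_families(scaled)
        ranking_s = rr.compare_aic(fits_s.values())
        assert ranking_s.recommended is ranking.recommended
        for fam in rr.Family:
            assert ranking_s.delta(fam) == pytest.approx(ranking.delta(fam), abs=5e-3)
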