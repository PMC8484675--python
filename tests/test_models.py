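"""GLM, gamma hurdle, LRT, Tukey-type contrasts, BIC selection, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from qmiseq import (
    bic_select,
    build_design,
    echo_covariate,
    expected_response,
    fit_factor_glm,
    fit_gamma_hurdle,
    fit_glm,
    log_distance,
    lr_test_factor,
    pairwise_contrasts,
    predict_response,
)
from qmiseq.models import _gamma_loglik

STATION_DISTANCES = np.array([0.0, 150.0, 220.0, 500.0, 750.0])


def simulate_gamma(rng, n=500, coefs=(5.42, -0.30, -1.25), shape=2.0):
    d = rng.choice(STATION_DISTANCES, n)
    dep = np.where(rng.random(n) < 0.5, "middle", "bottom")
    cov = log_distance(d)
    mu = np.exp(coefs[0] + coefs[1] * cov + coefs[2] * (dep == "middle"))
    y = rng.gamma(shape, mu / shape)
    return y, cov, dep


class TestGammaGlm:
    def test_intercept_only_closed_form(self, rng):
        y = rng.gamma(2.0, 3.0, 200)
        fit = fit_glm(y, pd.DataFrame({"const": np.ones(200)}), "gamma_log")
        assert fit.params["const"] == pytest.approx(np.log(y.mean()), rel=1e-6)

    def test_zero_in_response_directs_to_hurdle(self):
        y = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="hurdle"):
            fit_glm(y, pd.DataFrame({"const": np.ones(3)}), "gamma_log")

    def test_mle_matches_generic_optimizer(self, rng):
        """Oracle: direct numerical maximisation of the gamma log-likelihood."""
        y, cov, dep = simulate_gamma(rng, n=80)
        X = build_design(cov, dep, ("cov", "depth"))
        fit = fit_glm(y, X, "gamma_log")
        Xm = X.to_numpy()

        def neg(theta):
            beta, log_a = theta[:-1], theta[-1]
            mu = np.exp(Xm @ beta)
            return -_gamma_loglik(y, mu, np.exp(log_a))

        x0 = np.concatenate([fit.params.to_numpy() * 0.7, [0.0]])
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20000})
        assert -res.fun <= fit.llf + 1e-4
        assert np.allclose(res.x[:-1], fit.params.to_numpy(), atol=2e-3)

    def test_bic_identity(self, rng):
        y, cov, dep = simulate_gamma(rng, n=120)
        fit = fit_glm(y, build_design(cov, dep, ("cov", "depth")), "gamma_log")
        assert fit.bic == pytest.approx(fit.k * np.log(fit.n) - 2 * fit.llf)
        assert fit.k == 4  # 3 coefficients + shape


class TestPoissonGlm:
    def test_intercept_only_is_log_mean(self):
        y = np.array([2, 4, 6])
        fit = fit_glm(y, pd.DataFrame({"const": np.ones(3)}), "poisson_log")
        assert fit.params["const"] == pytest.approx(np.log(4.0), rel=1e-6)
        assert fit.k == 1

    def test_rejects_non_integer_response(self):
        with pytest.raises(ValueError):
            fit_glm(np.array([1.5, 2.0]), pd.DataFrame({"const": np.ones(2)}),
                    "poisson_log")


class TestGammaHurdle:
    def test_no_zeros_reduces_to_gamma_glm(self, rng):
        y, cov, dep = simulate_gamma(rng, n=150)
        X = build_design(cov, dep, ("cov", "depth"))
        hurdle = fit_gamma_hurdle(y, X)
        plain = fit_glm(y, X, "gamma_log")
        assert hurdle.degenerate == "all_positive"
        pd.testing.assert_series_equal(hurdle.params, plain.params)

    def test_likelihood_decomposes_into_components(self, rng):
        y, cov, dep = simulate_gamma(rng, n=300)
        zero = rng.random(300) < 0.3
        y = np.where(zero, 0.0, y)
        X = build_design(cov, dep, ("cov", "depth"))
        fit = fit_gamma_hurdle(y, X)
        pos = y > 0
        gamma_part = fit_glm(y[pos], X.loc[pos].reset_index(drop=True), "gamma_log")
        import statsmodels.api as sm
        binom = sm.GLM(pos.astype(float), np.ones((300, 1)),
                       family=sm.families.Binomial()).fit()
        assert fit.llf == pytest.approx(gamma_part.llf + binom.llf)
        assert fit.k == gamma_part.k + 1

    def test_distance_driven_zeros_give_negative_binomial_slope(self, rng):
        """Zeros only at the farthest stations force a negative presence slope."""
        d = np.repeat(STATION_DISTANCES, 60)
        cov = log_distance(d)
        dep = np.full(len(d), "bottom")
        mu = np.exp(3.0 - 0.2 * cov)
        y = rng.gamma(2.0, mu / 2.0)
        far = d >= 220.0
        y[far & (rng.random(len(d)) < 0.5)] = 0.0
        fit = fit_gamma_hurdle(y, build_design(cov, dep, ("cov",)),
                               build_design(cov, dep, ("cov",)))
        assert fit.binom_params["cov"] < 0

    def test_prediction_combines_presence_and_magnitude(self, rng):
        y, cov, dep = simulate_gamma(rng, n=300)
        y[rng.random(300) < 0.25] = 0.0
        fit = fit_gamma_hurdle(y, build_design(cov, dep, ("cov", "depth")))
        pred = predict_response(fit, log_distance(150.0), "bottom")
        mu_only = float(np.exp(fit.params["const"]
                               + fit.params["cov"] * log_distance(150.0)))
        p = 1 / (1 + np.exp(-fit.binom_params["const"]))
        assert pred == pytest.approx(p * mu_only)
        assert pred < mu_only


class TestLrTest:
    def test_single_level_factor_errors(self, rng):
        with pytest.raises(ValueError):
            lr_test_factor(rng.gamma(2, 1, 10), ["A"] * 10, "gamma_log")

    def test_statistic_nonnegative_and_monotone_llf(self, rng):
        y = rng.gamma(2.0, 5.0, 80)
        fac = np.repeat(list("ABCD"), 20)
        stat, df, p = lr_test_factor(y, fac, "gamma_log")
        assert stat >= 0 and df == 3 and 0 <= p <= 1

    def test_strong_shift_detected(self, rng):
        y = rng.gamma(2.0, 5.0, 80)
        fac = np.repeat(list("ABCD"), 20)
        y[fac == "A"] *= 10
        _, _, p = lr_test_factor(y, fac, "gamma_log")
        assert p < 1e-4


class TestContrasts:
    def test_two_levels_adjusted_equals_unadjusted(self, rng):
        y = rng.gamma(2.0, 5.0, 60)
        fac = np.repeat(["A", "B"], 30)
        fit = fit_factor_glm(y, fac, "gamma_log")
        ct = pairwise_contrasts(fit, seed=1)
        assert len(ct) == 1
        assert ct["p_adjusted"].iloc[0] == pytest.approx(
            ct["p_unadjusted"].iloc[0]
        )

    def test_elevated_level_dominates_significant_set(self, rng):
        y = rng.gamma(4.0, 2.0, 200)
        fac = np.repeat(list("ABCDE"), 40)
        y[fac == "C"] *= 6
        fit = fit_factor_glm(y, fac, "gamma_log")
        ct = pairwise_contrasts(fit, seed=2, n_mc=50_000)
        sig = ct[ct["p_adjusted"] < 0.05]
        assert len(sig) > 0
        assert (sig[["level_a", "level_b"]] == "C").any(axis=1).all()

    def test_holm_fallback_is_deterministic(self, rng):
        y = rng.gamma(2.0, 5.0, 120)
        fac = np.repeat(list("ABC"), 40)
        fit = fit_factor_glm(y, fac, "gamma_log")
        a = pairwise_contrasts(fit, adjust="holm")
        b = pairwise_contrasts(fit, adjust="holm")
        pd.testing.assert_frame_equal(a, b)

    def test_single_step_reproducible_under_seed(self, rng):
        y = rng.gamma(2.0, 5.0, 120)
        fac = np.repeat(list("ABC"), 40)
        fit = fit_factor_glm(y, fac, "gamma_log")
        a = pairwise_contrasts(fit, seed=7)
        b = pairwise_contrasts(fit, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestBicSelect:
    def test_candidate_table_has_five_rows(self, rng):
        y, cov, dep = simulate_gamma(rng, n=100)
        _, table = bic_select(y, cov, dep, "gamma")
        assert len(table) == 5
        assert set(table["terms"]) == {
            "1", "cov", "depth", "cov+depth", "cov+depth+cov:depth"
        }

    def test_pure_noise_prefers_small_models(self, rng):
        wins = 0
        for _ in range(30):
            n = 150
            d = rng.choice(STATION_DISTANCES, n)
            dep = np.where(rng.random(n) < 0.5, "middle", "bottom")
            y = rng.gamma(2.0, 2.5, n)
            best, _ = bic_select(y, log_distance(d), dep, "gamma")
            wins += best.spec.terms == ()
        assert wins >= 15  # intercept-only wins a plurality

    def test_auto_policy_switches_to_hurdle_on_zeros(self, rng):
        y, cov, dep = simulate_gamma(rng, n=200)
        best, _ = bic_select(y, cov, dep, "auto")
        assert best.spec.family == "gamma_log"
        y[:20] = 0.0
        best, _ = bic_select(y, cov, dep, "auto")
        assert best.spec.family == "gamma_hurdle"


class TestPrediction:
    def test_published_coefficients_at_reef_bottom(self):
        """exp(5.42 − 0.30·log(0.1)) ≈ 451 copies at the reef, bottom layer."""
        coefs = {"const": 5.42, "cov": -0.30, "depth_middle": -1.25}
        pred = expected_response(coefs, log_distance(0.0), "bottom")
        assert pred == pytest.approx(np.exp(5.42 - 0.30 * np.log(0.1)))
        assert pred == pytest.approx(451, rel=0.01)

    def test_zero_coefficients_predict_one(self):
        assert expected_response({}, 1.23, "middle") == pytest.approx(1.0)

    def test_covariate_helpers(self):
        assert log_distance(0.0) == pytest.approx(np.log(0.1))
        assert echo_covariate(1e-7) == pytest.approx(-7.0)
        with pytest.raises(ValueError):
            log_distance([-5.0])
        with pytest.raises(ValueError):
            echo_covariate([0.0])
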