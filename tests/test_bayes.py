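"""Closed-form conjugate posterior and predictive, checked against
independent samplers and textbook least squares."""

import numpy as np
import pytest
from scipy import stats

from imfaccred import (
    BayesianQuarterRegression,
    PriorSpec,
    build_design,
    ols_fit,
    posterior,
    predictive,
    predictive_draws,
    prior_density_curve,
    sample_posterior,
)
from imfaccred.bayes import quarter_design_row


def _design(resid, labels):
    return build_design(resid, labels)


class TestDesign:
    def test_one_observation_per_quarter(self):
        system = _design(np.zeros(4), [0, 1, 2, 3])
        assert system.X.shape == (4, 4)
        np.testing.assert_array_equal(system.X[:, 0], 1.0)
        np.testing.assert_array_equal(system.X[1:, 1:], np.eye(3))

    def test_all_in_first_quarter_is_rank_deficient(self):
        with pytest.raises(ValueError, match="rank"):
            _design(np.zeros(10), np.zeros(10, dtype=int))

    def test_crossproduct_matches_counting_oracle(self, balanced_residuals):
        resid, labels = balanced_residuals
        system = _design(resid, labels)
        XtX = system.X.T @ system.X
        counts = np.bincount(labels)
        assert XtX[0, 0] == len(resid)
        for j in range(1, 4):
            assert XtX[j, j] == counts[j] == XtX[0, j]


class TestOLS:
    def test_zero_response(self):
        system = _design(np.zeros(8), np.tile(np.arange(4), 2))
        beta, s2 = ols_fit(system)
        np.testing.assert_allclose(beta, 0.0, atol=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-20)

    def test_response_equal_to_intercept_column(self):
        system = _design(np.ones(8), np.tile(np.arange(4), 2))
        beta, s2 = ols_fit(system)
        np.testing.assert_allclose(beta, [1, 0, 0, 0], atol=1e-12)
        assert s2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self, balanced_residuals):
        resid, labels = balanced_residuals
        system = _design(resid, labels)
        beta, s2 = ols_fit(system)
        # independent oracle: lstsq on the same design
        expected, *_ = np.linalg.lstsq(system.X, resid, rcond=None)
        np.testing.assert_allclose(beta, expected, rtol=1e-10)
        assert s2 == pytest.approx(float(np.sum((resid - system.X @ expected) ** 2)))


class TestPosterior:
    def test_prior_at_ols_leaves_mean_unchanged(self, small_fixture):
        resid, labels = small_fixture
        system = _design(resid, labels)
        beta_hat, _ = ols_fit(system)
        post = posterior(system, PriorSpec(g=2.0, alpha=5, delta=5, prior_mean=beta_hat))
        np.testing.assert_allclose(post.mu_hat, beta_hat, rtol=1e-10)

    def test_unit_g_zero_prior_halves_coefficients(self, small_fixture):
        resid, labels = small_fixture
        system = _design(resid, labels)
        beta_hat, _ = ols_fit(system)
        post = posterior(system, PriorSpec(g=1.0, alpha=5, delta=5))
        np.testing.assert_allclose(post.mu_hat, beta_hat / 2, rtol=1e-10)

    def test_degrees_of_freedom(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=7.5, delta=7.5))
        assert post.df == len(resid) + 2 * 7.5

    def test_scale_matrix_symmetric_positive_definite(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        np.testing.assert_allclose(post.Sigma_hat, post.Sigma_hat.T)
        assert np.all(np.linalg.eigvalsh(post.Sigma_hat) > 0)

    def test_matches_gibbs_sampler_oracle(self, small_fixture):
        """Closed-form marginals agree with a brute-force Gibbs sampler
        alternating beta | sigma^2 and sigma^2 | beta."""
        resid, labels = small_fixture
        system = _design(resid, labels)
        prior = PriorSpec(g=1.0, alpha=10.0, delta=10.0)
        post = posterior(system, prior)

        X, y = system.X, system.y
        n, p = X.shape
        XtX = X.T @ X
        M = prior.g * XtX
        P = M + XtX
        P_inv = np.linalg.inv(P)
        L = np.linalg.cholesky(P_inv)
        beta_hat, _ = ols_fit(system)
        cond_mean = P_inv @ (XtX @ beta_hat)  # prior mean zero

        rng = np.random.default_rng(7)
        sigma2 = 1.0
        n_iter, burn = 24_000, 2_000
        betas = np.empty((n_iter, p))
        sigmas = np.empty(n_iter)
        for it in range(n_iter):
            beta = cond_mean + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
            rss = float(np.sum((y - X @ beta) ** 2))
            penalty = float(beta @ (M @ beta))
            shape = prior.alpha + (n + p) / 2.0
            scale = prior.delta + 0.5 * (rss + penalty)
            sigma2 = stats.invgamma.rvs(shape, scale=scale, random_state=rng)
            betas[it] = beta
            sigmas[it] = sigma2
        betas, sigmas = betas[burn:], sigmas[burn:]

        # marginal of each coefficient: t(df, mu_hat_j, sqrt(Sigma_hat_jj))
        for j in range(p):
            d, _ = stats.kstest(
                betas[:, j],
                lambda x, j=j: stats.t.cdf(
                    x, post.df, loc=post.mu_hat[j],
                    scale=np.sqrt(post.Sigma_hat[j, j])),
            )
            assert d < 0.03, f"coefficient {j}: KS distance {d:.4f}"
        d, _ = stats.kstest(
            sigmas, lambda x: stats.invgamma.cdf(x, post.ig_shape, scale=post.ig_scale)
        )
        assert d < 0.03, f"sigma^2 marginal: KS distance {d:.4f}"


class TestPredictive:
    def test_zero_coefficients_give_zero_mean(self):
        system = _design(np.zeros(8), np.tile(np.arange(4), 2))
        post = posterior(system, PriorSpec(g=1.0, alpha=2, delta=2))
        pred = predictive(post, np.eye(4) + np.eye(4, k=-4))
        np.testing.assert_allclose(pred.theta_hat, 0.0, atol=1e-12)

    def test_mean_is_shrunk_ols_prediction(self, balanced_residuals):
        resid, labels = balanced_residuals
        system = _design(resid, labels)
        beta_hat, _ = ols_fit(system)
        X_new = np.vstack([quarter_design_row(q) for q in range(4)])
        for g in (0.5, 1.0, 3.0):
            post = posterior(system, PriorSpec(g=g, alpha=25, delta=25))
            pred = predictive(post, X_new)
            np.testing.assert_allclose(pred.theta_hat, X_new @ beta_hat / (1 + g),
                                       rtol=1e-10)

    def test_shrinkage_monotone_in_g(self, balanced_residuals):
        resid, labels = balanced_residuals
        system = _design(resid, labels)
        X_new = quarter_design_row(2)
        norms = []
        for g in (0.5, 1, 2, 10, 100):
            post = posterior(system, PriorSpec(g=g, alpha=25, delta=25))
            norms.append(abs(predictive(post, X_new).theta_hat[0]))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2  # -> 0 as g grows

    def test_draw_moments_match_t_distribution(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        X_new = np.vstack([quarter_design_row(q) for q in range(4)])
        pred = predictive_draws(post, X_new, n_draws=200_000, seed=99)
        var_expected = np.diag(pred.tau_hat) * pred.df / (pred.df - 2)
        np.testing.assert_allclose(pred.draws.mean(axis=0), pred.theta_hat, atol=0.02)
        np.testing.assert_allclose(pred.draws.var(axis=0), var_expected, rtol=0.04)

    def test_matches_compositional_sampler_oracle(self, small_fixture):
        """Direct multivariate-t draws agree in distribution with the
        compositional route sigma^2 -> beta -> y_new."""
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        X_new = quarter_design_row(1)[None, :]
        direct = predictive_draws(post, X_new, n_draws=40_000, seed=5).draws[:, 0]

        rng = np.random.default_rng(6)
        beta, sigma2 = sample_posterior(post, 40_000, seed=rng)
        compositional = beta @ X_new[0] + rng.normal(0, np.sqrt(sigma2))
        d = stats.ks_2samp(direct, compositional).statistic
        assert d < 0.02

    def test_band_fraction_monotone_in_band(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        pred = predictive_draws(post, np.eye(4), n_draws=20_000, seed=3)
        f1 = pred.fraction_within(1.0)
        f2 = pred.fraction_within(2.0)
        assert np.all(f1 <= f2) and np.all(f2 <= 1.0)

    def test_reproducible_under_fixed_seed(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        a = predictive_draws(post, np.eye(4), n_draws=1000, seed=11).draws
        b = predictive_draws(post, np.eye(4), n_draws=1000, seed=11).draws
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch_rejected(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1.0, alpha=10, delta=10))
        with pytest.raises(ValueError, match="columns"):
            predictive(post, np.ones((1, 3)))


class TestFrequentistLimit:
    def test_flat_prior_recovers_least_squares(self, balanced_residuals):
        resid, labels = balanced_residuals
        system = _design(resid, labels)
        beta_hat, s2 = ols_fit(system)
        post = posterior(system, PriorSpec(g=1e-9, alpha=1e-9, delta=1e-9))
        np.testing.assert_allclose(post.mu_hat, beta_hat, rtol=1e-6)
        # predictive variance approaches the classical prediction variance
        X_new = quarter_design_row(0)[None, :]
        pred = predictive(post, X_new)
        n, p = system.X.shape
        classical = s2 / (n - p) * (1 + X_new @ np.linalg.inv(system.X.T @ system.X) @ X_new.T)
        ratio = (pred.tau_hat[0, 0] * pred.df / (pred.df - 2)) / classical[0, 0]
        assert 0.9 < ratio < 1.1


class TestPosteriorSampling:
    def test_concentrated_prior_pins_sigma_near_one(self):
        system = _design(np.random.default_rng(1).normal(0, 1, 40),
                         np.tile(np.arange(4), 10))
        post = posterior(system, PriorSpec(g=1.0, alpha=5000, delta=5000))
        _, sigma2 = sample_posterior(post, 5000, seed=2)
        assert abs(np.median(sigma2) - 1.0) < 0.05

    def test_credible_interval_coverage(self):
        """95% credible intervals for the intercept cover the true value
        about 95% of the time when data come from the model."""
        rng = np.random.default_rng(12)
        covered = 0
        reps = 200
        for _ in range(reps):
            resid = rng.normal(0.0, 1.0, 80)  # true beta = 0, sigma = 1
            labels = np.tile(np.arange(4), 20)
            post = posterior(_design(resid, labels), PriorSpec(g=0.5, alpha=4, delta=4))
            half = stats.t.ppf(0.975, post.df) * np.sqrt(post.Sigma_hat[0, 0])
            covered += abs(post.mu_hat[0]) <= half
        assert covered / reps > 0.90

    def test_fixed_seed_reproducible(self, small_fixture):
        resid, labels = small_fixture
        post = posterior(_design(resid, labels), PriorSpec(g=1, alpha=10, delta=10))
        b1, s1 = sample_posterior(post, 500, seed=4)
        b2, s2 = sample_posterior(post, 500, seed=4)
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(s1, s2)


class TestPriorDensity:
    def test_normalised_and_centred(self):
        grid = np.linspace(1e-3, 60, 60_000)
        for a in (5, 25, 100):
            dens = prior_density_curve(a, a, grid)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)
            assert abs(grid[np.argmax(dens)] - 1.0) < 0.35  # mode near 1
            # median approaches 1 as the prior tightens
            assert abs(stats.invgamma.median(a, scale=a) - 1.0) < 0.35 / np.sqrt(a)

    def test_moderate_prior_mass_within_expected_window(self):
        lo, hi = stats.invgamma.ppf([0.025, 0.975], 25, scale=25)
        assert 0.5 < lo and hi < 1.75

    def test_tightens_with_alpha(self):
        spreads = [np.diff(stats.invgamma.ppf([0.025, 0.975], a, scale=a))[0]
                   for a in (5, 25, 100)]
        assert spreads[0] > spreads[1] > spreads[2]


class TestEstimatorSurface:
    def test_fit_exposes_posterior_attributes(self, balanced_residuals):
        resid, labels = balanced_residuals
        model = BayesianQuarterRegression(g=1.0, alpha=25, delta=25).fit(labels, resid)
        assert model.df_ == 150
        assert model.mu_hat_.shape == (4,)
        np.testing.assert_allclose(model.mu_hat_, model.beta_hat_ / 2, rtol=1e-10)

    def test_default_prior_is_quarter_of_sample_size(self, balanced_residuals):
        resid, labels = balanced_residuals
        model = BayesianQuarterRegression().fit(labels, resid)
        assert model.prior_.alpha == 25.0
        assert model.prior_.delta == 25.0

    def test_sklearn_params_round_trip(self):
        model = BayesianQuarterRegression(g=2.0, alpha=7)
        params = model.get_params()
        assert params["g"] == 2.0
        clone = BayesianQuarterRegression(**params)
        assert clone.get_params() == params

    def test_predict_returns_shrunk_quarter_means(self, balanced_residuals):
        resid, labels = balanced_residuals
        model = BayesianQuarterRegression(g=1.0, alpha=25).fit(labels, resid)
        pred = model.predict([0, 1, 2, 3])
        np.testing.assert_allclose(
            pred[0], model.beta_hat_[0] / 2, rtol=1e-10)

    def test_unfitted_access_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            BayesianQuarterRegression().predict([0])

    def test_credible_table_brackets_estimate(self, balanced_residuals):
        resid, labels = balanced_residuals
        table = BayesianQuarterRegression(alpha=25).fit(labels, resid).credible_table()
        assert (table["lci"] <= table["estimate"]).all()
        assert (table["estimate"] <= table["uci"]).all()
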