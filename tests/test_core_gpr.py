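"""Unit tests for the exact GP: kernel, likelihood, gradient, prediction."""

import numpy as np
import pytest

from phenofill import (
    Hyperparameters,
    TimeSeries,
    fit_gpr,
    log_marginal_likelihood,
    lml_gradient,
    predict,
    se_kernel,
    train_hyperparameters,
)
from phenofill.errors import InsufficientDataError, InvalidInputError
from phenofill.synthetic import generate_gp_series

from conftest import random_series, random_theta


def dense_posterior(t, y, t_star, theta):
    """Independent oracle: explicit inverse, no Cholesky."""
    K = theta.sigma_f2 * np.exp(-0.5 * ((t[:, None] - t[None, :]) / theta.lengthscale) ** 2)
    Kn_inv = np.linalg.inv(K + theta.sigma_n2 * np.eye(t.size))
    ks = theta.sigma_f2 * np.exp(-0.5 * ((t[:, None] - t_star[None, :]) / theta.lengthscale) ** 2)
    mean = ks.T @ Kn_inv @ y
    var = theta.sigma_f2 + theta.sigma_n2 - np.einsum("ij,ji->i", ks.T, Kn_inv @ ks)
    return mean, var


def dense_lml(t, y, theta):
    Kn = theta.sigma_f2 * np.exp(
        -0.5 * ((t[:, None] - t[None, :]) / theta.lengthscale) ** 2
    ) + theta.sigma_n2 * np.eye(t.size)
    sign, logdet = np.linalg.slogdet(Kn)
    assert sign > 0
    return (-0.5 * y @ np.linalg.inv(Kn) @ y - 0.5 * logdet
            - 0.5 * t.size * np.log(2 * np.pi))


class TestKernel:
    def test_closed_form_values(self):
        th = Hyperparameters.from_linear(1.0, 1.0, 1e-9)
        assert se_kernel([0.0], [0.0], th)[0, 0] == pytest.approx(1.0)
        assert se_kernel([0.0], [1.0], th)[0, 0] == pytest.approx(np.exp(-0.5))

    def test_noise_only_on_identical_grids(self, theta):
        t = np.array([0.0, 3.0, 9.0])
        k = se_kernel(t, t, theta, include_noise=True)
        assert np.allclose(np.diag(k), theta.sigma_f2 + theta.sigma_n2)
        with pytest.raises(InvalidInputError):
            se_kernel(t, t[:2], theta, include_noise=True)

    def test_training_cov_min_eigenvalue_at_least_noise(self, rng):
        for _ in range(10):
            th = random_theta(rng)
            t = np.sort(rng.uniform(0, 100, 6))
            k = se_kernel(t, t, th, include_noise=True)
            assert np.linalg.eigvalsh(k).min() >= th.sigma_n2 - 1e-10

    def test_rejects_non_finite(self, theta):
        with pytest.raises(InvalidInputError):
            se_kernel([0.0, np.nan], [1.0], theta)


class TestHyperparameters:
    def test_log_linear_round_trip(self):
        th = Hyperparameters.from_linear(38.2, 0.62, 0.17)
        th2 = Hyperparameters.from_linear(th.lengthscale, np.sqrt(th.sigma_f2),
                                          np.sqrt(th.sigma_n2))
        assert np.allclose(th.as_array(), th2.as_array(), rtol=0, atol=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            Hyperparameters(np.nan, 0.0, 0.0)


class TestLogMarginalLikelihood:
    def test_single_zero_observation_closed_form(self, theta):
        ts = TimeSeries([0.0], [0.0])
        expected = -0.5 * np.log(theta.sigma_f2 + theta.sigma_n2) - 0.5 * np.log(2 * np.pi)
        assert log_marginal_likelihood(ts, theta) == pytest.approx(expected, abs=1e-12)

    def test_two_point_dense_oracle(self):
        th = Hyperparameters.from_linear(1.0, 1.0, 0.1)
        t, y = np.array([0.0, 1.0]), np.array([1.0, -1.0])
        assert log_marginal_likelihood(TimeSeries(t, y), th) == pytest.approx(
            dense_lml(t, y, th), abs=1e-10)

    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_matches_dense_oracle(self, rng, n):
        ts = random_series(rng, n)
        th = random_theta(rng)
        t, y = ts.masked()
        assert log_marginal_likelihood(ts, th) == pytest.approx(
            dense_lml(t, y, th), rel=1e-9)


class TestGradient:
    @pytest.mark.parametrize("rep", range(5))
    def test_matches_central_finite_differences(self, rng, rep):
        ts = random_series(rng, rng.integers(5, 20))
        th = random_theta(rng)
        g = lml_gradient(ts, th)
        h = 1e-5
        x0 = th.as_array()
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            fd = (log_marginal_likelihood(ts, Hyperparameters.from_array(x0 + e))
                  - log_marginal_likelihood(ts, Hyperparameters.from_array(x0 - e))
                  ) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_zero_data_gradient_matches_fd(self, theta):
        # with y = 0 only the complexity term varies; sign convention check
        ts = TimeSeries(np.linspace(0, 100, 12), np.zeros(12))
        g = lml_gradient(ts, theta)
        h = 1e-5
        x0 = theta.as_array()
        e = np.array([0.0, h, 0.0])
        fd = (log_marginal_likelihood(ts, Hyperparameters.from_array(x0 + e))
              - log_marginal_likelihood(ts, Hyperparameters.from_array(x0 - e))
              ) / (2 * h)
        assert g[1] == pytest.approx(fd, rel=1e-4)
        assert g[1] < 0  # more signal variance only penalizes a zero series


class TestFitPredict:
    def test_single_point_alpha_closed_form(self, theta):
        fit = fit_gpr(TimeSeries([0.0], [2.0]), theta, min_obs=1)
        assert fit.alpha[0] == pytest.approx(2.0 / (theta.sigma_f2 + theta.sigma_n2))

    def test_fit_invariants_and_determinism(self, rng, theta):
        ts = random_series(rng, 30)
        fit = fit_gpr(ts, theta)
        Kn = se_kernel(fit.train_times, fit.train_times, theta, include_noise=True)
        assert np.allclose(fit.chol_factor @ fit.chol_factor.T, Kn, rtol=1e-10)
        assert np.allclose(Kn @ fit.alpha, fit.train_values, rtol=1e-8)
        fit2 = fit_gpr(ts, theta)
        assert np.array_equal(fit.alpha, fit2.alpha)
        assert np.array_equal(fit.chol_factor, fit2.chol_factor)

    def test_alpha_matches_dense_solve(self, rng, theta):
        ts = random_series(rng, 50)
        fit = fit_gpr(ts, theta)
        t, y = ts.masked()
        Kn = se_kernel(t, t, theta, include_noise=True)
        assert np.allclose(fit.alpha, np.linalg.solve(Kn, y), rtol=1e-8)

    def test_too_few_points_raises(self, theta):
        with pytest.raises(InsufficientDataError):
            fit_gpr(TimeSeries([0.0, 1.0], [1.0, 2.0]), theta)

    def test_noiseless_gp_interpolates(self):
        th = Hyperparameters.from_linear(10.0, 1.0, 1e-8)
        t = np.array([0.0, 10.0, 25.0, 40.0, 55.0])
        y = np.array([0.5, 1.5, -0.7, 0.1, 2.0])
        ps = predict(fit_gpr(TimeSeries(t, y), th), y, t)
        assert np.allclose(ps.mean, y, atol=1e-6)

    def test_prior_reversion_far_from_data(self, theta):
        t = np.linspace(0, 50, 8)
        y = np.sin(t / 10)
        ps = predict(fit_gpr(TimeSeries(t, y), theta), y, [1e5])
        assert ps.mean[0] == pytest.approx(0.0, abs=1e-6)
        assert ps.sd[0] ** 2 == pytest.approx(theta.sigma_f2 + theta.sigma_n2, abs=1e-6)

    def test_one_point_posterior_closed_form(self):
        th = Hyperparameters.from_linear(20.0, 1.0, 1e-9)
        fit = fit_gpr(TimeSeries([0.0], [2.0]), th, min_obs=1)
        t_star = np.array([0.0, 5.0, 30.0])
        ps = predict(fit, [2.0], t_star)
        assert np.allclose(ps.mean, 2.0 * np.exp(-t_star**2 / (2 * 20.0**2)), atol=1e-6)

    @pytest.mark.parametrize("rep", range(5))
    def test_posterior_matches_dense_oracle(self, rng, rep):
        ts = random_series(rng, int(rng.integers(5, 50)))
        th = random_theta(rng)
        t, y = ts.masked()
        t_star = np.linspace(t[0] - 30, t[-1] + 30, 40)
        ps = predict(fit_gpr(ts, th), y, t_star)
        mean_o, var_o = dense_posterior(t, y, t_star, th)
        assert np.allclose(ps.mean, mean_o, atol=1e-8)
        assert np.allclose(ps.sd**2, np.clip(var_o, 0, None), atol=1e-8)

    def test_mean_subtraction_reverts_to_sample_mean(self, theta):
        # with centering, far-field prediction reverts to the data mean
        t = np.linspace(0, 50, 8)
        y = 3.0 + np.sin(t / 10)
        fit = fit_gpr(TimeSeries(t, y), theta, subtract_mean=True)
        ps = predict(fit, y, [1e5])
        assert ps.mean[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_sd_bounded_by_prior(self, rng, theta):
        ts = random_series(rng, 30)
        ps = predict(fit_gpr(ts, theta), ts.masked()[1],
                     np.linspace(-100, 830, 120))
        assert np.all(ps.sd >= 0)
        assert np.all(ps.sd**2 <= theta.sigma_f2 + theta.sigma_n2 + 1e-12)


class TestTraining:
    def test_seeded_determinism(self, small_series):
        th1, lml1 = train_hyperparameters(small_series, seed=3)
        th2, lml2 = train_hyperparameters(small_series, seed=3)
        assert np.array_equal(th1.as_array(), th2.as_array())
        assert lml1 == lml2

    def test_gradient_small_at_optimum(self, theta):
        ts = generate_gp_series(theta, np.sort(
            np.random.default_rng(5).uniform(0, 1000, 120)), seed=5)
        th, _ = train_hyperparameters(ts, seed=1)
        g = lml_gradient(ts, th)
        assert np.linalg.norm(g) < 0.5  # L-BFGS pgtol-level stationarity

    def test_returned_lml_is_the_maximum_seen(self, small_series):
        th, lml = train_hyperparameters(small_series, n_restarts=4, seed=9)
        assert lml == pytest.approx(log_marginal_likelihood(small_series, th), rel=1e-8)

    def test_recovers_generating_hyperparameters(self, theta):
        """Short recovery check (3 replicates, n=200) of the simulation
        design; the full 20-replicate n=300 study runs in the acceptance
        suite."""
        devs = []
        for rep in range(3):
            t = np.sort(np.random.default_rng(100 + rep).uniform(0, 1460, 200))
            ts = generate_gp_series(theta, t, seed=200 + rep)
            th, _ = train_hyperparameters(ts, seed=rep)
            devs.append(th.as_array() - theta.as_array())
        assert np.all(np.abs(np.median(devs, axis=0)) < 0.45)

    def test_insufficient_data_raises(self, theta):
        with pytest.raises(InsufficientDataError):
            train_hyperparameters(TimeSeries([0.0, 1.0], [0.1, 0.2]))
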