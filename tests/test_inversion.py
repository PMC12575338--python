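"""Inversion: likelihoods (direct and EKF), the Laplace engine against
conjugate oracles, and parameter recovery."""

import math

import numpy as np
import pytest

from sysobs.generative import GenerativeParams, NoiseSpec, ObservedPair
from sysobs.inversion import (
    GaussianBelief,
    InversionSettings,
    default_prior,
    laplace_fit,
    loglik,
    predict,
    variational_laplace,
)
from sysobs.workflows import ExperimentConfig, generate_dataset

LOG2PI = math.log(2 * math.pi)


class TestPredict:
    def test_reduced_fixture_self_consistency(self, fast_config):
        # prediction at the generating values reproduces the noise-free output
        cfg = fast_config
        truth = cfg.scenario_params("identical_observers").replace(obs_noise_sd=0.0)
        driver, observed, _ = generate_dataset(
            ExperimentConfig(params=truth, seeds=(1,)), "identical_observers",
            "none", 1,
        )
        pred = predict(
            truth, {"delta_a": truth.delta_a, "delta_k": 0.0}, driver,
            NoiseSpec(mode="none"),
        )
        np.testing.assert_allclose(pred.h_mu, observed.h_mu, atol=1e-12)
        np.testing.assert_allclose(pred.h_M, observed.h_M, atol=1e-12)

    @pytest.mark.parametrize("free", [{"delta_a": 0.7}, {"delta_k": 0.7}])
    def test_macro_deviations_leave_micro_unchanged(self, scene_driver, free):
        # delta_a and delta_k enter only the macroscopic equations
        params = GenerativeParams()
        base = predict(params, {}, scene_driver, NoiseSpec(mode="none"))
        shifted = predict(params, free, scene_driver, NoiseSpec(mode="none"))
        np.testing.assert_array_equal(base.h_mu, shifted.h_mu)
        assert not np.array_equal(base.h_M, shifted.h_M)


class TestLoglik:
    def test_gaussian_density_at_mode(self, scene_driver):
        # zero residuals: loglik = (2T/2) ln(lambda / 2 pi)
        params = GenerativeParams(obs_noise_sd=0.0)
        pred = predict(params, {}, scene_driver, NoiseSpec(mode="none"))
        lam = 40.0
        ll = loglik({}, pred, params, scene_driver, NoiseSpec(mode="none"), lam)
        T = len(pred.times)
        assert ll == pytest.approx(T * math.log(lam / (2 * math.pi)), rel=1e-12)

    def test_ekf_degenerates_to_deterministic(self, scene_driver):
        params = GenerativeParams(sigma_mu=0.0, sigma_M=0.0, obs_noise_sd=0.05)
        _, observed, _ = generate_dataset(
            ExperimentConfig(params=params, seeds=(1,)), "identical_observers",
            "none", 1,
        )
        driver, observed, _ = generate_dataset(
            ExperimentConfig(params=params, seeds=(1,)), "identical_observers",
            "none", 1,
        )
        ll_none = loglik({}, observed, params, driver, NoiseSpec(mode="none"), 400.0)
        ll_ekf = loglik({}, observed, params, driver, NoiseSpec(mode="additive"), 400.0)
        assert ll_ekf == pytest.approx(ll_none, abs=1e-8)

    def test_nonpositive_precision_rejected(self, scene_driver):
        params = GenerativeParams()
        pred = predict(params, {}, scene_driver, NoiseSpec(mode="none"))
        with pytest.raises(ValueError, match="precision"):
            loglik({}, pred, params, scene_driver, NoiseSpec(mode="none"), 0.0)

    def test_ekf_matches_independent_kalman_filter(self, scene_driver):
        """In the near-linear regime (tiny states, gentle observer gain) the
        EKF must agree with a scalar Kalman filter written from scratch."""
        params = GenerativeParams(
            a=-1.0, b=0.001, c=1.0, k=0.1, sigma_mu=0.005, sigma_M=0.005,
        )
        noise = NoiseSpec(mode="additive", shared_increments=True, seed=21)
        cfg = ExperimentConfig(params=params, seeds=(21,))
        driver, observed, _ = generate_dataset(cfg, "identical_observers", "additive", 21)
        observed = ObservedPair(times=observed.times, h_mu=observed.h_mu,
                                h_M=observed.h_M, fs=observed.fs)
        lam = 400.0
        values = {"delta_a": 0.5, "delta_k": 0.0}
        ll = loglik(values, observed, params, driver, noise, lam)

        # ---- independent oracle: textbook 2-state Kalman filter -----------
        dt = 1.0 / observed.fs
        v = np.interp(observed.times, driver.times, driver.values)
        a1, a2 = params.a, params.a + values["delta_a"]
        gamma = params.c * params.k  # linearised observer gain (both channels)
        # same discretisation as the model: 2nd-order transition, Euler cov
        phi1 = 1 + a1 * dt + (a1 * dt) ** 2 / 2
        phi2 = 1 + a2 * dt + (a2 * dt) ** 2 / 2
        q = params.sigma_mu**2
        R = np.eye(2) / lam
        H = np.array([[gamma, 0.0], [0.0, gamma]])
        x = np.zeros(2)
        P = np.zeros((2, 2))
        Q = np.array([[q, q], [q, q]])  # shared Wiener path: rank one
        A = np.diag([a1, a2])
        ll_ref = 0.0
        for i in range(len(v)):
            if i > 0:
                u = 0.5 * params.b * dt * np.array(
                    [(1 + a1 * dt) * v[i - 1] + v[i],
                     (1 + a2 * dt) * v[i - 1] + v[i]]
                )
                x = np.array([phi1 * x[0], phi2 * x[1]]) + u
                P = P + dt * (A @ P + P @ A.T + Q)
            y = np.array([observed.h_mu[i], observed.h_M[i]])
            # oracle predicts through the true tanh observer; in this regime
            # the Jacobian is gamma to ~1e-6 relative
            yhat = params.c * np.tanh(params.k * x)
            S = H @ P @ H.T + R
            nu = y - yhat
            ll_ref -= 0.5 * (2 * LOG2PI + np.log(np.linalg.det(S))
                             + nu @ np.linalg.solve(S, nu))
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ nu
            P = (np.eye(2) - K @ H) @ P
        assert ll == pytest.approx(ll_ref, abs=1e-6)


class TestLaplaceFit:
    """Conjugate oracle: Bayesian linear regression y = theta u + eps."""

    @pytest.fixture()
    def linear_problem(self):
        rng = np.random.default_rng(7)
        n = 50
        u = rng.normal(size=n)
        sigma = 0.5
        theta_true = 0.8
        y = theta_true * u + rng.normal(0, sigma, size=n)
        lam = 1.0 / sigma**2

        def ll(vec):
            r = y - vec[0] * u
            return 0.5 * n * math.log(lam / (2 * math.pi)) - 0.5 * lam * np.sum(r**2)

        # closed-form posterior under prior N(0, 1)
        prec_post = 1.0 + lam * np.sum(u**2)
        mean_post = lam * np.sum(u * y) / prec_post
        # closed-form log evidence: y ~ N(0, sigma^2 I + u u')
        C = sigma**2 * np.eye(n) + np.outer(u, u)
        sign, logdet = np.linalg.slogdet(C)
        log_ev = -0.5 * (n * LOG2PI + logdet + y @ np.linalg.solve(C, y))
        return ll, mean_post, 1.0 / prec_post, log_ev

    def test_matches_closed_form_posterior_and_evidence(self, linear_problem):
        ll, mean_post, var_post, log_ev = linear_problem
        prior = GaussianBelief(names=("theta",), mean=[0.0], cov=[[1.0]])
        post = laplace_fit(ll, prior, InversionSettings())
        assert post.mean[0] == pytest.approx(mean_post, abs=1e-6)
        assert post.cov[0, 0] == pytest.approx(var_post, rel=1e-4)
        assert post.free_energy == pytest.approx(log_ev, abs=1e-4)

    def test_free_energy_monotone_over_accepted_steps(self, linear_problem):
        ll, *_ = linear_problem
        prior = GaussianBelief(names=("theta",), mean=[0.0], cov=[[1.0]])
        post = laplace_fit(ll, prior, InversionSettings())
        trace = post.info["f_trace"]
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_complexity_is_nonnegative(self, linear_problem):
        # KL[posterior || prior] >= 0, i.e. F <= accuracy
        ll, *_ = linear_problem
        prior = GaussianBelief(names=("theta",), mean=[0.0], cov=[[1.0]])
        post = laplace_fit(ll, prior, InversionSettings())
        m, S = post.mean, post.cov
        m0, S0 = prior.mean, prior.cov
        d = 1
        kl = 0.5 * (
            np.trace(np.linalg.solve(S0, S))
            + (m - m0) @ np.linalg.solve(S0, m - m0)
            - d
            + np.log(np.linalg.det(S0) / np.linalg.det(S))
        )
        assert kl >= 0.0


class TestVariationalLaplace:
    def test_truth_recovery_at_low_noise(self):
        params = GenerativeParams(obs_noise_sd=0.01)
        cfg = ExperimentConfig(params=params, effect_size=0.0, seeds=(2,))
        driver, observed, _ = generate_dataset(cfg, "identical_observers", "none", 2)
        post = variational_laplace(observed, params, driver, NoiseSpec(mode="none"))
        for label in ("delta_a", "delta_k"):
            i = post.index(label)
            assert abs(post.mean[i]) < 3 * post.marginal_sd(label)

    def test_label_permutation_consistency(self, fast_config):
        driver, observed, _ = generate_dataset(
            fast_config, "identical_observers", "none", 1
        )
        settings = InversionSettings(estimate_obs_precision=False)
        p1 = GaussianBelief(names=("delta_a", "delta_k"), mean=[0, 0], cov=np.eye(2))
        p2 = GaussianBelief(names=("delta_k", "delta_a"), mean=[0, 0], cov=np.eye(2))
        post1 = variational_laplace(
            observed, fast_config.params, driver, NoiseSpec(mode="none"), p1, settings
        )
        post2 = variational_laplace(
            observed, fast_config.params, driver, NoiseSpec(mode="none"), p2, settings
        )
        swapped = post2.reorder(("delta_a", "delta_k"))
        np.testing.assert_allclose(post1.mean, swapped.mean, atol=1e-5)
        np.testing.assert_allclose(post1.cov, swapped.cov, rtol=1e-3, atol=1e-8)
        assert post1.free_energy == pytest.approx(post2.free_energy, abs=1e-3)

    def test_credible_interval_coverage(self):
        """95% interval for the true delta_a covers it in >= 90/100 replicates."""
        cfg = ExperimentConfig(seeds=(1,))
        hits = 0
        for seed in range(100):
            driver, observed, truth = generate_dataset(
                cfg, "identical_observers", "none", seed
            )
            post = variational_laplace(
                observed, cfg.params, driver, NoiseSpec(mode="none")
            )
            lo, hi = post.credible_interval("delta_a", 0.95)
            hits += lo <= truth.delta_a <= hi
        assert hits >= 90
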