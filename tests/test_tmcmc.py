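"""TMCMC sampler: likelihood arithmetic, tempering schedule, proposal
covariance, resample-and-move kernel, evidence accuracy and posterior
summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from hemobayes.tmcmc import (
    GaussianLikelihood,
    PriorBox,
    TMCMCConfig,
    log_likelihood,
    next_exponent,
    posterior_summary,
    resample_and_move,
    run_tmcmc,
    stage_covariance,
)


class TestLogLikelihood:
    def test_normalizing_constant_cancels(self):
        # m = 1, perfect fit, sigma = 1/sqrt(2 pi) -> log p = 0
        assert log_likelihood([1.5], [1.5], 1 / math.sqrt(2 * math.pi)) == \
            pytest.approx(0.0, abs=1e-14)

    def test_one_sigma_residuals_closed_form(self):
        m, sigma = 7, 0.3
        d = np.full(m, sigma)
        expected = -0.5 * m * math.log(2 * math.pi * sigma**2) - m / 2
        assert log_likelihood(d, np.zeros(m), sigma) == pytest.approx(expected)

    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=5)
        g = rng.normal(size=5)
        sigma = 0.7
        oracle = stats.multivariate_normal(mean=g, cov=sigma**2 * np.eye(5))
        assert log_likelihood(d, g, sigma) == pytest.approx(
            oracle.logpdf(d), abs=1e-10)

    def test_nonpositive_sigma(self):
        assert log_likelihood([1.0], [0.0], 0.0) == -math.inf

    def test_forward_failure_rejected(self):
        def bad_forward(theta):
            raise RuntimeError("blow-up")
        lik = GaussianLikelihood(bad_forward, np.zeros(3))
        assert lik(np.array([1.0, 0.5])) == -math.inf
        assert lik.n_failures == 1


class TestNextExponent:
    def test_equal_logliks_jump_to_posterior(self):
        assert next_exponent(np.full(10, -3.2), 0.0) == 1.0

    def test_two_point_cov_is_capped(self):
        # CoV of two weights is (x-1)/(x+1) < 1 for any exponent, so
        # the target 1.0 is unattainable and the schedule jumps to 1
        assert next_exponent(np.array([0.0, 10.0]), 0.0, target=1.0) == 1.0

    def test_bisection_self_consistency(self):
        rng = np.random.default_rng(11)
        ll = rng.normal(0.0, 5.0, size=1000)
        q1 = next_exponent(ll, 0.0, target=1.0, tol=1e-12)
        assert 0 < q1 < 1
        w = np.exp((q1 - 0.0) * (ll - ll.max()))
        assert np.std(w) / np.mean(w) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_schedule_terminates_at_one(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(0.0, 40.0, size=500)
        q, qs = 0.0, []
        while q < 1.0:
            q = next_exponent(ll, q)
            qs.append(q)
        assert all(b > a for a, b in zip(qs, qs[1:]))
        assert qs[-1] == 1.0


class TestStageCovariance:
    def test_two_point_variance(self):
        samples = np.array([[-1.0], [1.0]])
        cov = stage_covariance(samples, np.array([0.5, 0.5]), b=1.0)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_scaling_factor_squared(self):
        samples = np.array([[-1.0], [1.0]])
        cov = stage_covariance(samples, np.array([0.5, 0.5]), b=0.2)
        assert cov[0, 0] == pytest.approx(0.04)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 3))
        w = rng.random(40)
        w /= w.sum()
        b = 0.2
        mu = sum(w[k] * x[k] for k in range(40))
        oracle = np.zeros((3, 3))
        for k in range(40):
            d = (x[k] - mu)[:, None]
            oracle += w[k] * (d @ d.T)
        oracle *= b * b
        assert np.allclose(stage_covariance(x, w, b), oracle, atol=1e-12)

    def test_degenerate_covariance_jittered(self):
        samples = np.ones((5, 2))
        with pytest.warns(UserWarning, match="jitter"):
            cov = stage_covariance(samples, np.full(5, 0.2), jitter=1e-10)
        assert np.all(np.diag(cov) > 0)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            stage_covariance(np.zeros((3, 1)), np.array([1.0, 1.0, 1.0]))


class TestResampleAndMove:
    def test_preserves_standard_normal_target(self):
        # stationarity: iterating the kernel at q = 1 keeps N(0,1)
        rng = np.random.default_rng(0)
        n = 5000
        samples = rng.standard_normal((n, 1))
        prior = PriorBox(("x",), (-50.0,), (50.0,))

        def ll(th):
            return float(-0.5 * th[0] ** 2)

        loglik = np.array([ll(s) for s in samples])
        wbar = np.full(n, 1.0 / n)
        cov = np.array([[0.04 * np.var(samples)]])
        for stage in range(1, 6):
            samples, loglik, acc = resample_and_move(
                samples, loglik, wbar, cov, 1.0, prior, ll,
                seed=1, stage=stage)
        assert samples.shape[0] == n
        assert samples.mean() == pytest.approx(0.0, abs=0.05)
        assert samples.var() == pytest.approx(1.0, abs=0.1)

    def test_output_population_size_conserved(self):
        rng = np.random.default_rng(1)
        samples = rng.standard_normal((200, 2))
        ll = rng.normal(size=200)
        w = np.exp(ll - ll.max())
        wbar = w / w.sum()
        prior = PriorBox(("x", "y"), (-9.0, -9.0), (9.0, 9.0))
        out, out_ll, acc = resample_and_move(
            samples, ll, wbar, 0.04 * np.cov(samples.T), 0.5, prior,
            lambda th: float(-0.5 * th @ th), seed=2, stage=1)
        assert out.shape == (200, 2)
        assert 0.0 <= acc <= 1.0

    def test_non_psd_covariance_rejected(self):
        samples = np.zeros((10, 2))
        prior = PriorBox(("x", "y"), (-1.0, -1.0), (1.0, 1.0))
        with pytest.raises(ValueError, match="positive semidefinite"):
            resample_and_move(samples, np.zeros(10), np.full(10, 0.1),
                              np.array([[1.0, 0.0], [0.0, -1.0]]),
                              1.0, prior, lambda th: 0.0, seed=0, stage=1)


class TestRunTMCMC:
    def test_constant_likelihood_recovers_prior(self):
        prior = PriorBox(("x",), (-10.0,), (10.0,))
        ens = run_tmcmc(prior, lambda th: 2.5,
                        TMCMCConfig(n_samples=2000, seed=0))
        assert ens.log_evidence == pytest.approx(2.5, abs=1e-12)
        ks = stats.kstest(ens.samples[:, 0], stats.uniform(-10, 20).cdf)
        assert ks.pvalue > 0.01

    def test_gaussian_evidence_1d(self):
        prior = PriorBox(("x",), (-10.0,), (10.0,))

        def ll(th):
            return float(-0.5 * th[0] ** 2 - 0.5 * math.log(2 * math.pi))

        errs = [run_tmcmc(prior, ll, TMCMCConfig(n_samples=2000, seed=s)
                          ).log_evidence + math.log(20) for s in (0, 1)]
        assert all(abs(e) < 0.1 for e in errs)

    def test_prior_containment_and_schedule(self):
        prior = PriorBox(("x",), (0.0,), (1.0,))

        def ll(th):
            return float(stats.norm(0.7, 0.01).logpdf(th[0]))

        ens = run_tmcmc(prior, ll, TMCMCConfig(n_samples=500, seed=4))
        assert np.all(ens.samples >= 0.0) and np.all(ens.samples <= 1.0)
        qs = [r.exponent for r in ens.stages]
        assert all(b > a for a, b in zip(qs, qs[1:]))
        assert qs[-1] == 1.0
        assert ens.log_evidence == pytest.approx(
            sum(r.log_mean_weight for r in ens.stages))

    def test_linear_gaussian_conjugate_posterior(self):
        # forward g(theta) = H theta with known sigma: posterior is
        # Gaussian with precision H^T H / sigma^2 (flat prior limit on
        # a wide box); TMCMC moments must match within MC error
        rng = np.random.default_rng(7)
        H = rng.normal(size=(6, 2))
        theta_true = np.array([0.4, -0.3])
        sigma = 0.1
        data = H @ theta_true + sigma * rng.standard_normal(6)
        prec = H.T @ H / sigma**2
        cov = np.linalg.inv(prec)
        mean = cov @ (H.T @ data) / sigma**2

        def ll(th):
            r = data - H @ th
            return float(-0.5 * r @ r / sigma**2)

        prior = PriorBox(("a", "b"), (-5.0, -5.0), (5.0, 5.0))
        ens = run_tmcmc(prior, ll, TMCMCConfig(n_samples=2000, seed=1))
        se = np.sqrt(np.diag(cov) / 2000)
        # 3x the iid standard error, inflated for chain autocorrelation
        assert np.all(np.abs(ens.samples.mean(axis=0) - mean) < 10 * se)
        assert np.allclose(np.cov(ens.samples.T), cov, rtol=0.35)

    def test_ensemble_save_artifacts(self, tmp_path):
        prior = PriorBox(("x",), (-2.0,), (2.0,))
        ens = run_tmcmc(prior, lambda th: float(-8.0 * th[0] ** 2),
                        TMCMCConfig(n_samples=200, seed=9))
        out = tmp_path / "run"
        ens.save(out)
        import json
        import pandas as pd
        samples = pd.read_csv(out / "samples.csv")
        assert list(samples.columns) == ["x", "log_likelihood"]
        assert len(samples) == 200
        stages = pd.read_csv(out / "stages.csv")
        assert stages["exponent"].iloc[-1] == 1.0
        summary = json.loads((out / "summary.json").read_text())
        assert summary["log_evidence"] == pytest.approx(ens.log_evidence)

    def test_serial_parallel_equivalence(self):
        prior = PriorBox(("x", "y"), (-5.0, -5.0), (5.0, 5.0))

        def ll(th):
            return float(-0.5 * th @ th)

        a = run_tmcmc(prior, ll, TMCMCConfig(n_samples=300, seed=6,
                                             n_workers=1))
        b = run_tmcmc(prior, ll, TMCMCConfig(n_samples=300, seed=6,
                                             n_workers=2))
        assert np.array_equal(a.samples, b.samples)
        assert a.log_evidence == b.log_evidence


class TestPosteriorSummary:
    def _ensemble(self, values):
        prior = PriorBox(("x",), (-100.0,), (100.0,))
        from hemobayes.tmcmc import PosteriorEnsemble
        x = np.asarray(values, dtype=float)[:, None]
        return PosteriorEnsemble(x, np.zeros(len(values)), [], 0.0, prior)

    def test_constant_samples(self):
        mean, sd, u = posterior_summary(self._ensemble([1.0, 1.0, 1.0]), "x")
        assert (mean, sd, u) == (1.0, 0.0, 0.0)

    def test_hand_computed_cov(self):
        mean, sd, u = posterior_summary(
            self._ensemble([0.9, 1.0, 1.1]), "x")
        assert u == pytest.approx(math.sqrt(0.02 / 3), rel=1e-12)

    def test_definition_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(2.0, 0.3, size=400)
        mean, sd, u = posterior_summary(self._ensemble(x), "x")
        assert u == pytest.approx(x.std() / x.mean(), abs=1e-12)

    def test_zero_mean_flagged(self):
        with pytest.warns(UserWarning, match="CoV undefined"):
            _, _, u = posterior_summary(self._ensemble([-1.0, 1.0]), "x")
        assert math.isnan(u)

    def test_unknown_parameter(self):
        with pytest.raises(KeyError):
            posterior_summary(self._ensemble([1.0, 2.0]), "nope")
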