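"""Transitional Markov chain Monte Carlo with evidence estimation.

TMCMC tempers from the prior to the posterior through the bridge
densities  f_j ~ [p(D|theta)]^{q_j} pi(theta),  0 = q_0 < ... < q_l = 1.
Each tempering exponent is chosen so the coefficient of variation of
the plausibility weights  w = likelihood^{q_{j+1}-q_j}  hits a target
(1.0 by default); samples are then multinomially resampled by
normalized weight and moved by per-particle Metropolis chains with a
Gaussian proposal whose covariance is the b^2-scaled weighted sample
covariance (b = 0.2 by default).  The log-evidence accumulates as the
sum over stages of the log mean plausibility weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.special import logsumexp

__all__ = [
    "PriorBox",
    "GaussianLikelihood",
    "TMCMCConfig",
    "StageRecord",
    "PosteriorEnsemble",
    "log_likelihood",
    "next_exponent",
    "stage_covariance",
    "resample_and_move",
    "run_tmcmc",
    "posterior_summary",
]


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform prior on an axis-aligned box."""

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self):
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names, lower, upper must have equal length")
        for n, lo, hi in zip(self.names, self.lower, self.upper):
            if not lo < hi:
                raise ValueError(f"prior for {n}: lower bound must be < upper bound")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", tuple(float(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(float(v) for v in self.upper))

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, theta) -> bool:
        theta = np.asarray(theta)
        return bool(
            np.all(theta >= np.asarray(self.lower))
            and np.all(theta <= np.asarray(self.upper))
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return lo + (hi - lo) * rng.random((n, self.dim))

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(np.asarray(self.upper) - np.asarray(self.lower))))


class GaussianLikelihood:
    """Gaussian-error likelihood p(D | theta) with covariance sigma^2 I.

    ``forward`` maps the model parameters (all components of theta
    except the designated noise component) to a predicted data vector
    the same length as ``data``; the noise level sigma is read from
    ``theta[sigma_index]``.  A forward failure is treated as log
    likelihood -inf, i.e. the sample is rejected.
    """

    def __init__(self, forward, data, sigma_index: int = -1,
                 forward_exceptions=(RuntimeError, ValueError)):
        self.forward = forward
        self.data = np.asarray(data, dtype=float).reshape(-1)
        self.sigma_index = sigma_index
        self.forward_exceptions = tuple(forward_exceptions)
        self.n_failures = 0

    @property
    def m(self) -> int:
        return self.data.size

    def __call__(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        sigma = theta[self.sigma_index]
        if sigma <= 0:
            return -math.inf
        idx = self.sigma_index % theta.size
        model_theta = np.delete(theta, idx)
        try:
            g = np.asarray(self.forward(model_theta), dtype=float).reshape(-1)
        except self.forward_exceptions:
            self.n_failures += 1
            return -math.inf
        if g.size != self.m:
            raise ValueError(
                f"forward map returned {g.size} values, data has {self.m}"
            )
        return log_likelihood(self.data, g, sigma)


def log_likelihood(data, prediction, sigma: float) -> float:
    """Log density of D under N(g, sigma^2 I):
    -(m/2) log(2 pi sigma^2) - ||D - g||^2 / (2 sigma^2)."""
    if sigma <= 0:
        return -math.inf
    r = np.asarray(data, dtype=float) - np.asarray(prediction, dtype=float)
    m = r.size
    J = float(r @ r) / sigma**2
    if not np.isfinite(J):
        return -math.inf
    return -0.5 * m * math.log(2.0 * math.pi * sigma**2) - 0.5 * J


@dataclass(frozen=True)
class TMCMCConfig:
    """Sampler settings; the population size stays constant across
    stages."""

    n_samples: int = 500
    cov_scale: float = 0.2  # the proposal scaling factor b
    cov_target: float = 1.0  # tolerance CoV of the plausibility weights
    exponent_tolerance: float = 1e-10
    max_stages: int = 60
    seed: int = 0
    n_workers: int = 1
    covariance_jitter: float = 1e-12

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.cov_scale <= 0 or self.cov_target <= 0:
            raise ValueError("cov_scale and cov_target must be > 0")


@dataclass
class StageRecord:
    stage: int
    exponent: float  # q_{j+1} targeted by this stage
    log_mean_weight: float  # log S_j
    acceptance_rate: float
    covariance: np.ndarray
    effective_sample_size: float


@dataclass
class PosteriorEnsemble:
    """Final TMCMC population plus per-stage diagnostics."""

    samples: np.ndarray  # (N, dim)
    log_likelihoods: np.ndarray  # (N,)
    stages: list[StageRecord]
    log_evidence: float
    prior: PriorBox

    def marginal(self, name: str) -> np.ndarray:
        try:
            i = self.prior.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.samples[:, i]

    def save(self, directory) -> None:
        """Write samples, per-stage diagnostics and a result summary
        (CSV + JSON) under ``directory``."""
        import json
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        df = pd.DataFrame(self.samples, columns=list(self.prior.names))
        df["log_likelihood"] = self.log_likelihoods
        df.to_csv(os.path.join(directory, "samples.csv"), index=False)
        pd.DataFrame([
            {"stage": r.stage, "exponent": r.exponent,
             "log_mean_weight": r.log_mean_weight,
             "acceptance_rate": r.acceptance_rate,
             "effective_sample_size": r.effective_sample_size}
            for r in self.stages
        ]).to_csv(os.path.join(directory, "stages.csv"), index=False)
        summary = {
            "log_evidence": self.log_evidence,
            "n_samples": int(self.samples.shape[0]),
            "n_stages": len(self.stages),
            "prior": {
                "names": list(self.prior.names),
                "lower": list(self.prior.lower),
                "upper": list(self.prior.upper),
            },
        }
        with open(os.path.join(directory, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)


# ---------------------------------------------------------------------------
# stage mechanics

def _weight_cov(loglik: np.ndarray, dq: float) -> float:
    """Population coefficient of variation of likelihood^dq weights."""
    s = dq * (loglik - loglik.max())
    w = np.exp(s)
    mean = w.mean()
    return float(w.std() / mean)


def next_exponent(loglik, q_j: float, target: float = 1.0,
                  tol: float = 1e-10) -> float:
    """Choose q_{j+1}: the exponent increment whose plausibility
    weights have coefficient of variation equal to ``target``,
    capped at 1 (bisection; weights handled in log space)."""
    loglik = np.asarray(loglik, dtype=float)
    finite = loglik[np.isfinite(loglik)]
    if finite.size == 0:
        raise ValueError("all log-likelihoods are -inf; no viable samples")
    if q_j >= 1.0:
        raise ValueError("tempering already complete")
    dq_max = 1.0 - q_j
    if np.ptp(finite) == 0 and finite.size == loglik.size:
        return 1.0
    if _weight_cov(loglik, dq_max) <= target:
        return 1.0
    lo, hi = 0.0, dq_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _weight_cov(loglik, mid) <= target:
            lo = mid
        else:
            hi = mid
    return q_j + 0.5 * (lo + hi)


def stage_covariance(samples, wbar, b: float = 0.2,
                     jitter: float = 1e-12) -> np.ndarray:
    """b^2-scaled weighted sample covariance used as the Metropolis
    proposal covariance."""
    samples = np.asarray(samples, dtype=float)
    wbar = np.asarray(wbar, dtype=float)
    if abs(wbar.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    mu = wbar @ samples
    d = samples - mu
    cov = b * b * (d.T * wbar) @ d
    cov = 0.5 * (cov + cov.T)
    if np.all(np.linalg.eigvalsh(cov) <= 0):
        warnings.warn("degenerate stage covariance; adding diagonal jitter")
        cov = cov + jitter * np.eye(cov.shape[0])
    return cov


def _run_chain(start, start_ll, n_steps, chol, q, prior, loglik_fn, rng):
    """One Metropolis chain targeting likelihood^q * prior; returns
    (samples, logliks, n_accepted)."""
    dim = start.size
    theta = start.copy()
    ll = start_ll
    out = np.empty((n_steps, dim))
    out_ll = np.empty(n_steps)
    accepted = 0
    for i in range(n_steps):
        prop = theta + chol @ rng.standard_normal(dim)
        if prior.contains(prop):
            prop_ll = loglik_fn(prop)
            log_ratio = q * (prop_ll - ll) if np.isfinite(prop_ll) else -math.inf
            if log_ratio >= 0 or rng.random() < math.exp(log_ratio):
                theta, ll = prop, prop_ll
                accepted += 1
        out[i] = theta
        out_ll[i] = ll
    return out, out_ll, accepted


def resample_and_move(samples, loglik, wbar, cov, q_next, prior, loglik_fn,
                      seed, stage: int, n_workers: int = 1):
    """Multinomial resampling followed by per-particle Metropolis moves.

    Each particle selected n_k times seeds an independent chain of
    length n_k targeting likelihood^q_next * prior; chain RNG streams
    are keyed by (seed, stage, chain) so results are identical for any
    worker count.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    cov = np.asarray(cov, dtype=float)
    eig_min = float(np.linalg.eigvalsh(cov).min())
    if eig_min < -1e-12 * max(1.0, float(np.trace(cov))):
        raise ValueError("stage covariance is not positive semidefinite")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # PSD but rank-deficient: regularize minimally
        bump = 1e-14 * max(float(np.trace(cov)) / cov.shape[0], 1e-300)
        chol = np.linalg.cholesky(cov + bump * np.eye(cov.shape[0]))
    stage_rng = np.random.default_rng([seed, stage, 0])
    counts = stage_rng.multinomial(n, wbar)
    chains = [(k, int(c)) for k, c in enumerate(counts) if c > 0]

    def work(chain_idx, k, c):
        rng = np.random.default_rng([seed, stage, 1 + chain_idx])
        return _run_chain(samples[k], loglik[k], c, chol, q_next, prior,
                          loglik_fn, rng)

    if n_workers > 1:
        results = Parallel(n_jobs=n_workers, prefer="threads")(
            delayed(work)(i, k, c) for i, (k, c) in enumerate(chains)
        )
    else:
        results = [work(i, k, c) for i, (k, c) in enumerate(chains)]

    new_samples = np.vstack([r[0] for r in results])
    new_ll = np.concatenate([r[1] for r in results])
    accepted = sum(r[2] for r in results)
    return new_samples, new_ll, accepted / n


# ---------------------------------------------------------------------------
# driver

def run_tmcmc(prior: PriorBox, loglik_fn, cfg: TMCMCConfig) -> PosteriorEnsemble:
    """Sample the posterior ~ likelihood * prior and estimate the
    evidence.

    Starts with ``cfg.n_samples`` prior draws; each stage selects the
    next tempering exponent, records log S_j, and regenerates the
    population by resampling and Metropolis moves.  Terminates after
    the stage that reaches q = 1.  Likelihood evaluations go through a
    parallel-map contract whose results are identical to serial
    execution for a fixed seed.
    """
    rng0 = np.random.default_rng([cfg.seed, 0, 0])
    samples = prior.sample(rng0, cfg.n_samples)

    if cfg.n_workers > 1:
        ll = np.array(Parallel(n_jobs=cfg.n_workers, prefer="threads")(
            delayed(loglik_fn)(s) for s in samples
        ))
    else:
        ll = np.array([loglik_fn(s) for s in samples])

    q = 0.0
    log_evidence = 0.0
    stages: list[StageRecord] = []
    for stage in range(1, cfg.max_stages + 1):
        q_next = next_exponent(ll, q, cfg.cov_target, cfg.exponent_tolerance)
        dq = q_next - q
        s = dq * ll
        log_S = float(logsumexp(s) - math.log(ll.size))
        log_w = s - logsumexp(s)
        wbar = np.exp(log_w)
        ess = float(1.0 / np.sum(wbar**2))
        cov = stage_covariance(samples, wbar, cfg.cov_scale, cfg.covariance_jitter)
        samples, ll, acc = resample_and_move(
            samples, ll, wbar, cov, q_next, prior, loglik_fn,
            cfg.seed, stage, cfg.n_workers)
        log_evidence += log_S
        stages.append(StageRecord(stage, q_next, log_S, acc, cov, ess))
        q = q_next
        if q >= 1.0:
            break
    else:
        raise RuntimeError(
            f"TMCMC did not reach q = 1 within {cfg.max_stages} stages "
            f"(final q = {q:.4f}); diagnostics: "
            + ", ".join(f"q{r.stage}={r.exponent:.3g}" for r in stages)
        )
    return PosteriorEnsemble(samples, ll, stages, log_evidence, prior)


def posterior_summary(ensemble: PosteriorEnsemble, name: str):
    """Marginal posterior mean, population SD and coefficient of
    variation u = SD/mean for one parameter."""
    x = ensemble.marginal(name)
    mean = float(x.mean())
    sd = float(x.std())
    if mean == 0.0:
        warnings.warn(f"posterior mean of {name} is zero; CoV undefined")
        return mean, sd, math.nan
    return mean, sd, sd / mean
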