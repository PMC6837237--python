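"""Evidence-based localization of arterial defects.

A candidate model M_i frees the scaled stiffness (or scaled area) of
artery i — plus the noise level sigma — and fixes every other artery
at its healthy reference value; M_{i:j} frees two arteries.  Each
model is fit to the observed velocity data by TMCMC, which also
returns its log-evidence; normalizing evidence x model-prior over the
candidate class gives the model-selection posterior Pr(M_i | D), a
probabilistic statement of where the defect is.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ArterialNetwork
from .observations import ObservationSet
from .solver import InflowWaveform, SolverConfig, SolverError, simulate
from .tmcmc import (
    GaussianLikelihood,
    PosteriorEnsemble,
    PriorBox,
    TMCMCConfig,
    posterior_summary,
    run_tmcmc,
)

__all__ = [
    "DefectModelSpec",
    "ModelSelectionResult",
    "make_forward",
    "model_posterior",
    "evaluate_model",
    "run_selection",
]


@dataclass(frozen=True)
class DefectModelSpec:
    """One candidate defect model.

    ``free_arteries`` lists the arteries whose scaled parameter
    (stiffness beta or relaxed area alpha, per ``parameter``) is free;
    the prior box covers those factors followed by the noise level
    sigma as its last component.
    """

    model_id: str
    free_arteries: tuple[int, ...]
    parameter: str  # "stiffness" or "area"
    prior: PriorBox

    def __post_init__(self):
        object.__setattr__(self, "free_arteries", tuple(self.free_arteries))
        if not 1 <= len(self.free_arteries) <= 2:
            raise ValueError("a defect model frees one or two arteries")
        if self.parameter not in ("stiffness", "area"):
            raise ValueError(f"unknown parameter kind {self.parameter!r}")
        if self.prior.dim != len(self.free_arteries) + 1:
            raise ValueError(
                "prior must cover the defect factors plus the noise level"
            )


def single_defect_model(artery_id: int, parameter: str = "stiffness",
                        factor_bounds=(0.0, 3.0),
                        sigma_bounds=(0.0, 1.0)) -> DefectModelSpec:
    """M_i: one free artery; uniform prior on (factor, sigma)."""
    sym = "beta" if parameter == "stiffness" else "alpha"
    lo = (max(factor_bounds[0], 1e-12), max(sigma_bounds[0], 0.0))
    return DefectModelSpec(
        f"M_{artery_id}", (artery_id,), parameter,
        PriorBox((f"{sym}_{artery_id}", "sigma"),
                 (factor_bounds[0], sigma_bounds[0]),
                 (factor_bounds[1], sigma_bounds[1])),
    )


def pair_defect_model(artery_a: int, artery_b: int,
                      parameter: str = "stiffness",
                      factor_bounds=(0.0, 3.0),
                      sigma_bounds=(0.0, 1.0)) -> DefectModelSpec:
    """M_{a:b}: two free arteries; uniform prior on (f_a, f_b, sigma)."""
    sym = "beta" if parameter == "stiffness" else "alpha"
    return DefectModelSpec(
        f"M_{artery_a}:{artery_b}", (artery_a, artery_b), parameter,
        PriorBox((f"{sym}_{artery_a}", f"{sym}_{artery_b}", "sigma"),
                 (factor_bounds[0], factor_bounds[0], sigma_bounds[0]),
                 (factor_bounds[1], factor_bounds[1], sigma_bounds[1])),
    )


# ---------------------------------------------------------------------------
# forward maps

def make_forward(net: ArterialNetwork, waveform: InflowWaveform,
                 cfg: SolverConfig, sensors, entries):
    """Build a forward map theta -> flattened sensor velocities.

    ``entries`` is a sequence of ("stiffness", artery_id),
    ("area", artery_id) or ("viscosity", None); each theta component
    is the multiplicative factor applied to the corresponding
    reference value (reference stiffness/area of the artery, or the
    network's reference viscosity).  Raises SolverError on forward
    failure, which the likelihood converts to -inf.
    """
    entries = tuple(entries)
    for kind, aid in entries:
        if kind not in ("stiffness", "area", "viscosity"):
            raise ValueError(f"unknown forward entry kind {kind!r}")
        if kind != "viscosity":
            net.artery(aid)  # raises for unknown ids

    def forward(theta):
        theta = np.asarray(theta, dtype=float)
        if theta.size != len(entries):
            raise ValueError("parameter vector does not match forward entries")
        trial = net
        updates = {}
        fluid = trial.fluid
        for (kind, aid), factor in zip(entries, theta):
            if factor <= 0:
                raise SolverError("non-positive scale factor")
            if kind == "viscosity":
                fluid = fluid.with_viscosity(factor * net.fluid.viscosity)
            else:
                g = updates.get(aid, trial.artery(aid))
                if kind == "stiffness":
                    g = replace(g, stiffness=factor * g.reference_stiffness)
                else:
                    g = replace(g, relaxed_area=factor * g.reference_area)
                updates[aid] = g
        if updates:
            trial = trial.with_arteries(updates)
        if fluid is not trial.fluid:
            trial = trial.with_fluid(fluid)
        return simulate(trial, waveform, cfg, sensors).flat()

    return forward


def _model_seed(master_seed: int, model_id: str) -> int:
    return (1000003 * master_seed + zlib.crc32(model_id.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# model posterior arithmetic

def model_posterior(log_evidences, prior=None) -> np.ndarray:
    """Pr(M_i | D) from per-model log-evidences and a model prior
    (uniform by default); computed with max-subtraction so arbitrary
    offsets in the log-evidences cancel."""
    le = np.asarray(log_evidences, dtype=float)
    if le.size == 0:
        raise ValueError("need at least one model")
    if prior is None:
        logp = np.zeros(le.size)
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.size != le.size or np.any(prior < 0):
            raise ValueError("model prior must be nonnegative, one value per model")
        if abs(prior.sum() - 1.0) > 1e-8:
            raise ValueError("model prior must sum to 1")
        with np.errstate(divide="ignore"):
            logp = np.log(prior)
    s = le + logp
    s = s - s.max()
    w = np.exp(s)
    return w / w.sum()


# ---------------------------------------------------------------------------
# per-model inference

def evaluate_model(
    model: DefectModelSpec,
    data: ObservationSet,
    net: ArterialNetwork,
    waveform: InflowWaveform,
    solver_cfg: SolverConfig,
    tmcmc_cfg: TMCMCConfig,
) -> tuple[float, PosteriorEnsemble]:
    """Fit one defect model to the data; returns (log-evidence,
    posterior ensemble).

    The forward map substitutes the free factors into the healthy
    reference network, simulates, and samples the data's sensors on
    the data's time grid.
    """
    n_samples = data.times.size
    cfg = replace(solver_cfg,
                  final_time=n_samples * data.sensors.sampling_period)
    entries = [(model.parameter, aid) for aid in model.free_arteries]
    forward = make_forward(net, waveform, cfg, data.sensors, entries)
    lik = GaussianLikelihood(forward, data.flat(),
                             forward_exceptions=(SolverError,))
    cfg_t = replace(tmcmc_cfg, seed=_model_seed(tmcmc_cfg.seed, model.model_id))
    ensemble = run_tmcmc(model.prior, lik, cfg_t)
    return ensemble.log_evidence, ensemble


@dataclass
class ModelSelectionResult:
    """Per-model evidences, posterior probabilities and parameter
    summaries over a candidate class."""

    records: list[dict]
    winning_model: str | None
    complete: bool = True
    failures: dict = field(default_factory=dict)

    @property
    def probabilities(self) -> dict[str, float]:
        return {r["model_id"]: r["probability"] for r in self.records}

    def record(self, model_id: str) -> dict:
        for r in self.records:
            if r["model_id"] == model_id:
                return r
        raise KeyError(model_id)

    def to_frame(self, render_small_as_tilde: bool = False) -> pd.DataFrame:
        rows = []
        for r in self.records:
            est = ", ".join(f"{m:.3f}" for m in r["estimates"])
            u = ", ".join(f"{100 * u:.2f}" for u in r["estimate_covs"])
            prob = r["probability"]
            rows.append({
                "model": r["model_id"],
                "estimate": est,
                "u_%": u,
                "sigma_hat": r["sigma_hat"],
                "u_sigma_%": 100 * r["sigma_cov"],
                "log_evidence": r["log_evidence"],
                "Pr(M|D)": "~0" if (render_small_as_tilde and prob < 1e-8)
                           else prob,
            })
        return pd.DataFrame(rows)


def run_selection(
    models,
    data: ObservationSet,
    net: ArterialNetwork,
    waveform: InflowWaveform,
    solver_cfg: SolverConfig,
    tmcmc_cfg: TMCMCConfig,
    model_prior=None,
    keep_ensembles: bool = False,
) -> ModelSelectionResult:
    """Evaluate a class of candidate defect models and assemble the
    model-selection posterior.

    Any model whose evaluation fails is reported in ``failures`` and
    the result is marked incomplete; probabilities are normalized over
    the models that completed.
    """
    models = list(models)
    if len(models) < 1:
        raise ValueError("need at least one candidate model")
    records = []
    failures = {}
    for model in models:
        try:
            log_ev, ens = evaluate_model(model, data, net, waveform,
                                         solver_cfg, tmcmc_cfg)
        except Exception as exc:  # keep going; report at the end
            failures[model.model_id] = str(exc)
            continue
        means, covs = [], []
        for name in model.prior.names[:-1]:
            mean, _, u = posterior_summary(ens, name)
            means.append(mean)
            covs.append(u)
        s_mean, _, s_u = posterior_summary(ens, "sigma")
        rec = {
            "model_id": model.model_id,
            "free_arteries": model.free_arteries,
            "parameter": model.parameter,
            "log_evidence": log_ev,
            "estimates": means,
            "estimate_covs": covs,
            "sigma_hat": s_mean,
            "sigma_cov": s_u,
        }
        if keep_ensembles:
            rec["ensemble"] = ens
        records.append(rec)
    if not records:
        return ModelSelectionResult([], None, complete=False, failures=failures)
    probs = model_posterior(
        [r["log_evidence"] for r in records],
        None if model_prior is None else
        [model_prior[r["model_id"]] for r in records],
    )
    for r, p in zip(records, probs):
        r["probability"] = float(p)
    winner = max(records, key=lambda r: r["probability"])["model_id"]
    return ModelSelectionResult(records, winner,
                                complete=not failures, failures=failures)
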