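"""Synthetic noisy observations of arterial flow velocity.

Observed data are modelled as D_k = v_k + sigma * eps_k with
independent standard-normal eps_k and a noise level sigma set to a
stated fraction (typically 1% or 5%) of the pooled standard deviation
eta of all clean velocities in the experiment.  A second, systemic
corruption multiplies every artery's relaxed reference area by
(1 + sigma_alpha * eps_k), so that no parameter setting of the
inference model reproduces the data exactly (model misspecification).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import ArterialNetwork, DefectSpec, apply_defect
from .solver import InflowWaveform, SensorConfig, SolverConfig, simulate

__all__ = [
    "ObservationSet",
    "pooled_scale",
    "add_noise",
    "perturb_reference_areas",
    "generate_dataset",
]

# fixed offsets deriving independent RNG streams from one master seed
_OBS_STREAM = 1
_PARAM_STREAM = 2


@dataclass
class ObservationSet:
    """Noisy velocity time series per sensor — the data D.

    ``values`` has shape (n_sensors, n_times); ``sigma`` is the
    additive noise level in m/s, ``eta`` the pooled clean-velocity
    standard deviation so that sigma = noise_fraction * eta.
    """

    sensors: SensorConfig
    times: np.ndarray
    values: np.ndarray
    noise_fraction: float = 0.0
    sigma: float = 0.0
    eta: float = 0.0
    seed: int | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (len(self.sensors), self.times.size):
            raise ValueError("values shape must be (n_sensors, n_times)")

    @property
    def n_data(self) -> int:
        return self.values.size

    def flat(self) -> np.ndarray:
        """Sensor-major data vector, matching SimulationResult.flat()."""
        return self.values.reshape(-1).copy()

    def to_csv(self, path, sidecar=None) -> None:
        rows = []
        for s, (aid, pos) in enumerate(self.sensors.sensors):
            for t, v in zip(self.times, self.values[s]):
                rows.append((s, aid, str(pos), t, v))
        pd.DataFrame(
            rows, columns=["sensor_id", "artery_id", "position", "time_s", "velocity_m_s"]
        ).to_csv(path, index=False)
        if sidecar is not None:
            meta = {
                "noise_fraction": self.noise_fraction,
                "sigma": self.sigma,
                "eta": self.eta,
                "seed": self.seed,
                "sampling_period": self.sensors.sampling_period,
                "ground_truth": self.ground_truth,
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=2, default=float)

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "ObservationSet":
        df = pd.read_csv(path)
        sensor_rows = df.drop_duplicates("sensor_id").sort_values("sensor_id")
        times = np.sort(df["time_s"].unique())
        sensors = SensorConfig(
            sensors=tuple(
                (int(r.artery_id), _parse_position(r.position))
                for r in sensor_rows.itertuples()
            ),
            sampling_period=float(times[0]) if times.size == 1 else float(
                np.median(np.diff(times))
            ),
        )
        values = np.empty((len(sensors), times.size))
        for s in range(len(sensors)):
            sub = df[df.sensor_id == s].sort_values("time_s")
            values[s] = sub["velocity_m_s"].to_numpy()
        obs = cls(sensors, times, values)
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
            obs.noise_fraction = meta.get("noise_fraction", 0.0)
            obs.sigma = meta.get("sigma", 0.0)
            obs.eta = meta.get("eta", 0.0)
            obs.seed = meta.get("seed")
            obs.ground_truth = meta.get("ground_truth", {})
        return obs


def _parse_position(pos):
    try:
        return float(pos)
    except (TypeError, ValueError):
        return str(pos)


def pooled_scale(velocities) -> float:
    """Population standard deviation of all clean velocities pooled
    across sensors and times (the scale eta that noise levels are
    quoted against)."""
    v = np.asarray(velocities, dtype=float).reshape(-1)
    if v.size < 2:
        raise ValueError("need at least 2 velocity values to pool a scale")
    return float(np.std(v))  # population (n-denominator) convention


def add_noise(clean, sensors: SensorConfig, times, fraction: float,
              seed: int) -> ObservationSet:
    """Corrupt a clean velocity record with additive Gaussian noise at
    ``fraction`` of the pooled velocity scale."""
    if fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    clean = np.asarray(clean, dtype=float)
    eta = pooled_scale(clean)
    sigma = fraction * eta
    rng = np.random.default_rng([_OBS_STREAM, seed])
    noisy = clean + sigma * rng.standard_normal(clean.shape)
    return ObservationSet(
        sensors, times, noisy,
        noise_fraction=fraction, sigma=sigma, eta=eta, seed=seed,
    )


def perturb_reference_areas(net: ArterialNetwork, sigma_alpha: float,
                            seed: int) -> ArterialNetwork:
    """Multiply every relaxed area by (1 + sigma_alpha * eps), eps iid
    standard normal, leaving reference areas untouched so the scaled
    area alpha records the corruption.

    Rejects draws that would produce a non-positive area (only
    possible for implausibly large ``sigma_alpha``).
    """
    if sigma_alpha < 0:
        raise ValueError("sigma_alpha must be >= 0")
    if sigma_alpha == 0:
        return net
    rng = np.random.default_rng([_PARAM_STREAM, seed])
    ids = sorted(net.arteries)
    factors = 1.0 + sigma_alpha * rng.standard_normal(len(ids))
    if np.any(factors <= 0):
        raise ValueError(
            f"sigma_alpha = {sigma_alpha} produced a non-positive area; "
            "choose a smaller parameter noise level"
        )
    new = {}
    for aid, f in zip(ids, factors):
        g = net.arteries[aid]
        new[aid] = replace(g, relaxed_area=f * g.relaxed_area)
    return net.with_arteries(new)


def generate_dataset(
    net: ArterialNetwork,
    defect: DefectSpec | None,
    waveform: InflowWaveform,
    cfg: SolverConfig,
    sensors: SensorConfig,
    fraction: float = 0.01,
    sigma_alpha: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Produce a synthetic dataset with known ground truth.

    Applies the defect (and, optionally, multiplicative reference-area
    corruption) to the network, runs the forward simulation, and adds
    observation noise.  The ground-truth sidecar records the injected
    defect, the realized noise level and the seeds, for later
    accuracy assessment.
    """
    truth_net = net
    if defect is not None:
        truth_net = apply_defect(truth_net, defect)
    if sigma_alpha > 0:
        truth_net = perturb_reference_areas(truth_net, sigma_alpha, seed)
    clean = simulate(truth_net, waveform, cfg, sensors)
    obs = add_noise(clean.velocities, sensors, clean.times, fraction, seed)
    obs.ground_truth = {
        "defect": None if defect is None else {
            "artery_id": defect.artery_id,
            "parameter": defect.parameter,
            "factor": defect.factor,
        },
        "noise_fraction": fraction,
        "sigma": obs.sigma,
        "eta": obs.eta,
        "sigma_alpha": sigma_alpha,
        "seed": seed,
        "alphas": {aid: truth_net.arteries[aid].alpha for aid in sorted(net.arteries)},
        "betas": {aid: truth_net.arteries[aid].beta for aid in sorted(net.arteries)},
    }
    return obs
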