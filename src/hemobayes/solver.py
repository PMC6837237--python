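"""Nonlinear 1D pulse-wave propagation on an arterial network.

The conservation form solved on each artery is

    dU/dt + dF/dx = S(U),    U = [A, u],
    F = [A u,  u^2/2 + p_e / rho],    S = [0,  K_r u / (rho A)],

with the elastic tube law closing the pressure.  Space is discretized
by a discontinuous Galerkin method with orthonormal Legendre modes of
degree ``p`` on ``N`` elements per artery; interfaces use upwind
fluxes built from the Riemann invariants W_{1,2} = u +- 4c, and time
integration is second-order Adams-Bashforth bootstrapped by a single
forward-Euler step.  Bifurcations enforce conservation of mass and
continuity of total pressure via Newton iteration; the inlet
prescribes a velocity waveform reflection-free and terminal outlets
are fully absorbing (incoming invariant held at its rest value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .network import ArterialNetwork, wave_speed

__all__ = [
    "SolverConfig",
    "InflowWaveform",
    "SensorConfig",
    "SimulationResult",
    "SolverError",
    "simulate",
    "junction_solve",
    "default_inflow",
    "stable_time_step",
]

#: Default sampling period of the velocity sensors, s.
DEFAULT_SAMPLING_PERIOD = 0.064

_STATUS_MESSAGES = {
    _kernel.STATUS_BLOWUP: "non-physical cross-sectional area (solver blow-up)",
    _kernel.STATUS_CFL: "CFL bound violated during run",
    _kernel.STATUS_JUNCTION: "junction Newton iteration failed to converge",
    _kernel.STATUS_BOUNDARY: "characteristic boundary state became non-physical",
}


class SolverError(RuntimeError):
    """Raised when the forward simulation fails; carries location info."""

    def __init__(self, message, artery_id=None, element=None, time=None):
        super().__init__(message)
        self.artery_id = artery_id
        self.element = element
        self.time = time


@dataclass(frozen=True)
class SolverConfig:
    """Discretization settings.

    ``time_step`` of ``None`` selects the largest stable step from the
    CFL condition (with ``speed_margin`` headroom for flow-induced
    wave-speed increases) and rounds it down so the sensor sampling
    period is an exact integer multiple.
    """

    elements_per_artery: int = 4
    polynomial_degree: int = 2
    time_step: float | None = None
    final_time: float = 3.328
    newton_tolerance: float = 1e-12
    newton_max_iterations: int = 50
    cfl_number: float = 0.5
    speed_margin: float = 2.0

    def __post_init__(self):
        if self.elements_per_artery < 1:
            raise ValueError("need at least one element per artery")
        if self.polynomial_degree < 0:
            raise ValueError("polynomial degree must be >= 0")
        if not 0 < self.cfl_number <= 0.5:
            raise ValueError("cfl_number must lie in (0, 0.5]")


@dataclass(frozen=True)
class InflowWaveform:
    """Periodic inlet velocity as a truncated Fourier series.

    u(t) = a[0] + sum_k a[k] cos(2 pi k t / T) + b[k] sin(2 pi k t / T)
    over ``n_cycles`` repetitions of the fundamental period ``T``.
    """

    period: float
    cos_amplitudes: tuple[float, ...]
    sin_amplitudes: tuple[float, ...]
    n_cycles: int = 3

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if len(self.cos_amplitudes) != len(self.sin_amplitudes):
            raise ValueError("cosine and sine amplitude lists must match")

    @property
    def duration(self) -> float:
        return self.n_cycles * self.period

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi / self.period
        u = np.full_like(t, self.cos_amplitudes[0], dtype=float)
        for k in range(1, len(self.cos_amplitudes)):
            u += self.cos_amplitudes[k] * np.cos(k * w * t)
            u += self.sin_amplitudes[k] * np.sin(k * w * t)
        return u if u.ndim else float(u)


def default_inflow(
    period: float = 1.1,
    peak_velocity: float = 0.5,
    systole_fraction: float = 0.3,
    n_harmonics: int = 10,
    n_cycles: int = 3,
) -> InflowWaveform:
    """Cardiac-like inflow: Fourier fit of a half-sine systolic pulse.

    The pulse rises over ``systole_fraction`` of the cycle to
    ``peak_velocity`` and the remainder of the cycle is diastolic
    rest; truncation to ``n_harmonics`` harmonics yields the smooth
    trigonometric-polynomial inflow used throughout.
    """
    n_grid = 4096
    t = np.arange(n_grid) / n_grid * period
    t_sys = systole_fraction * period
    u = np.where(t < t_sys, peak_velocity * np.sin(np.pi * t / t_sys), 0.0)
    spec = np.fft.rfft(u) / n_grid
    a = [float(spec[0].real)]
    b = [0.0]
    for k in range(1, n_harmonics + 1):
        a.append(2.0 * float(spec[k].real))
        b.append(-2.0 * float(spec[k].imag))
    return InflowWaveform(period, tuple(a), tuple(b), n_cycles)


@dataclass(frozen=True)
class SensorConfig:
    """Velocity measurement locations and cadence.

    Each sensor is ``(artery_id, position)`` with position the keyword
    ``"start"``/``"end"`` or a coordinate in metres from the upstream
    end of the artery.
    """

    sensors: tuple[tuple[int, object], ...]
    sampling_period: float = DEFAULT_SAMPLING_PERIOD

    def __post_init__(self):
        if not self.sensors:
            raise ValueError("need at least one sensor")
        if self.sampling_period <= 0:
            raise ValueError("sampling period must be > 0")
        object.__setattr__(self, "sensors", tuple(tuple(s) for s in self.sensors))

    def __len__(self):
        return len(self.sensors)


@dataclass
class SimulationResult:
    """Sensor velocity records plus solver diagnostics."""

    times: np.ndarray  # (n_samples,)
    velocities: np.ndarray  # (n_sensors, n_samples)
    sensors: SensorConfig
    metadata: dict = field(default_factory=dict)
    boundary_mass_flux: np.ndarray | None = None  # (nt, 2) inlet/terminal A*u
    area_coefficients: np.ndarray | None = None
    velocity_coefficients: np.ndarray | None = None

    def flat(self) -> np.ndarray:
        """Sensor-major flattened velocity vector (the forward-map output)."""
        return self.velocities.reshape(-1).copy()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, (aid, pos) in enumerate(self.sensors.sensors):
            for t, v in zip(self.times, self.velocities[s]):
                rows.append((s, aid, str(pos), t, v))
        return pd.DataFrame(
            rows, columns=["sensor_id", "artery_id", "position", "time_s", "velocity_m_s"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def junction_solve(parent_state, child_states, geoms, density,
                   tol: float = 1e-12, max_iterations: int = 50):
    """Coupled boundary values at a Y-bifurcation.

    Given the parent artery's outlet trace ``(A, u)``, the two
    daughters' inlet traces, and the three artery geometries
    ``(parent, child_a, child_b)``, solves the six bifurcation
    conditions — conservation of mass A1 u1 = A2 u2 + A3 u3,
    continuity of total pressure p + rho u^2/2 into each daughter,
    and the three outgoing Riemann invariants held at their upwinded
    values — by Newton iteration.  Returns (A1, u1, A2, u2, A3, u3).
    """
    (ap, up) = parent_state
    (aa, ua), (ab, ub) = child_states
    gp, ga, gb = geoms
    W1 = up + 4.0 * wave_speed(ap, gp, density)
    W2a = ua - 4.0 * wave_speed(aa, ga, density)
    W2b = ub - 4.0 * wave_speed(ab, gb, density)
    ok, a1, u1, a2, u2, a3, u3 = _kernel._junction_newton(
        W1, W2a, W2b,
        gp.stiffness, gp.relaxed_area,
        ga.stiffness, ga.relaxed_area,
        gb.stiffness, gb.relaxed_area,
        ap, aa, ab, density, tol, max_iterations)
    if not ok:
        # report the residuals at the failed iterate
        p1 = gp.stiffness * (math.sqrt(a1) - math.sqrt(gp.relaxed_area))
        raise SolverError(
            f"junction Newton failed to converge within {max_iterations} "
            f"iterations (last A = {a1:.3e}, {a2:.3e}, {a3:.3e}; "
            f"parent pressure residual scale {p1:.3e} Pa)")
    return a1, u1, a2, u2, a3, u3


# ---------------------------------------------------------------------------
# basis construction

def _orthonormal_legendre(p: int, nq: int):
    """Values and derivatives of sqrt(k+1/2) P_k at Gauss points."""
    xq, wq = np.polynomial.legendre.leggauss(nq)
    nm = p + 1
    phi = np.empty((nm, nq))
    dphi = np.empty((nm, nq))
    phi_L = np.empty(nm)
    phi_R = np.empty(nm)
    for k in range(nm):
        coef = np.zeros(k + 1)
        coef[k] = math.sqrt(k + 0.5)
        phi[k] = np.polynomial.legendre.legval(xq, coef)
        dphi[k] = np.polynomial.legendre.legval(xq, np.polynomial.legendre.legder(coef))
        phi_L[k] = np.polynomial.legendre.legval(-1.0, coef)
        phi_R[k] = np.polynomial.legendre.legval(1.0, coef)
    return xq, wq, phi, dphi, phi_L, phi_R


# ---------------------------------------------------------------------------
# network flattening

def _flatten(net: ArterialNetwork):
    """Deterministic artery ordering: inlet first, then ascending id."""
    ids = [net.inlet_artery] + sorted(a for a in net.arteries if a != net.inlet_artery)
    index = {aid: i for i, aid in enumerate(ids)}
    n = len(ids)
    length = np.array([net.arteries[a].length for a in ids])
    A0 = np.array([net.arteries[a].relaxed_area for a in ids])
    B = np.array([net.arteries[a].stiffness for a in ids])
    parents, c1, c2 = [], [], []
    for par in sorted(net.topology):
        lo, hi = sorted(net.topology[par])
        parents.append(index[par])
        c1.append(index[lo])
        c2.append(index[hi])
    terminals = np.array([index[a] for a in net.terminal_arteries], dtype=np.int64)
    return (ids, index, length, A0, B,
            np.array(parents, dtype=np.int64),
            np.array(c1, dtype=np.int64),
            np.array(c2, dtype=np.int64),
            terminals)


def stable_time_step(net: ArterialNetwork, cfg: SolverConfig) -> float:
    """Largest time step allowed by the CFL estimate.

    Uses the relaxed-area wave speed times ``speed_margin`` (headroom
    for area dilation and defect stiffening) plus a 1 m/s advective
    scale, and the 1/(2p+1) factor of nodal DG stability.
    """
    h_min = min(g.length for g in net.arteries.values()) / cfg.elements_per_artery
    c0 = max(
        wave_speed(g.relaxed_area, g, net.fluid.density) for g in net.arteries.values()
    )
    speed = cfg.speed_margin * c0 + 1.0
    return cfg.cfl_number * h_min / ((2 * cfg.polynomial_degree + 1) * speed)


def _resolve_sensors(net, sensors, index, length, nelem, p):
    ns = len(sensors)
    sens_art = np.empty(ns, dtype=np.int64)
    sens_elem = np.empty(ns, dtype=np.int64)
    sens_phi = np.empty((ns, p + 1))
    for s, (aid, pos) in enumerate(sensors.sensors):
        if aid not in index:
            raise KeyError(f"sensor references unknown artery {aid}")
        i = index[aid]
        ell = length[i]
        if pos == "start":
            x = 0.0
        elif pos == "end":
            x = ell
        else:
            x = float(pos)
            if not 0.0 <= x <= ell:
                raise ValueError(f"sensor position {x} outside artery {aid} [0, {ell}]")
        h = ell / nelem
        e = min(int(x / h), nelem - 1)
        xi = 2.0 * (x - e * h) / h - 1.0
        for k in range(p + 1):
            coef = np.zeros(k + 1)
            coef[k] = math.sqrt(k + 0.5)
            sens_phi[s, k] = np.polynomial.legendre.legval(xi, coef)
        sens_art[s] = i
        sens_elem[s] = e
    return sens_art, sens_elem, sens_phi


# ---------------------------------------------------------------------------
# driver

def simulate(
    net: ArterialNetwork,
    waveform: InflowWaveform,
    cfg: SolverConfig,
    sensors: SensorConfig,
    keep_state: bool = False,
) -> SimulationResult:
    """Run the pulse-wave simulation and sample sensor velocities.

    Starting from rest (u = 0, A = A0 everywhere) the network is
    driven by ``waveform`` at the inlet; velocities are recorded at
    every sensor each ``sampling_period`` from t = dt2 up to
    ``cfg.final_time``.  Deterministic: identical inputs give
    bit-identical output.
    """
    (ids, index, length, A0, B, parents, c1, c2, terminals) = _flatten(net)
    nelem = cfg.elements_per_artery
    p = cfg.polynomial_degree
    nm = p + 1
    rho = net.fluid.density
    h = length / nelem
    h_min = float(h.min())

    dt2 = sensors.sampling_period
    n_samples = int(math.floor(cfg.final_time / dt2 + 1e-9))
    if n_samples < 1:
        raise ValueError("final_time shorter than one sampling period")

    if cfg.time_step is None:
        dt_target = stable_time_step(net, cfg)
        stride = max(1, int(math.ceil(dt2 / dt_target - 1e-12)))
    else:
        stride = int(round(dt2 / cfg.time_step))
        if stride < 1 or abs(stride * cfg.time_step - dt2) > 1e-9 * dt2:
            raise ValueError("sampling period must be an integer multiple of time_step")
    dt = dt2 / stride
    nt = n_samples * stride

    # static CFL check on the configured step (the kernel re-checks
    # against the instantaneous max |u| + c during the run)
    c0 = np.array([wave_speed(net.arteries[a].relaxed_area, net.arteries[a], rho)
                   for a in ids])
    if dt > 0.5 * h_min / float(c0.max() + 1.0):
        raise ValueError(
            f"time step {dt:g} violates the CFL bound "
            f"{0.5 * h_min / float(c0.max() + 1.0):g}"
        )

    xq, wq, phi, dphi, phi_L, phi_R = _orthonormal_legendre(p, nm)
    sens_art, sens_elem, sens_phi = _resolve_sensors(
        net, sensors, index, length, nelem, p)

    a_coef = np.zeros((len(ids), nelem, nm))
    u_coef = np.zeros((len(ids), nelem, nm))
    a_coef[:, :, 0] = A0[:, None] * math.sqrt(2.0)  # A = A0, phi_0 = 1/sqrt(2)

    inflow_u = waveform.evaluate(np.arange(nt) * dt)
    out = np.empty((len(sensors), n_samples))
    bflux = np.empty((nt, 2))
    c_rest = np.sqrt(B / (2.0 * rho)) * A0**0.25

    status, ei, ee, step = _kernel.run_simulation(
        a_coef, u_coef, h, A0, B, c_rest,
        parents, c1, c2, terminals,
        np.ascontiguousarray(inflow_u, dtype=float), dt, nt, rho,
        net.fluid.friction_coefficient, net.fluid.external_pressure,
        phi, dphi, wq, phi_L, phi_R,
        cfg.newton_tolerance, cfg.newton_max_iterations,
        h_min, 0.5,
        stride, sens_art, sens_elem, sens_phi,
        out, bflux)
    if status != _kernel.STATUS_OK:
        aid = ids[ei] if 0 <= ei < len(ids) else None
        raise SolverError(
            f"{_STATUS_MESSAGES.get(status, 'solver failure')} "
            f"(artery {aid}, element {ee}, t = {step * dt:.6f} s)",
            artery_id=aid, element=ee, time=step * dt)

    times = (np.arange(n_samples) + 1) * dt2
    meta = {
        "time_step": dt,
        "stride": stride,
        "n_steps": nt,
        "elements_per_artery": nelem,
        "polynomial_degree": p,
        "final_time": n_samples * dt2,
        "sampling_period": dt2,
        "artery_order": list(ids),
    }
    result = SimulationResult(times, out, sensors, meta)
    result.boundary_mass_flux = bflux
    if keep_state:
        result.area_coefficients = a_coef
        result.velocity_coefficients = u_coef
    return result
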