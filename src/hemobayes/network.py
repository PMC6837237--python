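"""Branching arterial networks: geometry, material law, defects.

An arterial tree is a rooted binary tree of one-dimensional vessel
segments.  Each segment carries an elastic tube law

    p(A) = p_ext + B (sqrt(A) - sqrt(A0)),

where ``A`` is the instantaneous cross-sectional area, ``A0`` the
relaxed (zero-transmural-pressure) area and ``B`` the wall stiffness
(Pa m^-1), collecting Young's modulus, wall thickness and a Poisson
ratio of 1/2 into a single coefficient.  Structural defects —
aneurysms and stenoses — are modelled as multiplicative perturbations
of the stiffness (scaled stiffness ``beta = B/B*``) or the relaxed
area (scaled area ``alpha = A0/A0*``) of one artery; a healthy artery
has ``beta = alpha = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ArteryGeometry",
    "ArterialNetwork",
    "DefectSpec",
    "FluidProperties",
    "tube_law_pressure",
    "wave_speed",
    "build_fixture_network",
    "apply_defect",
    "load_network",
    "save_network",
]

#: Standard density of whole blood, kg m^-3.
BLOOD_DENSITY = 1060.0
#: Reference dynamic viscosity of blood, Pa s.
BLOOD_VISCOSITY = 0.0045


@dataclass(frozen=True)
class FluidProperties:
    """Bulk fluid constants shared by every artery of a network.

    The friction coefficient ``K_r = -22 mu pi`` follows from the
    assumed axial velocity profile and always tracks the viscosity.
    """

    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY
    external_pressure: float = 0.0

    @property
    def friction_coefficient(self) -> float:
        return -22.0 * self.viscosity * math.pi

    def with_viscosity(self, mu: float) -> "FluidProperties":
        return replace(self, viscosity=mu)


@dataclass(frozen=True)
class ArteryGeometry:
    """One vessel segment.

    ``stiffness`` and ``relaxed_area`` are the values actually used by
    the solver; ``reference_stiffness``/``reference_area`` are the
    healthy baselines, so the scaled parameters ``beta``/``alpha``
    equal 1 for an undamaged artery.
    """

    artery_id: int
    length: float  # m
    relaxed_area: float  # m^2
    stiffness: float  # Pa m^-1
    reference_area: float | None = None
    reference_stiffness: float | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"artery {self.artery_id}: length must be > 0")
        if self.relaxed_area <= 0:
            raise ValueError(f"artery {self.artery_id}: relaxed area must be > 0")
        if self.stiffness <= 0:
            raise ValueError(f"artery {self.artery_id}: stiffness must be > 0")
        if self.reference_area is None:
            object.__setattr__(self, "reference_area", self.relaxed_area)
        if self.reference_stiffness is None:
            object.__setattr__(self, "reference_stiffness", self.stiffness)

    @property
    def beta(self) -> float:
        """Scaled stiffness B / B*."""
        return self.stiffness / self.reference_stiffness

    @property
    def alpha(self) -> float:
        """Scaled relaxed area A0 / A0*."""
        return self.relaxed_area / self.reference_area


@dataclass(frozen=True)
class DefectSpec:
    """A structural defect: multiply one artery's stiffness or relaxed
    area by ``factor`` relative to its healthy reference value."""

    artery_id: int
    parameter: str  # "stiffness" or "area"
    factor: float

    def __post_init__(self):
        if self.parameter not in ("stiffness", "area"):
            raise ValueError(f"unknown defect parameter {self.parameter!r}")
        if self.factor <= 0:
            raise ValueError("defect factor must be > 0")


@dataclass(frozen=True)
class ArterialNetwork:
    """A rooted binary tree of arteries.

    ``topology`` maps a parent artery id to its ordered ``(left,
    right)`` daughter ids; arteries absent from the map are terminal.
    """

    arteries: dict[int, ArteryGeometry]
    topology: dict[int, tuple[int, int]]
    inlet_artery: int
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self):
        _validate_tree(self.arteries, self.topology, self.inlet_artery)

    @property
    def terminal_arteries(self) -> list[int]:
        return sorted(a for a in self.arteries if a not in self.topology)

    @property
    def n_arteries(self) -> int:
        return len(self.arteries)

    def artery(self, artery_id: int) -> ArteryGeometry:
        try:
            return self.arteries[artery_id]
        except KeyError:
            raise KeyError(f"artery {artery_id} not in network") from None

    def with_arteries(self, new: dict[int, ArteryGeometry]) -> "ArterialNetwork":
        arteries = dict(self.arteries)
        arteries.update(new)
        return ArterialNetwork(arteries, self.topology, self.inlet_artery, self.fluid)

    def with_fluid(self, fluid: FluidProperties) -> "ArterialNetwork":
        return ArterialNetwork(self.arteries, self.topology, self.inlet_artery, fluid)


def _validate_tree(arteries, topology, inlet):
    if inlet not in arteries:
        raise ValueError(f"inlet artery {inlet} not present")
    seen = set()
    stack = [inlet]
    while stack:
        a = stack.pop()
        if a in seen:
            raise ValueError(f"artery {a} reached twice: topology is not a tree")
        seen.add(a)
        if a in topology:
            kids = topology[a]
            if len(kids) != 2:
                raise ValueError(f"artery {a}: bifurcations need exactly 2 children")
            for c in kids:
                if c not in arteries:
                    raise ValueError(f"child artery {c} of {a} not present")
                stack.append(c)
    if seen != set(arteries):
        orphans = sorted(set(arteries) - seen)
        raise ValueError(f"arteries {orphans} unreachable from inlet {inlet}")


# ---------------------------------------------------------------------------
# material law

def tube_law_pressure(A, geom: ArteryGeometry, p_ext: float = 0.0):
    """Internal pressure from the elastic tube law.

    p = p_ext + B (sqrt(A) - sqrt(A0)); vanishing transmural pressure
    at the relaxed area, strictly increasing in ``A``.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("cross-sectional area must be > 0")
    p = p_ext + geom.stiffness * (np.sqrt(A) - math.sqrt(geom.relaxed_area))
    return p if p.ndim else float(p)


def wave_speed(A, geom: ArteryGeometry, density: float = BLOOD_DENSITY):
    """Pulse-wave speed c = sqrt(A/rho * dp/dA) = sqrt(B/(2 rho)) A^{1/4}."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or density <= 0:
        raise ValueError("area and density must be > 0")
    c = math.sqrt(geom.stiffness / (2.0 * density)) * A ** 0.25
    return c if c.ndim else float(c)


# ---------------------------------------------------------------------------
# defect injection

def apply_defect(net: ArterialNetwork, defect: DefectSpec) -> ArterialNetwork:
    """Return a copy of ``net`` with one artery's stiffness or relaxed
    area set to ``factor`` times its *reference* value.

    The scaled parameter (beta or alpha) of the targeted artery then
    equals ``factor`` exactly; every other artery is untouched.
    """
    geom = net.artery(defect.artery_id)
    if defect.parameter == "stiffness":
        geom = replace(geom, stiffness=defect.factor * geom.reference_stiffness)
    else:
        geom = replace(geom, relaxed_area=defect.factor * geom.reference_area)
    return net.with_arteries({defect.artery_id: geom})


# ---------------------------------------------------------------------------
# fixture generation

#: Length range of the study tree, m.
FIXTURE_LENGTH_RANGE = (0.026, 0.17)
#: Relaxed-area range of the study tree, m^2.
FIXTURE_AREA_RANGE = (1e-6, 1e-5)
#: Pulse-wave speed range used to assign stiffnesses, m s^-1.
FIXTURE_WAVE_SPEED_RANGE = (4.0, 8.0)


def build_fixture_network(
    n_arteries: int = 19,
    seed: int = 0,
    fluid: FluidProperties | None = None,
) -> ArterialNetwork:
    """Generate a seeded test tree in the study parameter ranges.

    Arteries are labelled 1..n in breadth-first order (artery ``k``
    bifurcates into ``2k`` and ``2k+1``), giving a full binary tree
    for any odd ``n_arteries``.  Lengths are drawn uniformly from
    [0.026, 0.17] m.  Areas decrease down the tree: the root is drawn
    near the top of [1e-6, 1e-5] m^2 and each daughter is a random
    fraction of its parent, clipped to the range, which mimics the
    taper of a real arterial tree.  Stiffnesses are assigned so the
    relaxed wave speed lies in a physiological 4-8 m/s band.

    The generated values are stored as both actual and reference
    parameters, so every artery starts with beta = alpha = 1.
    """
    if n_arteries < 3 or n_arteries % 2 == 0:
        raise ValueError("n_arteries must be odd and >= 3 for a full binary tree")
    rng = np.random.default_rng(seed)
    fluid = fluid or FluidProperties()

    lo_l, hi_l = FIXTURE_LENGTH_RANGE
    lo_a, hi_a = FIXTURE_AREA_RANGE
    lo_c, hi_c = FIXTURE_WAVE_SPEED_RANGE

    areas: dict[int, float] = {1: float(rng.uniform(0.6 * hi_a, hi_a))}
    for k in range(2, n_arteries + 1):
        parent_area = areas[k // 2]
        frac = rng.uniform(0.65, 0.9)
        areas[k] = float(np.clip(frac * parent_area, lo_a, hi_a))

    arteries = {}
    for k in range(1, n_arteries + 1):
        length = float(rng.uniform(lo_l, hi_l))
        c0 = float(rng.uniform(lo_c, hi_c))
        # invert c = sqrt(B/(2 rho)) A0^{1/4} for the stiffness
        B = 2.0 * fluid.density * c0**2 / math.sqrt(areas[k])
        arteries[k] = ArteryGeometry(k, length, areas[k], B)

    topology = {
        k: (2 * k, 2 * k + 1)
        for k in range(1, n_arteries + 1)
        if 2 * k + 1 <= n_arteries
    }
    return ArterialNetwork(arteries, topology, inlet_artery=1, fluid=fluid)


# ---------------------------------------------------------------------------
# config I/O

def save_network(net: ArterialNetwork, path) -> None:
    """Write a network to a YAML config file."""
    doc = {
        "inlet_artery": net.inlet_artery,
        "fluid": {
            "density": net.fluid.density,
            "viscosity": net.fluid.viscosity,
            "external_pressure": net.fluid.external_pressure,
        },
        "arteries": {
            int(a.artery_id): {
                "length": float(a.length),
                "relaxed_area": float(a.relaxed_area),
                "stiffness": float(a.stiffness),
                "reference_area": float(a.reference_area),
                "reference_stiffness": float(a.reference_stiffness),
                "parent": next(
                    (int(p) for p, kids in net.topology.items() if a.artery_id in kids),
                    None,
                ),
            }
            for a in net.arteries.values()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_network(path) -> ArterialNetwork:
    """Read a network config, validating invariants; errors name the
    offending artery."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    fluid = FluidProperties(**doc.get("fluid", {}))
    arteries = {}
    children: dict[int, list[int]] = {}
    for aid, rec in doc["arteries"].items():
        aid = int(aid)
        try:
            arteries[aid] = ArteryGeometry(
                aid,
                rec["length"],
                rec["relaxed_area"],
                rec["stiffness"],
                rec.get("reference_area"),
                rec.get("reference_stiffness"),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"artery {aid}: invalid config ({exc})") from exc
        parent = rec.get("parent")
        if parent is not None:
            children.setdefault(int(parent), []).append(aid)
    topology = {}
    for parent, kids in children.items():
        if len(kids) != 2:
            raise ValueError(
                f"artery {parent}: has {len(kids)} children, bifurcations need 2"
            )
        topology[parent] = tuple(sorted(kids))  # ascending-id convention
    return ArterialNetwork(arteries, topology, int(doc["inlet_artery"]), fluid)
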