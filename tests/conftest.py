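"""Shared fixtures: a small seeded arterial tree, desk-scale solver
settings, and the (expensive, session-scoped) batch of seeded
defect-localization replications reused by several tests."""

import numpy as np
import pytest

import hemobayes as hb
from hemobayes.network import ArterialNetwork, ArteryGeometry, FluidProperties
from hemobayes.selection import pair_defect_model, single_defect_model
from hemobayes.tmcmc import TMCMCConfig


@pytest.fixture(scope="session")
def net7():
    """Seven-artery binary tree: 1 -> (2, 3), 2 -> (4, 5), 3 -> (6, 7)."""
    return hb.build_fixture_network(7, seed=11)


@pytest.fixture(scope="session")
def net19():
    return hb.build_fixture_network(19, seed=11)


@pytest.fixture(scope="session")
def one_cycle_wave():
    return hb.default_inflow(n_cycles=1)


@pytest.fixture(scope="session")
def desk_cfg():
    """Desk-scale discretization: 1 element/artery, 13 velocity samples."""
    return hb.SolverConfig(elements_per_artery=1, final_time=0.832)


@pytest.fixture(scope="session")
def sensors_two(net7):
    """Two non-adjacent sensors: ends of the root and of a parallel
    branch relative to the artery-2 defect used throughout."""
    return hb.SensorConfig(sensors=((1, "end"), (7, "end")))


@pytest.fixture(scope="session")
def single_artery_net():
    g = ArteryGeometry(1, 0.2, 5e-6, 2e7)
    return ArterialNetwork({1: g}, {}, 1, FluidProperties())


#: The ten seeded localization replications: (parameter, factor,
#: parameter-noise level sigma_alpha).  The true defect is always in
#: artery 2; scenarios cover a stiffness defect, an area aneurysm and
#: an area stenosis, each including one misspecified run.
LOCALIZATION_SCENARIOS = [
    ("stiffness", 0.5, 0.0),
    ("stiffness", 0.5, 0.0),
    ("stiffness", 0.5, 0.0),
    ("stiffness", 0.5, 0.01),
    ("area", 1.5, 0.0),
    ("area", 1.5, 0.0),
    ("area", 1.5, 0.01),
    ("area", 0.5, 0.0),
    ("area", 0.5, 0.0),
    ("area", 0.5, 0.01),
]

TRUE_DEFECT_ARTERY = 2


@pytest.fixture(scope="session")
def localization_runs(net7, one_cycle_wave, desk_cfg, sensors_two):
    """Run model selection for each scenario; each candidate class is
    {M_2, M_3, M_4, M_6, M_2:3} over the scenario's parameter kind."""
    results = []
    for rep, (par, fac, sa) in enumerate(LOCALIZATION_SCENARIOS):
        data = hb.generate_dataset(
            net7, hb.DefectSpec(TRUE_DEFECT_ARTERY, par, fac),
            one_cycle_wave, desk_cfg, sensors_two,
            fraction=0.01, sigma_alpha=sa, seed=100 + rep)
        models = [single_defect_model(i, par) for i in (2, 3, 4, 6)]
        models.append(pair_defect_model(2, 3, par))
        sel = hb.run_selection(
            models, data, net7, one_cycle_wave, desk_cfg,
            TMCMCConfig(n_samples=128, seed=1000 + rep))
        results.append({
            "scenario": (par, fac, sa),
            "selection": sel,
            "data": data,
        })
    return results
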