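"""Shared fixtures: the synthetic core network, the reference environment, and
session-cached solved models (the expensive lexicographic solves are reused
across test modules)."""

from __future__ import annotations

import numpy as np
import pytest

from dielfba import (DielConstraintSet, ScenarioConfig, apply_vacuole_capacity,
                     build_toy_core, couple_water_loss, expand_diel,
                     make_profile, maximize_phloem, minimize_water,
                     pareto_scan, run_scenario)
from dielfba.network import MetabolicNetwork, Metabolite, Reaction, ToyOptions


@pytest.fixture(scope="session")
def toy_net():
    return build_toy_core()


@pytest.fixture(scope="session")
def env_default():
    return make_profile()


@pytest.fixture(scope="session")
def cs_default():
    return DielConstraintSet()


@pytest.fixture(scope="session")
def model_factory(toy_net, env_default, cs_default):
    """Fresh water-coupled diel model with the requested vacuole capacity."""
    def make(capacity="C3", net=None, env=None, cs=None):
        cs = cs or cs_default
        caps = {"C3": cs.vacuole_capacity_c3, "CAM": cs.vacuole_capacity_cam,
                "unlimited": None}
        capacity = caps.get(capacity, capacity)
        model = expand_diel(net or toy_net, env or env_default, cs)
        couple_water_loss(model)
        apply_vacuole_capacity(model, capacity)
        return model
    return make


@pytest.fixture(scope="session")
def c3_pareto(model_factory):
    return pareto_scan(model_factory("C3"), step_pct=10, floor_pct=20,
                       flux_min=False)


@pytest.fixture(scope="session")
def cam_pareto(model_factory):
    return pareto_scan(model_factory("CAM"), step_pct=10, floor_pct=20,
                       flux_min=False)


@pytest.fixture(scope="session")
def unlimited_pareto(model_factory):
    return pareto_scan(model_factory("unlimited"), step_pct=10, floor_pct=20,
                       flux_min=False)


@pytest.fixture(scope="session")
def scenario_solutions(toy_net, env_default, cs_default):
    """The three ICDH variants at a common 80% phloem floor (CAM capacity),
    solved through the full lexicographic stack."""
    ref_model = expand_diel(toy_net, env_default, cs_default)
    couple_water_loss(ref_model)
    apply_vacuole_capacity(ref_model, cs_default.vacuole_capacity_cam)
    p_max = maximize_phloem(ref_model, flux_min=False).phloem_output
    floor = 0.8 * p_max
    out = {"p_max": p_max, "floor": floor}
    for name in ("ICDH_rev", "ICDH_irrev", "ICDH_irrev_Cit_night"):
        cfg = ScenarioConfig.named(name, flux_min=True)
        out[name] = run_scenario(cfg, toy_net, env_default, cs_default,
                                 phloem_floor=floor)
    return out


@pytest.fixture(scope="session")
def unlimited_80(toy_net, env_default, cs_default):
    cfg = ScenarioConfig(vacuole_mode="unlimited", flux_min=True)
    return run_scenario(cfg, toy_net, env_default, cs_default)


def make_mini_network(export_lb=1.0, export_ub=1.0, prod_ub=10.0,
                      tag_phloem=False):
    """Two-reaction single-metabolite network with one storable: a minimal
    instance for worked examples and oracle comparisons. With ``tag_phloem``
    the export reaction carries the phloem role (which also activates the
    day:night export coupling on expansion)."""
    mets = [Metabolite("X_c", "X", "cytosol", n_carbon=1)]
    export_tags = {"exchange"} | ({"PHLOEM_EXPORT"} if tag_phloem else set())
    rxns = [
        Reaction("PROD", {"X_c": 1.0}, 0.0, prod_ub, tags={"exchange"}),
        Reaction("EXPORT", {"X_c": -1.0}, export_lb, export_ub,
                 tags=export_tags),
    ]
    return MetabolicNetwork(mets, rxns, storables=["X_c"])


@pytest.fixture
def mini_net():
    return make_mini_network()
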