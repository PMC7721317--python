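"""YAML configuration: environment, gas-exchange, constraint and tag-pattern
blocks, with defaults matching the package's reference study conditions."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .assembly import DielConstraintSet
from .environment import GasExchangeParams, make_profile
from .network import (DEFAULT_COMPARTMENT_PATTERNS, DEFAULT_TAG_PATTERNS,
                      ToyOptions, build_toy_core, read_sbml)

__all__ = ["default_config", "load_config", "build_from_config"]


def default_config() -> dict:
    return {
        "network": {
            "source": "toy",          # or a path to an SBML file
            "icdh_reversible": True,
            "phloem_sucrose_fraction": 0.8,
        },
        "environment": {
            "n_steps": 24,
            "t_min": 20.0, "t_max": 30.0,
            "rh_min": 0.4, "rh_max": 0.8,
            "i_max": 250.0, "daylength": 12.0,
        },
        "gas": {
            "c_atm": 400.0, "ci_ratio": 0.7,
            "diff_ratio": 1.6, "pressure": 101.325,
        },
        "constraints": {
            "phloem_day_night_ratio": 3.0,
            "nitrate_day_night_ratio": 1.5,
            "maintenance_day_night_ratio": 3.0,
            "maintenance_atp_nadph_ratio": 3.0,
            "rubisco_carb_oxy_ratio": 3.0,
            "co2_uptake_max": 15.0,
            "vacuole_capacity_c3": 0.1,
            "cam_capacity_factor": 3.1,
            "light_compensation": 30.0,
            "maintenance_per_light": 0.008,
        },
        "tags": dict(DEFAULT_TAG_PATTERNS),
        "compartments": dict(DEFAULT_COMPARTMENT_PATTERNS),
    }


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def build_from_config(cfg: dict):
    """Instantiate (network, environment profile, constraint set, gas params)
    from a configuration dictionary."""
    netcfg = cfg.get("network", {})
    source = netcfg.get("source", "toy")
    if source == "toy":
        net = build_toy_core(ToyOptions(
            icdh_reversible=bool(netcfg.get("icdh_reversible", True)),
            phloem_sucrose_fraction=float(
                netcfg.get("phloem_sucrose_fraction", 0.8)),
        ))
    else:
        net = read_sbml(Path(source), tag_patterns=cfg.get("tags"),
                        compartment_patterns=cfg.get("compartments"))
    env = make_profile(**cfg.get("environment", {}))
    cs = DielConstraintSet(**cfg.get("constraints", {}))
    gas = GasExchangeParams(**cfg.get("gas", {}))
    return net, env, cs, gas
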