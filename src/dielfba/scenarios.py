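"""Named model variants, environment grid scans and water-saving metrics.

Scenario axes: reversibility of mitochondrial ICDH (clamping its carboxylating
direction isolates the isocitrate-citrate-Pro-2OG night-fixation cycle),
blocking daytime vacuolar (iso)citrate import (the malate-for-citrate exchange
of CAM phase II), and the vacuolar storage capacity (C3 anatomy, CAM anatomy =
3.1x C3, or unlimited).

Water savings are reported against the C3-anatomy model at 100% productivity
under the same environment. Within a scenario family the phloem floor is
derived from one common reference model so that constraint-relaxation
orderings (water_rev <= water_irrev <= water_irrev,cit_night) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assembly import (DielConstraintSet, DielModel, apply_vacuole_capacity,
                       couple_water_loss, expand_diel)
from .environment import EnvironmentProfile, GasExchangeParams, make_profile
from .network import MetabolicNetwork
from .optimize import (DielSolution, InfeasibleModelError, maximize_phloem,
                       minimize_water)

__all__ = [
    "ScenarioConfig",
    "ScanRecord",
    "build_scenario_model",
    "run_scenario",
    "environment_grid",
    "ci_sensitivity",
    "records_to_frame",
]


@dataclass
class ScenarioConfig:
    """One named model variant.

    ``icdh_mode='irreversible'`` with ``cit_night_only=True`` reproduces the
    ICDH_irrev,Cit_night variant; ``cit_night_only`` blocks vacuolar
    (iso)citrate import during day steps only (export stays open).
    """

    icdh_mode: str = "reversible"
    cit_night_only: bool = False
    vacuole_mode: str = "CAM"          # C3 | CAM | unlimited
    productivity_fraction: float = 80.0
    environment: dict = field(default_factory=dict)
    flux_min: bool = True

    def __post_init__(self):
        if self.icdh_mode not in ("reversible", "irreversible"):
            raise ValueError(f"unknown icdh_mode {self.icdh_mode!r}")
        if self.vacuole_mode not in ("C3", "CAM", "unlimited"):
            raise ValueError(f"unknown vacuole_mode {self.vacuole_mode!r}")
        if not 0 < self.productivity_fraction <= 100:
            raise ValueError("productivity_fraction must lie in (0, 100]")

    @classmethod
    def named(cls, name: str, **kwargs) -> "ScenarioConfig":
        presets = {
            "ICDH_rev": dict(icdh_mode="reversible"),
            "ICDH_irrev": dict(icdh_mode="irreversible"),
            "ICDH_irrev_Cit_night": dict(icdh_mode="irreversible",
                                         cit_night_only=True),
        }
        if name not in presets:
            raise KeyError(f"unknown scenario {name!r}; choose from {list(presets)}")
        return cls(**{**presets[name], **kwargs})


def _capacity_for(mode: str, cs: DielConstraintSet):
    return {"C3": cs.vacuole_capacity_c3,
            "CAM": cs.vacuole_capacity_cam,
            "unlimited": None}[mode]


def build_scenario_model(cfg: ScenarioConfig, net: MetabolicNetwork,
                         env: EnvironmentProfile | None = None,
                         cs: DielConstraintSet | None = None,
                         gas: GasExchangeParams | None = None) -> DielModel:
    """Expand the network and apply the scenario's constraint modifications."""
    cs = cs or DielConstraintSet()
    env = env or make_profile(**cfg.environment)
    for tag in ("ICDH_M",):
        if not net.find_all_by_tag(tag):
            raise ValueError(f"scenario requires a reaction tagged {tag}")
    model = expand_diel(net, env, cs, gas)
    couple_water_loss(model)
    apply_vacuole_capacity(model, _capacity_for(cfg.vacuole_mode, cs))
    icdh = net.find_by_tag("ICDH_M").id
    if cfg.icdh_mode == "irreversible":
        j = net.reaction_index(icdh)
        model.lb[j, :] = np.maximum(model.lb[j, :], 0.0)
    if cfg.cit_night_only:
        vac_cit = [r.id for r in net.find_all_by_tag("vacuolar-transport")
                   if any(net.metabolite(m).compartment == "vacuole"
                          and net.metabolite(m).name in ("citrate", "isocitrate")
                          for m in r.stoichiometry)]
        if not vac_cit:
            raise ValueError("cit_night_only requires vacuolar (iso)citrate "
                             "transporter tags")
        for rid in vac_cit:
            j = net.reaction_index(rid)
            # import direction (into the vacuole) blocked during the day
            for t in model.day_steps:
                model.ub[j, t] = min(model.ub[j, t], 0.0)
    return model


def run_scenario(cfg: ScenarioConfig, net: MetabolicNetwork,
                 env: EnvironmentProfile | None = None,
                 cs: DielConstraintSet | None = None,
                 gas: GasExchangeParams | None = None,
                 phloem_floor: float | None = None) -> DielSolution:
    """Solve a scenario at its productivity fraction via the lexicographic
    stack. ``phloem_floor`` (mol m-2 d-1) overrides the fraction-of-own-max
    floor; pass a common floor when comparing scenario variants."""
    model = build_scenario_model(cfg, net, env, cs, gas)
    if phloem_floor is None:
        p_max = maximize_phloem(model, flux_min=False).phloem_output
        phloem_floor = p_max * cfg.productivity_fraction / 100.0
    return minimize_water(model, phloem_floor, flux_min=cfg.flux_min)


@dataclass
class ScanRecord:
    """One environment-grid cell: water totals and derived saving metrics.

    ``saving_abs/rel`` compare the water-saving (ICDH_rev) CAM model at the
    scan fraction against the C3-anatomy model at 100% productivity;
    ``icdh_abs/rel`` quantify the extra saving contributed by carboxylating
    mitochondrial ICDH (difference between the irreversible and reversible
    variants at the same phloem floor).
    """

    T_max: float
    RH_min: float
    I_max: float
    daylength: float
    water_C3_100: float = float("nan")
    water_rev: float = float("nan")
    water_irrev: float = float("nan")
    status: str = "ok"

    @property
    def saving_abs(self) -> float:
        return self.water_C3_100 - self.water_rev

    @property
    def saving_rel_pct(self) -> float:
        return 100.0 * self.saving_abs / self.water_C3_100

    @property
    def icdh_abs(self) -> float:
        return self.water_irrev - self.water_rev

    @property
    def icdh_rel_pct(self) -> float:
        return 100.0 * self.icdh_abs / self.water_C3_100


#: default grids: light regimes from cloudy to sunny canopies and three
#: photoperiods from short to long days
DEFAULT_LIGHT_REGIMES = (100.0, 250.0, 800.0, 1600.0)
DEFAULT_DAYLENGTHS = (16.0, 12.0, 8.0)
DEFAULT_T_MAX_GRID = tuple(np.arange(10.0, 48.1, 2.0))
DEFAULT_RH_MIN_GRID = tuple(np.arange(0.4, 1.001, 0.1))


def environment_grid(net: MetabolicNetwork,
                     t_max_values=DEFAULT_T_MAX_GRID,
                     rh_min_values=DEFAULT_RH_MIN_GRID,
                     light_day_combos=None,
                     fraction: float = 80.0,
                     cs: DielConstraintSet | None = None,
                     gas: GasExchangeParams | None = None,
                     n_steps: int = 24) -> list:
    """Scan T_max x RH_min cells for each (light, daylength) combination.

    Three solves per cell: the C3-anatomy model at 100% productivity (the
    water-saving reference) and the CAM-anatomy ICDH_rev / ICDH_irrev models
    at ``fraction`` of the reference CAM maximum. T_min and RH_max co-vary
    with the scanned values (T_min = T_max - 10 degC, RH_max = RH_min + 0.4
    capped at 1). Per-cell failures are recorded and the scan continues.
    """
    if light_day_combos is None:
        light_day_combos = [(i, d) for i in DEFAULT_LIGHT_REGIMES
                            for d in DEFAULT_DAYLENGTHS]
    cs = cs or DielConstraintSet()
    records = []
    for i_max, daylength in light_day_combos:
        for t_max in t_max_values:
            for rh_min in rh_min_values:
                rec = ScanRecord(T_max=float(t_max), RH_min=float(rh_min),
                                 I_max=float(i_max), daylength=float(daylength))
                try:
                    env = make_profile(
                        n_steps=n_steps, t_min=t_max - 10.0, t_max=t_max,
                        rh_min=rh_min, rh_max=min(1.0, rh_min + 0.4),
                        i_max=i_max, daylength=daylength)
                    c3 = build_scenario_model(
                        ScenarioConfig(vacuole_mode="C3"), net, env, cs, gas)
                    p_c3 = maximize_phloem(c3, flux_min=False).phloem_output
                    rec.water_C3_100 = minimize_water(
                        c3, p_c3, flux_min=False).water_total
                    rev = build_scenario_model(
                        ScenarioConfig("reversible", vacuole_mode="CAM"),
                        net, env, cs, gas)
                    p_ref = maximize_phloem(rev, flux_min=False).phloem_output
                    floor = p_ref * fraction / 100.0
                    rec.water_rev = minimize_water(
                        rev, floor, flux_min=False).water_total
                    irrev = build_scenario_model(
                        ScenarioConfig("irreversible", vacuole_mode="CAM"),
                        net, env, cs, gas)
                    rec.water_irrev = minimize_water(
                        irrev, floor, flux_min=False).water_total
                except (InfeasibleModelError, ValueError) as exc:
                    rec.status = f"failed: {exc}"
                records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "T_max": r.T_max, "RH_min": r.RH_min, "I_max": r.I_max,
            "daylength": r.daylength, "water_C3_100": r.water_C3_100,
            "water_rev": r.water_rev, "water_irrev": r.water_irrev,
            "saving_abs": r.saving_abs, "saving_rel_pct": r.saving_rel_pct,
            "icdh_abs": r.icdh_abs, "icdh_rel_pct": r.icdh_rel_pct,
            "status": r.status,
        })
    return pd.DataFrame(rows)


def ci_sensitivity(net: MetabolicNetwork, ci_ratios,
                   fraction: float = 80.0,
                   vacuole_mode: str = "CAM",
                   env: EnvironmentProfile | None = None,
                   cs: DielConstraintSet | None = None) -> pd.DataFrame:
    """Predicted water loss at a fixed productivity fraction as a function of
    the internal:atmospheric CO2 ratio.

    The water cost per CO2 scales as 1/(1 - ci_ratio), so water loss is
    monotone increasing in the ratio.
    """
    ci_ratios = list(ci_ratios)
    for c in ci_ratios:
        if not 0.0 < c < 1.0:
            raise ValueError(f"ci_ratio must lie in (0, 1), got {c}")
    cs = cs or DielConstraintSet()
    env = env or make_profile()
    rows = []
    for ci in ci_ratios:
        gas = GasExchangeParams(ci_ratio=ci)
        cfg = ScenarioConfig(vacuole_mode=vacuole_mode,
                             productivity_fraction=fraction, flux_min=False)
        sol = run_scenario(cfg, net, env, cs, gas)
        rows.append({"ci_ratio": ci, "water_total": sol.water_total,
                     "phloem_output": sol.phloem_output})
    return pd.DataFrame(rows)
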