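"""Time expansion of a metabolic network into a cyclic diel model.

``expand_diel`` concatenates N copies of the network (one per time interval of
the 24-h cycle) and couples consecutive copies through non-negative linker
reactions for each storable metabolite; the last interval feeds the first, so
the cycle is closed and every storable is conserved over the day. Per-step
constraints encode the diel physiology: light-bounded photon uptake, Rubisco
active only in daylight at a fixed carboxylation:oxygenation ratio, day:night
ratio couplings for phloem export, nitrate uptake and maintenance, a cap on
stomatal CO2 uptake, and an optional vacuolar storage capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentProfile, GasExchangeParams, water_per_co2
from .network import MetabolicNetwork, REQUIRED_ROLES

__all__ = [
    "DielConstraintSet",
    "DielModel",
    "expand_diel",
    "apply_vacuole_capacity",
    "couple_water_loss",
]


@dataclass
class DielConstraintSet:
    """Diel physiological constraints.

    Ratios are per-hour day:night rates; the vacuolar storage capacity is the
    total amount of solutes (mol m-2 leaf) that may be carried across any step
    boundary in the vacuole. A CAM leaf has ``cam_capacity_factor`` times the
    C3 capacity (morphological estimate); ``None``/inf capacity removes the
    constraint entirely.
    """

    phloem_day_night_ratio: float = 3.0
    nitrate_day_night_ratio: float = 1.5  # 3:2
    maintenance_day_night_ratio: float = 3.0
    maintenance_atp_nadph_ratio: float = 3.0
    rubisco_carb_oxy_ratio: float = 3.0
    co2_uptake_max: float = 15.0  # umol m-2 s-1
    vacuole_capacity_c3: float = 0.1  # mol m-2 leaf (see scripts/calibrate_vacuole.py)
    cam_capacity_factor: float = 3.1
    light_compensation: float = 30.0  # umol m-2 s-1
    maintenance_per_light: float = 0.008  # ATP maintenance flux per unit mean day light
    #: per-storable capacity weights (mol capacity consumed per mol stored);
    #: uniform by default, config-exposed because osmotic weighting is unknown.
    capacity_weights: dict = field(default_factory=dict)
    count_nitrate_in_capacity: bool = True

    def __post_init__(self):
        for name in ("phloem_day_night_ratio", "nitrate_day_night_ratio",
                     "maintenance_day_night_ratio", "maintenance_atp_nadph_ratio",
                     "rubisco_carb_oxy_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vacuole_capacity_c3 < 0:
            raise ValueError("vacuole capacity must be non-negative")

    @property
    def vacuole_capacity_cam(self) -> float:
        return self.cam_capacity_factor * self.vacuole_capacity_c3


class DielModel:
    """Time-expanded cyclic diel model.

    Holds the base network, per-step flux bounds (reactions x steps arrays),
    linker definitions, linear coupling rows, and the gas-exchange coupling.
    The optimization module compiles this declarative structure into LP/QP
    matrices. Linker fluxes are indexed (storable, t) and transfer the amount
    accumulated during step t to step t+1 (mod N): a linker flux of
    1 umol m-2 s-1 over a 1-h step carries 3.6 mmol m-2 into the next step.
    """

    def __init__(self, base: MetabolicNetwork, env: EnvironmentProfile,
                 cs: DielConstraintSet, gas: GasExchangeParams | None = None):
        self.base = base
        self.env = env
        self.cs = cs
        self.gas = gas or GasExchangeParams()
        self.n_steps = env.n_steps
        R = len(base.reactions)
        bounds = base.bounds
        self.lb = np.tile(bounds[:, :1], (1, self.n_steps))
        self.ub = np.tile(bounds[:, 1:], (1, self.n_steps))
        self.storables = list(base.storables)
        self.linker_ub = 10000.0
        #: list of ([(rxn_id, step, coeff), ...], rhs) equality rows
        self.coupling_rows: list = []
        self.vacuole_capacity: float | None = None
        self.water_coupled: bool = False
        self.water_coeffs: np.ndarray | None = None

    # -- helpers ---------------------------------------------------------
    @property
    def day_steps(self) -> np.ndarray:
        return np.flatnonzero(self.env.is_day)

    @property
    def night_steps(self) -> np.ndarray:
        return np.flatnonzero(~self.env.is_day)

    @property
    def vacuolar_storables(self) -> list:
        out = []
        for mid in self.storables:
            met = self.base.metabolite(mid)
            if met.compartment != "vacuole":
                continue
            if not self.cs.count_nitrate_in_capacity and not met.carries_carbon:
                continue
            out.append(mid)
        return out

    def set_bounds(self, rxn_id: str, lb=None, ub=None, steps=None) -> None:
        j = self.base.reaction_index(rxn_id)
        steps = range(self.n_steps) if steps is None else np.atleast_1d(steps)
        for t in steps:
            if lb is not None:
                self.lb[j, t] = lb
            if ub is not None:
                self.ub[j, t] = ub
            if self.lb[j, t] > self.ub[j, t]:
                raise ValueError(
                    f"bounds crossed for {rxn_id} at step {t}: "
                    f"[{self.lb[j, t]}, {self.ub[j, t]}]"
                )

    def copy(self) -> "DielModel":
        other = DielModel(self.base, self.env, self.cs, self.gas)
        other.lb = self.lb.copy()
        other.ub = self.ub.copy()
        other.coupling_rows = [([tuple(e) for e in row], rhs)
                               for row, rhs in self.coupling_rows]
        other.vacuole_capacity = self.vacuole_capacity
        other.water_coupled = self.water_coupled
        other.water_coeffs = (None if self.water_coeffs is None
                              else self.water_coeffs.copy())
        other.linker_ub = self.linker_ub
        return other

    def bounds_table(self):
        """Audit dump: one row per (reaction, step) with effective bounds."""
        import pandas as pd

        rows = []
        for j, rxn in enumerate(self.base.reactions):
            for t in range(self.n_steps):
                rows.append((rxn.id, t, self.lb[j, t], self.ub[j, t]))
        return pd.DataFrame(rows, columns=["reaction_id", "step", "lb", "ub"])


def _shared_rate_rows(rxn_id: str, day: np.ndarray, night: np.ndarray,
                      day_night_ratio: float) -> list:
    """Equality rows forcing one per-hour rate across all day steps, another
    across all night steps, in the given day:night ratio."""
    rows = []
    for steps in (day, night):
        for t in steps[1:]:
            rows.append(([(rxn_id, int(steps[0]), 1.0), (rxn_id, int(t), -1.0)], 0.0))
    if len(day) and len(night):
        rows.append((
            [(rxn_id, int(day[0]), 1.0), (rxn_id, int(night[0]), -day_night_ratio)],
            0.0,
        ))
    return rows


def expand_diel(net: MetabolicNetwork, env: EnvironmentProfile,
                cs: DielConstraintSet | None = None,
                gas: GasExchangeParams | None = None,
                strict_tags: bool = True) -> DielModel:
    """Expand a network into the cyclic diel model with all per-step
    constraints applied.

    With ``strict_tags`` (default) every required role tag must resolve;
    ``strict_tags=False`` applies only the constraints whose tags exist,
    which is useful for reduced test instances.
    """
    cs = cs or DielConstraintSet()
    N = env.n_steps
    if 24 % N != 0 and abs(N * env.step_hours - 24.0) > 1e-9:
        raise ValueError(f"number of steps ({N}) must divide 24 h")
    if strict_tags:
        net.validate_tags(REQUIRED_ROLES)

    model = DielModel(net, env, cs, gas)
    day, night = model.day_steps, model.night_steps

    def tag_id(tag):
        try:
            return net.find_by_tag(tag).id
        except KeyError:
            if strict_tags:
                raise
            return None

    light = tag_id("LIGHT_UPTAKE")
    if light is not None:
        for t in range(N):
            model.set_bounds(light, ub=float(env.I[t]), steps=t)

    carb, oxy = tag_id("RUBISCO_CARB"), tag_id("RUBISCO_OXY")
    if carb is not None and oxy is not None:
        # Rubisco only active in daylight; fixed carboxylation:oxygenation
        for t in night:
            model.set_bounds(carb, lb=0.0, ub=0.0, steps=int(t))
            model.set_bounds(oxy, lb=0.0, ub=0.0, steps=int(t))
        for t in day:
            model.coupling_rows.append((
                [(carb, int(t), 1.0), (oxy, int(t), -cs.rubisco_carb_oxy_ratio)],
                0.0,
            ))

    co2_up = tag_id("CO2_UPTAKE")
    if co2_up is not None:
        j = net.reaction_index(co2_up)
        model.ub[j, :] = np.minimum(model.ub[j, :], cs.co2_uptake_max)
        model.lb[j, :] = np.maximum(model.lb[j, :], 0.0)

    phloem = tag_id("PHLOEM_EXPORT")
    if phloem is not None:
        model.coupling_rows += _shared_rate_rows(
            phloem, day, night, cs.phloem_day_night_ratio)

    nitrate = tag_id("NITRATE_UPTAKE")
    if nitrate is not None:
        model.coupling_rows += _shared_rate_rows(
            nitrate, day, night, cs.nitrate_day_night_ratio)

    atp_m, nadph_m = tag_id("ATP_MAINT"), tag_id("NADPH_MAINT")
    if atp_m is not None and nadph_m is not None:
        mean_day_light = float(np.mean(env.I[day])) if len(day) else 0.0
        atp_day = cs.maintenance_per_light * mean_day_light
        atp_night = atp_day / cs.maintenance_day_night_ratio
        for t in range(N):
            atp = atp_day if env.is_day[t] else atp_night
            nadph = atp / cs.maintenance_atp_nadph_ratio
            model.set_bounds(atp_m, lb=atp, ub=atp, steps=t)
            model.set_bounds(nadph_m, lb=nadph, ub=nadph, steps=t)

    return model


def apply_vacuole_capacity(model: DielModel, capacity) -> DielModel:
    """Constrain the total vacuolar solute amount carried across every step
    boundary to ``capacity`` (mol m-2 leaf).

    Starch (plastid) is never counted: it accumulates freely. ``capacity`` of
    ``None`` or +inf removes the constraint (the unlimited-storage variant);
    0 forces every vacuolar linker to zero while leaving starch untouched.
    """
    if capacity is not None and capacity < 0:
        raise ValueError("vacuole capacity must be non-negative (or None/inf)")
    if capacity is not None and math.isinf(capacity):
        capacity = None
    model.vacuole_capacity = capacity
    return model


def couple_water_loss(model: DielModel) -> DielModel:
    """Attach the gas-exchange coupling: per-step auxiliary water-loss
    variables tied to CO2 uptake and a daily total usable as an objective."""
    model.base.find_by_tag("CO2_UPTAKE")  # raises if the role is missing
    model.water_coeffs = np.asarray(
        water_per_co2(model.env.T, model.env.RH, model.gas), dtype=float)
    model.water_coupled = True
    return model
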