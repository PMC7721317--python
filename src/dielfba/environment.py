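"""Diel environment profiles and the stomatal gas-exchange model.

Temperature and relative humidity follow skewed sine curves over the 24-h
cycle; light follows a truncated Gaussian centred on solar noon. A linearized
stomatal diffusion model converts the metabolic CO2 demand into transpirational
water loss: water vapour and CO2 diffuse through the same stomatal pore, so the
molar water cost of one mole of CO2 taken up is the ratio of the two diffusion
gradients scaled by the H2O:CO2 diffusivity ratio.

Units: temperature in deg C, relative humidity as a fraction in [0, 1],
photon flux and metabolic fluxes in umol m-2 s-1, pressures in kPa,
daily totals in mol m-2 d-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EnvironmentProfile",
    "GasExchangeParams",
    "buck_saturation_vapor_pressure",
    "skewed_diel_curve",
    "light_curve",
    "make_profile",
    "water_per_co2",
    "total_water_loss",
]

#: Default light compensation point (umol m-2 s-1); intensities below it count
#: as darkness.
LIGHT_COMPENSATION = 30.0


def buck_saturation_vapor_pressure(T):
    """Saturation vapour pressure of water in kPa (Buck equation).

    Accurate to better than 0.1% over 0-50 degC, which covers every diel
    temperature regime scanned here.
    """
    T = np.asarray(T, dtype=float)
    return 0.61121 * np.exp((18.678 - T / 234.5) * (T / (257.14 + T)))


@dataclass
class GasExchangeParams:
    """Parameters of the linearized stomatal diffusion model.

    c_atm : atmospheric CO2 mole fraction (umol mol-1).
    ci_ratio : internal:atmospheric CO2 concentration ratio; the CO2 gradient
        driving uptake is ``c_atm * (1 - ci_ratio)``.
    diff_ratio : H2O:CO2 diffusivity ratio through the stomatal pore.
    pressure : atmospheric pressure (kPa).
    esat : saturation vapour pressure function, kPa as a function of degC.
    """

    c_atm: float = 400.0
    ci_ratio: float = 0.7
    diff_ratio: float = 1.6
    pressure: float = 101.325
    esat: Callable = field(default=buck_saturation_vapor_pressure, repr=False)

    def __post_init__(self):
        if not 0.0 < self.ci_ratio < 1.0:
            raise ValueError(f"ci_ratio must lie in (0, 1), got {self.ci_ratio}")
        if self.diff_ratio <= 0:
            raise ValueError("diff_ratio must be positive")
        if self.c_atm <= 0 or self.pressure <= 0:
            raise ValueError("c_atm and pressure must be positive")


def skewed_diel_curve(t, v_min, v_max, t_min=5.0, t_max=15.0, skew=1.0):
    """Evaluate a 24-h periodic skewed sine curve.

    The curve attains ``v_min`` exactly at hour ``t_min`` and ``v_max`` exactly
    at hour ``t_max`` and is monotone on each arc between the two extremes.
    It is implemented as a sine of a phase-warped clock: the interval from
    ``t_min`` to ``t_max`` (forward in time, mod 24) is mapped linearly onto
    the rising half-wave [-pi/2, pi/2], the remainder onto the falling
    half-wave. ``skew`` != 1 warps position within each arc (u -> u**skew),
    which skews the shoulders while keeping the anchors fixed.
    """
    if v_min > v_max:
        raise ValueError(f"v_min ({v_min}) must not exceed v_max ({v_max})")
    if skew <= 0:
        raise ValueError("skew must be positive")
    t = np.asarray(t, dtype=float)
    if v_min == v_max:
        return np.broadcast_to(np.float64(v_min), t.shape).copy() if t.shape else float(v_min)
    t_min = t_min % 24.0
    t_max = t_max % 24.0
    if t_min == t_max:
        raise ValueError("t_min and t_max must be distinct hours")
    d_up = (t_max - t_min) % 24.0  # duration of the rising arc
    d_down = 24.0 - d_up
    dt = (t - t_min) % 24.0
    rising = dt <= d_up
    u = np.where(rising, dt / d_up, (dt - d_up) / d_down)
    u = u ** skew
    phase = np.where(rising, -np.pi / 2 + np.pi * u, np.pi / 2 + np.pi * u)
    value = v_min + (v_max - v_min) * (np.sin(phase) + 1.0) / 2.0
    return float(value) if value.ndim == 0 else value


def light_curve(t, i_max=250.0, daylength=12.0, compensation=LIGHT_COMPENSATION,
                noon=12.0):
    """Photon flux at hour ``t``: Gaussian around solar noon, clamped below the
    light compensation point.

    The Gaussian width is chosen so that intensity equals ``compensation``
    exactly at ``noon +/- daylength/2``; everything below the compensation
    point is darkness (set to 0).
    """
    if not 0.0 < daylength < 24.0:
        raise ValueError("daylength must lie in (0, 24) hours")
    if i_max <= compensation:
        raise ValueError(
            f"i_max ({i_max}) must exceed the compensation point ({compensation}); "
            "otherwise no daytime exists"
        )
    t = np.asarray(t, dtype=float)
    sigma = (daylength / 2.0) / np.sqrt(2.0 * np.log(i_max / compensation))
    # hour distance to noon on the 24-h circle
    dt = np.abs((t - noon + 12.0) % 24.0 - 12.0)
    intensity = i_max * np.exp(-(dt ** 2) / (2.0 * sigma ** 2))
    # tolerance keeps the exact window edges (I == compensation) lit despite
    # floating-point rounding of the Gaussian
    intensity = np.where(intensity < compensation - 1e-9, 0.0, intensity)
    return float(intensity) if intensity.ndim == 0 else intensity


@dataclass
class EnvironmentProfile:
    """Per-time-step environment over one 24-h cycle.

    Arrays are sampled at step midpoints. ``is_day[t]`` is true exactly when
    the light intensity reaches the compensation point.
    """

    n_steps: int
    step_hours: float
    T: np.ndarray
    RH: np.ndarray
    I: np.ndarray
    is_day: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.RH = np.asarray(self.RH, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.is_day = np.asarray(self.is_day, dtype=bool)
        if abs(self.n_steps * self.step_hours - 24.0) > 1e-9:
            raise ValueError("n_steps * step_hours must equal 24 h")
        for name in ("T", "RH", "I", "is_day"):
            if len(getattr(self, name)) != self.n_steps:
                raise ValueError(f"{name} must have length n_steps={self.n_steps}")
        if np.any(self.RH < 0) or np.any(self.RH > 1):
            raise ValueError("RH must lie in [0, 1]")
        if np.any(self.I < 0):
            raise ValueError("light intensity must be non-negative")

    @property
    def step_seconds(self) -> float:
        return self.step_hours * 3600.0

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.n_steps) + 0.5) * self.step_hours

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "hour": self.midpoints,
                "T": self.T,
                "RH": self.RH,
                "I": self.I,
                "is_day": self.is_day,
            }
        )


def make_profile(
    n_steps: int = 24,
    t_min: float = 20.0,
    t_max: float = 30.0,
    rh_min: float = 0.4,
    rh_max: float = 0.8,
    i_max: float = 250.0,
    daylength: float = 12.0,
    compensation: float = LIGHT_COMPENSATION,
    noon: float = 12.0,
    t_max_hour: float = 15.0,
    skew: float = 0.5,
) -> EnvironmentProfile:
    """Build a diel profile from summary climate parameters.

    Temperature peaks mid-afternoon (``t_max_hour``, default 15:00) and is
    lowest one hour before sunrise; relative humidity is anti-phased with
    temperature (most humid before dawn, driest mid-afternoon). The default
    ``skew`` of 0.5 reproduces the asymmetry of measured diel temperature
    records: rapid warming after sunrise, slow cooling towards the pre-dawn
    minimum. A symmetric sine (``skew=1``) underestimates early-morning
    temperatures.
    """
    if 24.0 % n_steps != 0 and abs(round(24.0 / n_steps) - 24.0 / n_steps) > 1e-9:
        raise ValueError("n_steps must divide 24")
    step_hours = 24.0 / n_steps
    hours = (np.arange(n_steps) + 0.5) * step_hours
    sunrise = noon - daylength / 2.0
    t_min_hour = (sunrise - 1.0) % 24.0
    T = skewed_diel_curve(hours, t_min, t_max, t_min_hour, t_max_hour, skew)
    RH = skewed_diel_curve(hours, rh_min, rh_max, t_max_hour, t_min_hour, skew)
    intensity = light_curve(hours, i_max, daylength, compensation, noon)
    is_day = intensity >= compensation
    return EnvironmentProfile(
        n_steps=n_steps,
        step_hours=step_hours,
        T=np.atleast_1d(T),
        RH=np.atleast_1d(RH),
        I=np.atleast_1d(intensity),
        is_day=np.atleast_1d(is_day),
    )


def water_per_co2(T, RH, params: GasExchangeParams | None = None):
    """Molar water cost of CO2 uptake (mol H2O per mol CO2).

    r = diff_ratio * (e_sat(T)/P) * (1 - RH) / (c_atm_frac * (1 - ci_ratio))

    where ``c_atm_frac`` is the atmospheric CO2 mole fraction. The vapour
    gradient assumes saturation inside the leaf; the CO2 gradient is the
    atmospheric mole fraction times (1 - ci_ratio).
    """
    params = params or GasExchangeParams()
    RH = np.asarray(RH, dtype=float)
    if np.any(RH > 1.0) or np.any(RH < 0.0):
        raise ValueError("RH must lie in [0, 1]")
    vapour_gradient = (params.esat(T) / params.pressure) * (1.0 - RH)
    co2_gradient = params.c_atm * 1e-6 * (1.0 - params.ci_ratio)
    r = params.diff_ratio * vapour_gradient / co2_gradient
    return float(r) if np.ndim(r) == 0 else r


def total_water_loss(
    co2_uptake: Sequence[float],
    env: EnvironmentProfile,
    params: GasExchangeParams | None = None,
) -> float:
    """Daily transpirational water loss (mol m-2 d-1) for a per-step CO2
    uptake profile (umol m-2 s-1).

    Linear in the uptake vector; net CO2 efflux carries no transpiration cost
    and must be modelled as a separate reaction, so negative uptake is an
    error here.
    """
    uptake = np.asarray(co2_uptake, dtype=float)
    if len(uptake) != env.n_steps:
        raise ValueError("uptake profile length must equal env.n_steps")
    if np.any(uptake < 0):
        raise ValueError("CO2 uptake must be non-negative (efflux is a separate reaction)")
    r = water_per_co2(env.T, env.RH, params)
    return float(np.sum(r * uptake * env.step_seconds) * 1e-6)
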