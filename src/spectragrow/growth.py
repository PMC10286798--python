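"""Two-state dynamic growth model for lettuce dry mass.

The plant state is the pair (x_nsdm, x_sdm): non-structural dry mass (starch,
glucose and other mobilizable carbohydrates) and structural dry mass, both in
g m⁻².  Gross canopy photosynthesis feeds the non-structural pool; a
temperature-sensitive growth rate converts non-structural into structural
material with a conversion loss, and maintenance respiration drains the pool
in proportion to structural mass:

    dx_nsdm/dt = c_α f_phot − r_gr x_sdm − f_resp − ((1−c_β)/c_β) r_gr x_sdm
    dx_sdm/dt  = r_gr x_sdm

Photosynthesis follows a rectangular-hyperbola light/CO₂ response limited by
a canopy CO₂ conductance (boundary layer, stomatal and carboxylation
conductances in series) and attenuated by canopy closure through a Beer-law
term in structural mass.  Temperature enters through Q10 laws for growth
rate, respiration and the CO₂ compensation point, and through an empirical
parabola for carboxylation conductance valid between 5 and 40 °C.

The light input I is the spectral irradiance integrated over 400-750 nm
(PAR plus far-red, W m⁻²).  The quantum use efficiency c_ε (g CO₂ fixed per
joule) is the one coefficient treated as spectrum-dependent; everything else
is a fixed cultivar/environment coefficient (see :class:`GrowthParameters`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigError, IntegrationError, ModelValidityWarning, OutOfRangeError

__all__ = [
    "GrowthParameters",
    "PlantState",
    "EnvironmentSchedule",
    "Trajectory",
    "co2_compensation",
    "light_use_efficiency",
    "carboxylation_conductance",
    "canopy_conductance",
    "max_gross_photosynthesis",
    "gross_photosynthesis",
    "growth_rate",
    "maintenance_respiration",
    "state_derivatives",
    "simulate",
]


@dataclass(frozen=True)
class GrowthParameters:
    """Model coefficients for lettuce cultivation.

    Defaults are the literature values for soil-grown lettuce; use
    ``dataclasses.replace(params, c_tau=0.14)`` for hydroponics.

    Attributes
    ----------
    c_alpha : float
        CO₂ → CH₂O conversion (molecular weight ratio), dimensionless.
    c_beta : float
        Yield factor: fraction of mobilized carbohydrate retained when
        non-structural material is converted to structure.
    c_gr_max : float
        Saturation growth rate at 20 °C, s⁻¹.
    c_gamma : float
        Growth-rate saturation coefficient, dimensionless.
    c_q10_gr : float
        Q10 of the growth rate.
    c_resp_sht, c_resp_rt : float
        Shoot / root maintenance respiration coefficients at 25 °C, s⁻¹.
    c_q10_resp : float
        Q10 of maintenance respiration.
    c_tau : float
        Root fraction of total dry mass (0.15 soil, 0.14 hydroponic).
    c_k : float
        Canopy extinction coefficient.
    c_lar : float
        Structural leaf area ratio, m² g⁻¹.
    c_omega : float
        CO₂ density conversion, g m⁻³ per ppm (µmol mol⁻¹) of concentration.
    c_big_gamma : float
        CO₂ compensation point at 20 °C, ppm.
    c_q10_big_gamma : float
        Q10 of the CO₂ compensation point.
    c_eps : float
        Default quantum use efficiency, g CO₂ per J of light energy.
    g_bnd, g_stm : float
        Boundary-layer and stomatal conductances, m s⁻¹.
    plant_density : float
        Plants per m², used only to convert the model's per-area masses to
        per-plant masses.  Default 1, i.e. model-native g m⁻².
    """

    c_alpha: float = 0.68
    c_beta: float = 0.8
    c_gr_max: float = 5e-6
    c_gamma: float = 1.0
    c_q10_gr: float = 1.6
    c_resp_sht: float = 3.47e-7
    c_resp_rt: float = 1.16e-7
    c_q10_resp: float = 2.0
    c_tau: float = 0.15
    c_k: float = 0.9
    c_lar: float = 75e-3
    c_omega: float = 1.83e-3
    c_big_gamma: float = 40.0
    c_q10_big_gamma: float = 2.0
    c_eps: float = 17.0e-6
    g_bnd: float = 0.007
    g_stm: float = 0.005
    plant_density: float = 1.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if not 0 < self.c_beta < 1:
            raise ValueError("c_beta must lie in (0, 1)")
        if not 0 < self.c_tau < 1:
            raise ValueError("c_tau must lie in (0, 1)")

    def with_(self, **kwargs) -> "GrowthParameters":
        return replace(self, **kwargs)


DEFAULT_PARAMETERS = GrowthParameters()


@dataclass(frozen=True)
class PlantState:
    """Non-structural and structural dry mass, g m⁻²."""

    x_nsdm: float
    x_sdm: float

    def __post_init__(self):
        if not (math.isfinite(self.x_nsdm) and math.isfinite(self.x_sdm)):
            raise ValueError("plant state must be finite")
        if self.x_nsdm < 0 or self.x_sdm < 0:
            warnings.warn(
                "negative dry mass: outside the model's validity region",
                ModelValidityWarning,
                stacklevel=2,
            )

    @property
    def total(self) -> float:
        return self.x_nsdm + self.x_sdm


def co2_compensation(temperature_c: float, params: GrowthParameters = DEFAULT_PARAMETERS) -> float:
    """CO₂ compensation point Γ (ppm) at canopy temperature ``temperature_c``.

    Q10 law anchored at 40 ppm at 20 °C: Γ = c_Γ · c_Q10,Γ^((T−20)/10).
    """
    return params.c_big_gamma * params.c_q10_big_gamma ** ((temperature_c - 20.0) / 10.0)


def light_use_efficiency(c_eps: float, co2_ppm: float, big_gamma_ppm: float) -> float:
    """Light-use efficiency ε (g J⁻¹): c_ε attenuated by photorespiration.

    ε = c_ε (C − Γ) / (C + 2Γ).  Approaches c_ε as Γ → 0 and zero at the
    compensation point.
    """
    denom = co2_ppm + 2.0 * big_gamma_ppm
    if denom <= 0.0:
        raise ValueError("C_CO2 + 2*Gamma must be positive")
    return c_eps * (co2_ppm - big_gamma_ppm) / denom


def carboxylation_conductance(temperature_c: float) -> float:
    """Carboxylation conductance g_car (m s⁻¹), empirical parabola in T.

    g_car = −1.32×10⁻⁵ T² + 5.94×10⁻⁴ T − 2.64×10⁻³, valid for 5 < T < 40 °C
    (the parabola's roots); outside that range the correlation would return a
    non-positive conductance, so an :class:`OutOfRangeError` is raised.
    """
    g = -1.32e-5 * temperature_c**2 + 5.94e-4 * temperature_c - 2.64e-3
    if g <= 0.0:
        raise OutOfRangeError(
            f"carboxylation conductance correlation invalid at T={temperature_c:g} degC "
            "(valid strictly between 5 and 40 degC)"
        )
    return g


def canopy_conductance(g_bnd: float, g_stm: float, g_car: float) -> float:
    """Series combination of boundary-layer, stomatal and carboxylation
    conductances: 1/g = 1/g_bnd + 1/g_stm + 1/g_car."""
    for g in (g_bnd, g_stm, g_car):
        if g <= 0.0:
            raise ValueError("conductances must be positive")
    return 1.0 / (1.0 / g_bnd + 1.0 / g_stm + 1.0 / g_car)


def max_gross_photosynthesis(
    eps: float,
    irradiance: float,
    g_co2: float,
    co2_ppm: float,
    big_gamma_ppm: float,
    params: GrowthParameters = DEFAULT_PARAMETERS,
) -> float:
    """Closed-canopy gross assimilation rate f_phot,max (g m⁻² s⁻¹).

    Rectangular hyperbola between the light-limited rate εI and the
    CO₂-diffusion-limited rate g_CO₂ · c_ω · (C − Γ).  Returns 0 (with a
    warning) when CO₂ is at or below the compensation point.
    """
    if co2_ppm <= big_gamma_ppm:
        warnings.warn(
            "CO2 at or below compensation point: photosynthesis suppressed",
            ModelValidityWarning,
            stacklevel=2,
        )
        return 0.0
    light_term = eps * irradiance
    co2_term = g_co2 * params.c_omega * (co2_ppm - big_gamma_ppm)
    denom = light_term + co2_term
    if denom <= 0.0:
        return 0.0
    return light_term * co2_term / denom


def gross_photosynthesis(
    x_sdm: float, f_phot_max: float, params: GrowthParameters = DEFAULT_PARAMETERS
) -> float:
    """Canopy gross photosynthesis f_phot (g m⁻² s⁻¹).

    Beer-law canopy closure in structural mass:
    f_phot = (1 − exp(−c_K c_lar (1−c_τ) x_sdm)) · f_phot,max.
    """
    if x_sdm < 0:
        raise ValueError("structural dry mass must be non-negative")
    return -math.expm1(-params.c_k * params.c_lar * (1.0 - params.c_tau) * x_sdm) * f_phot_max


def growth_rate(
    temperature_c: float,
    x_nsdm: float,
    x_sdm: float,
    params: GrowthParameters = DEFAULT_PARAMETERS,
) -> float:
    """Specific growth rate r_gr (s⁻¹) of structural material.

    Saturates in the non-structural fraction and scales with a Q10 law:
    r_gr = c_gr,max · x_nsdm / (c_γ x_sdm + x_nsdm) · c_Q10,gr^((T−20)/10).
    """
    denom = params.c_gamma * x_sdm + x_nsdm
    if denom <= 0.0:
        raise ValueError("c_gamma*x_sdm + x_nsdm must be positive")
    return (
        params.c_gr_max
        * (x_nsdm / denom)
        * params.c_q10_gr ** ((temperature_c - 20.0) / 10.0)
    )


def maintenance_respiration(
    temperature_c: float, x_sdm: float, params: GrowthParameters = DEFAULT_PARAMETERS
) -> float:
    """Maintenance respiration f_resp (g m⁻² s⁻¹).

    Shoot and root coefficients weighted by the root fraction c_τ, applied to
    structural mass with a Q10 law anchored at 25 °C.
    """
    if x_sdm < 0:
        raise ValueError("structural dry mass must be non-negative")
    base = params.c_resp_sht * (1.0 - params.c_tau) + params.c_resp_rt * params.c_tau
    return base * x_sdm * params.c_q10_resp ** ((temperature_c - 25.0) / 10.0)


def state_derivatives(
    x_nsdm: float,
    x_sdm: float,
    temperature_c: float,
    co2_ppm: float,
    irradiance: float,
    c_eps: float | None = None,
    params: GrowthParameters = DEFAULT_PARAMETERS,
) -> tuple[float, float]:
    """Time derivatives (dx_nsdm/dt, dx_sdm/dt) in g m⁻² s⁻¹.

    Composes the pointwise physiology: photosynthesis gains enter the
    non-structural pool scaled by c_α; growth transfers r_gr·x_sdm into
    structure with an extra (1−c_β)/c_β conversion loss; respiration drains
    the pool.
    """
    if c_eps is None:
        c_eps = params.c_eps
    big_gamma = co2_compensation(temperature_c, params)
    eps = light_use_efficiency(c_eps, co2_ppm, big_gamma)
    g_co2 = canopy_conductance(
        params.g_bnd, params.g_stm, carboxylation_conductance(temperature_c)
    )
    f_max = max_gross_photosynthesis(eps, irradiance, g_co2, co2_ppm, big_gamma, params)
    f_phot = gross_photosynthesis(x_sdm, f_max, params)
    f_resp = maintenance_respiration(temperature_c, x_sdm, params)
    if x_nsdm <= 0.0 and x_sdm <= 0.0:
        r_gr = 0.0
    else:
        r_gr = growth_rate(temperature_c, x_nsdm, x_sdm, params)
    growth_flux = r_gr * x_sdm
    d_nsdm = (
        params.c_alpha * f_phot
        - growth_flux
        - f_resp
        - (1.0 - params.c_beta) / params.c_beta * growth_flux
    )
    return d_nsdm, growth_flux


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant environmental forcing over [0, duration] seconds.

    ``edges`` has length n+1 (starting at 0); segment i spans
    ``[edges[i], edges[i+1])`` with temperature ``temperature_c[i]`` (°C),
    CO₂ ``co2_ppm[i]`` (ppm) and irradiance ``irradiance_w_m2[i]`` (W m⁻²,
    integrated 400-750 nm; 0 during the dark period).
    """

    edges: np.ndarray
    temperature_c: np.ndarray
    co2_ppm: np.ndarray
    irradiance_w_m2: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        t = np.asarray(self.temperature_c, dtype=float)
        c = np.asarray(self.co2_ppm, dtype=float)
        i = np.asarray(self.irradiance_w_m2, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ConfigError("schedule needs at least one segment")
        if edges[0] != 0.0:
            raise ConfigError("schedule must start at t=0")
        if np.any(np.diff(edges) <= 0):
            raise ConfigError("segment edges must be strictly increasing")
        n = edges.size - 1
        if not (t.shape == c.shape == i.shape == (n,)):
            raise ConfigError("per-segment arrays must match the number of segments")
        if np.any(i < 0):
            raise ConfigError("irradiance must be non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "co2_ppm", c)
        object.__setattr__(self, "irradiance_w_m2", i)

    @property
    def duration(self) -> float:
        return float(self.edges[-1])

    @property
    def n_segments(self) -> int:
        return self.edges.size - 1

    def segment_index(self, t: float) -> int:
        idx = int(np.searchsorted(self.edges, t, side="right") - 1)
        return min(max(idx, 0), self.n_segments - 1)

    def values_at(self, t: float) -> tuple[float, float, float]:
        """(temperature, CO₂, irradiance) at time ``t`` seconds."""
        i = self.segment_index(t)
        return (
            float(self.temperature_c[i]),
            float(self.co2_ppm[i]),
            float(self.irradiance_w_m2[i]),
        )

    def segments(self):
        for i in range(self.n_segments):
            yield (
                float(self.edges[i]),
                float(self.edges[i + 1]),
                float(self.temperature_c[i]),
                float(self.co2_ppm[i]),
                float(self.irradiance_w_m2[i]),
            )

    def truncated(self, duration_s: float) -> "EnvironmentSchedule":
        """Schedule restricted to [0, duration_s]."""
        if not 0 < duration_s <= self.duration:
            raise ConfigError("truncation time must lie in (0, duration]")
        k = int(np.searchsorted(self.edges, duration_s, side="left"))
        edges = np.concatenate([self.edges[:k], [duration_s]])
        n = edges.size - 1
        return EnvironmentSchedule(
            edges, self.temperature_c[:n], self.co2_ppm[:n], self.irradiance_w_m2[:n]
        )

    def repeated_to(self, duration_s: float) -> "EnvironmentSchedule":
        """Tile the schedule cyclically to cover at least ``duration_s``."""
        if duration_s <= self.duration:
            return self.truncated(duration_s)
        reps = int(np.ceil(duration_s / self.duration))
        edges = [self.edges]
        for r in range(1, reps):
            edges.append(self.edges[1:] + r * self.duration)
        full = EnvironmentSchedule(
            np.concatenate(edges),
            np.tile(self.temperature_c, reps),
            np.tile(self.co2_ppm, reps),
            np.tile(self.irradiance_w_m2, reps),
        )
        return full.truncated(duration_s)

    @classmethod
    def from_segments(cls, segments: Sequence[dict]) -> "EnvironmentSchedule":
        """Build from dicts with keys t_start_h, t_end_h, T_C, CO2_ppm, I_W_m2."""
        if not segments:
            raise ConfigError("empty segment list")
        required = {"t_start_h", "t_end_h", "T_C", "CO2_ppm", "I_W_m2"}
        edges = [float(segments[0]["t_start_h"]) * 3600.0]
        temps, co2s, irrs = [], [], []
        for seg in segments:
            missing = required - set(seg)
            if missing:
                raise ConfigError(f"segment missing fields: {sorted(missing)}")
            start, end = float(seg["t_start_h"]) * 3600.0, float(seg["t_end_h"]) * 3600.0
            if not np.isclose(start, edges[-1]):
                raise ConfigError("segments must be contiguous")
            edges.append(end)
            temps.append(float(seg["T_C"]))
            co2s.append(float(seg["CO2_ppm"]))
            irrs.append(float(seg["I_W_m2"]))
        return cls(np.asarray(edges), np.asarray(temps), np.asarray(co2s), np.asarray(irrs))


@dataclass(frozen=True)
class Trajectory:
    """Simulated state history.

    Times in seconds; masses in g m⁻².  ``plant_density`` (plants m⁻²) is
    carried along so per-plant masses can be derived.
    """

    t_s: np.ndarray
    x_nsdm: np.ndarray
    x_sdm: np.ndarray
    plant_density: float = 1.0

    @property
    def total(self) -> np.ndarray:
        return self.x_nsdm + self.x_sdm

    @property
    def total_per_plant(self) -> np.ndarray:
        return self.total / self.plant_density

    @property
    def final_state(self) -> PlantState:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            return PlantState(float(self.x_nsdm[-1]), float(self.x_sdm[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t_s / 3600.0,
                "x_nsdm_g_m2": self.x_nsdm,
                "x_sdm_g_m2": self.x_sdm,
                "total_g_m2": self.total,
                "total_g_per_plant": self.total_per_plant,
            }
        )


def simulate(
    initial: PlantState,
    env: EnvironmentSchedule,
    c_eps: float | None = None,
    params: GrowthParameters = DEFAULT_PARAMETERS,
    t_eval_s: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the growth ODEs over an environment schedule.

    Adaptive Runge-Kutta (RK45) restarted at every segment boundary so the
    solver never steps across a forcing discontinuity.  States are recorded at
    segment boundaries plus any requested ``t_eval_s`` output times.  Negative
    non-structural mass triggers a :class:`ModelValidityWarning` but is not
    clamped.
    """
    if c_eps is None:
        c_eps = params.c_eps
    times = [0.0]
    ns = [initial.x_nsdm]
    sd = [initial.x_sdm]
    if env.duration <= 0.0:
        return Trajectory(np.array(times), np.array(ns), np.array(sd), params.plant_density)
    extra = np.sort(np.asarray(t_eval_s, dtype=float)) if t_eval_s is not None else None
    y = [initial.x_nsdm, initial.x_sdm]
    for t0, t1, temp, co2, irr in env.segments():

        def rhs(t, y, temp=temp, co2=co2, irr=irr):
            return state_derivatives(y[0], y[1], temp, co2, irr, c_eps, params)

        t_pts = [t1]
        if extra is not None:
            inner = extra[(extra > t0) & (extra < t1)]
            t_pts = list(inner) + [t1]
        sol = solve_ivp(
            rhs, (t0, t1), y, method="RK45", rtol=rtol, atol=atol, t_eval=t_pts, dense_output=False
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on segment [{t0:g}, {t1:g}] s: {sol.message}")
        times.extend(sol.t.tolist())
        ns.extend(sol.y[0].tolist())
        sd.extend(sol.y[1].tolist())
        y = [sol.y[0][-1], sol.y[1][-1]]
    if min(ns) < 0 or min(sd) < 0:
        warnings.warn(
            "trajectory left the model validity region (negative dry mass)",
            ModelValidityWarning,
            stacklevel=2,
        )
    return Trajectory(np.asarray(times), np.asarray(ns), np.asarray(sd), params.plant_density)
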