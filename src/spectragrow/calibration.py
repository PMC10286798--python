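"""Inverse calibration of the quantum use efficiency c_ε.

Harvest dry mass is strictly increasing in c_ε whenever the schedule carries
light and CO₂ above the compensation point, so the observed harvest mass
pins down a unique c_ε.  The calibrator verifies that monotonicity
empirically on the bracket, expands the bracket geometrically if the target
is not straddled, and then runs Brent's method on the residual
``harvest_mass(c_ε) − target``.

Targets may be stated per plant (converted to per-area through the
``plant_density`` parameter) or per square metre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ModelValidityWarning, NoRootError, NonMonotoneError
from .growth import (
    DEFAULT_PARAMETERS,
    EnvironmentSchedule,
    GrowthParameters,
    PlantState,
    simulate,
)

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "calibrate_ce",
    "calibrate_all",
    "DEFAULT_BRACKET",
    "MAX_BRACKET",
]

#: Default c_ε search bracket (g J⁻¹): two orders of magnitude around the
#: observed range of calibrated efficiencies for lettuce.
DEFAULT_BRACKET = (1e-7, 1e-4)
#: Hard limits for automatic bracket expansion.
MAX_BRACKET = (1e-8, 1e-3)


@dataclass(frozen=True)
class CalibrationProblem:
    """One treatment's inverse problem.

    ``target_mass`` is the observed harvest dry mass, in grams per plant when
    ``per_plant`` is True (converted through ``params.plant_density``),
    otherwise in g m⁻².  ``harvest_time_s`` defaults to the schedule end.
    """

    target_mass: float
    env: EnvironmentSchedule
    params: GrowthParameters = DEFAULT_PARAMETERS
    initial: PlantState = field(default_factory=lambda: PlantState(0.005, 0.045))
    harvest_time_s: float | None = None
    per_plant: bool = True

    def __post_init__(self):
        if self.target_mass <= 0:
            raise ValueError("target mass must be positive")
        t_h = self.harvest_time_s
        if t_h is not None and not 0 < t_h <= self.env.duration:
            raise ValueError("harvest time must lie within the schedule")

    @property
    def target_area_mass(self) -> float:
        """Target in model units (g m⁻²)."""
        if self.per_plant:
            return self.target_mass * self.params.plant_density
        return self.target_mass

    def harvest_mass(self, c_eps: float, rtol: float = 1e-8) -> float:
        """Simulated total dry mass (g m⁻²) at harvest for a given c_ε."""
        env = self.env
        if self.harvest_time_s is not None and self.harvest_time_s < env.duration:
            env = env.truncated(self.harvest_time_s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            traj = simulate(self.initial, env, c_eps, self.params, rtol=rtol)
        return float(traj.total[-1])


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one calibration run."""

    c_eps: float
    achieved_mass: float  # g m^-2
    residual: float  # achieved - target, g m^-2
    iterations: int
    function_calls: int
    bracket: tuple[float, float]
    converged: bool

    @property
    def relative_residual(self) -> float:
        return abs(self.residual) / (self.achieved_mass - self.residual)


def calibrate_ce(
    problem: CalibrationProblem,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    rel_tol: float = 1e-8,
) -> CalibrationResult:
    """Find the c_ε whose simulated harvest mass matches the observed mass.

    Raises
    ------
    NonMonotoneError
        If harvest mass does not increase from the lower to the upper bracket
        end (the bracketing root-finder would be meaningless).
    NoRootError
        If the target lies below the dark-decay mass at the minimal c_ε or
        above the light-saturated mass at the maximal c_ε, even after
        expanding the bracket to :data:`MAX_BRACKET`.
    """
    target = problem.target_area_mass
    calls = 0

    def mass(ce: float) -> float:
        nonlocal calls
        calls += 1
        return problem.harvest_mass(ce)

    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    m_lo, m_hi = mass(lo), mass(hi)
    if m_hi <= m_lo:
        raise NonMonotoneError(
            f"harvest mass not increasing across bracket: m({lo:g})={m_lo:g}, m({hi:g})={m_hi:g}"
        )
    # Expand geometrically until the target is straddled or the hard limits hit.
    while m_lo > target and lo > MAX_BRACKET[0]:
        lo = max(lo / 10.0, MAX_BRACKET[0])
        m_lo = mass(lo)
    while m_hi < target and hi < MAX_BRACKET[1]:
        hi = min(hi * 10.0, MAX_BRACKET[1])
        m_hi = mass(hi)
    if m_lo == target:
        return CalibrationResult(lo, m_lo, 0.0, 0, calls, (lo, hi), True)
    if m_hi == target:
        return CalibrationResult(hi, m_hi, 0.0, 0, calls, (lo, hi), True)
    if not m_lo < target < m_hi:
        raise NoRootError(
            f"target {target:g} g m^-2 outside reachable range "
            f"[{m_lo:g}, {m_hi:g}] for c_eps in [{lo:g}, {hi:g}]"
        )
    root, info = brentq(
        lambda ce: mass(ce) - target, lo, hi, xtol=1e-22, rtol=9e-16, full_output=True
    )
    achieved = mass(root)
    residual = achieved - target
    converged = abs(residual) <= rel_tol * target
    return CalibrationResult(
        float(root), achieved, residual, info.iterations, calls, (lo, hi), converged
    )


def calibrate_all(
    records: pd.DataFrame,
    problem_builder: Callable[[pd.Series], CalibrationProblem],
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    rel_tol: float = 1e-8,
) -> pd.DataFrame:
    """Calibrate c_ε for every row of a treatment table.

    ``problem_builder`` maps a record (a row of ``records``) to a
    :class:`CalibrationProblem`.  Failures are reported in the output table —
    one row per input record with ``converged`` False and the error message —
    never silently dropped.
    """
    rows = []
    for _, rec in records.iterrows():
        entry = {"treatment": rec.get("treatment"), "ce_g_per_J": np.nan,
                 "achieved_g_m2": np.nan, "residual": np.nan,
                 "converged": False, "message": ""}
        try:
            result = calibrate_ce(problem_builder(rec), bracket=bracket, rel_tol=rel_tol)
            entry.update(
                ce_g_per_J=result.c_eps,
                achieved_g_m2=result.achieved_mass,
                residual=result.residual,
                converged=result.converged,
            )
        except (NoRootError, NonMonotoneError, ValueError) as exc:
            entry["message"] = f"{type(exc).__name__}: {exc}"
        rows.append(entry)
    return pd.DataFrame(
        rows,
        columns=["treatment", "ce_g_per_J", "achieved_g_m2", "residual", "converged", "message"],
    )
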