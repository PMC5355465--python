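"""Serum IgG dynamics in IgG multiple myeloma.

Monoclonal (tumor-secreted) and polyclonal (normal-repertoire) IgG are
kinetically identical and compete for the same saturable FcRn recycling
capacity, so each clone's elimination depends on the *total* plasma IgG.
During successful treatment the monoclonal production rate falls, total
plasma IgG drops, the shared fractional catabolic rate decreases, and
both species are eliminated more slowly — the monoclonal serum response
therefore lags the underlying tumor response, and polyclonal IgG
transiently rises above its pre-treatment level.

The monoclonal production schedule is phenomenological:
``Im(t) = (Im0 − Im_inf)·exp(−k_kill·t) + Im_inf``, i.e. exponential
tumor kill toward a residual production rate, with polyclonal production
constant at its normal value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (IntegrationError, MetabolicParameters, steady_state)
from .quantities import DEFAULT_CONSTANTS, UnitConstants, quantity_to_conc

__all__ = [
    "ProductionSchedule",
    "MyelomaState",
    "ScenarioConfig",
    "SimulationResult",
    "production_rate",
    "initial_conditions",
    "simulate",
    "fcr_trajectory",
]


@dataclass(frozen=True)
class ProductionSchedule:
    """IgG synthesis-rate model during treatment.

    ``Im0``/``Im_inf`` are the initial and asymptotic monoclonal
    production rates (µmol day⁻¹), ``k_kill`` the tumor-kill rate
    constant (day⁻¹), ``Ip0`` the constant polyclonal production rate
    (µmol day⁻¹; ~15 in normal adults).  ``Im_inf > Im0`` is allowed and
    describes progression rather than response.
    """

    Im0: float
    Im_inf: float
    k_kill: float
    Ip0: float = 15.0

    def __post_init__(self) -> None:
        for name in ("Im0", "Im_inf", "k_kill", "Ip0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_response(self) -> bool:
        return self.Im0 >= self.Im_inf


class MyelomaState(NamedTuple):
    """Monoclonal/polyclonal IgG quantities in plasma and periphery (µmol)."""

    x1m: float
    x2m: float
    x1p: float
    x2p: float


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete myeloma simulation scenario."""

    params: MetabolicParameters
    schedule: ProductionSchedule
    sample_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 366.0, 7.0))  # weekly for a year
    output_unit: str = "g_per_l"
    constants: UnitConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times, dtype=float)
        if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing with >= 2 points")
        if self.output_unit not in ("umol", "g_per_l"):
            raise ValueError("output_unit must be 'umol' or 'g_per_l'")
        object.__setattr__(self, "sample_times", times)


def production_rate(schedule: ProductionSchedule, t) -> np.ndarray | float:
    """Monoclonal IgG production rate Im(t) (µmol day⁻¹)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = (schedule.Im0 - schedule.Im_inf) * np.exp(-schedule.k_kill * t) \
        + schedule.Im_inf
    return float(out) if out.ndim == 0 else out


def initial_conditions(params: MetabolicParameters,
                       schedule: ProductionSchedule) -> MyelomaState:
    """Pre-treatment steady state split between the two clones.

    The total system is at the equilibrium for production
    ``I0 = Im0 + Ip0``; each clone holds a share proportional to its
    production rate, and each peripheral compartment is ``(k21/k12)``
    times its plasma counterpart.  These initial conditions zero all
    four derivatives at t = 0.
    """
    I0 = schedule.Im0 + schedule.Ip0
    if I0 == 0:
        return MyelomaState(0.0, 0.0, 0.0, 0.0)
    total = steady_state(params, I0)
    ratio = params.k21 / params.k12
    x1m = schedule.Im0 / I0 * total.x1
    x1p = schedule.Ip0 / I0 * total.x1
    return MyelomaState(x1m=x1m, x2m=ratio * x1m, x1p=x1p, x2p=ratio * x1p)


def _rhs(t, y, params: MetabolicParameters, schedule: ProductionSchedule):
    x1m, x2m, x1p, x2p = y
    elim = params.k31 - params.Vmax / (params.KM + x1m + x1p)
    Im = (schedule.Im0 - schedule.Im_inf) * np.exp(-schedule.k_kill * t) \
        + schedule.Im_inf
    return [
        -(params.k21 + elim) * x1m + params.k12 * x2m + Im,
        params.k21 * x1m - params.k12 * x2m,
        -(params.k21 + elim) * x1p + params.k12 * x2p + schedule.Ip0,
        params.k21 * x1p - params.k12 * x2p,
    ]


@dataclass
class SimulationResult:
    """Simulated clone-resolved trajectories (quantities in µmol)."""

    times: np.ndarray
    x1m: np.ndarray
    x2m: np.ndarray
    x1p: np.ndarray
    x2p: np.ndarray
    scenario: ScenarioConfig

    @property
    def total_plasma(self) -> np.ndarray:
        return self.x1m + self.x1p

    def concentrations(self) -> pd.DataFrame:
        """Monoclonal, polyclonal and total plasma concentrations in the
        scenario's output unit."""
        if self.scenario.output_unit == "umol":
            mono, poly = self.x1m, self.x1p
        else:
            c = self.scenario.constants
            factor = c.molar_mass / c.plasma_volume_v1
            mono, poly = self.x1m * factor, self.x1p * factor
        return pd.DataFrame({
            "time_days": self.times,
            "monoclonal": mono,
            "polyclonal": poly,
            "total": mono + poly,
        })


def simulate(scenario: ScenarioConfig) -> SimulationResult:
    """Integrate the clone-resolved 4-state system from its steady state.

    The two clones share the saturable recycling term
    ``Vmax/(KM + x1m + x1p)``; their sum therefore follows the
    single-species model with production ``Im(t) + Ip0``.
    """
    scenario.params.validate()
    y0 = list(initial_conditions(scenario.params, scenario.schedule))
    times = scenario.sample_times
    sol = solve_ivp(_rhs, (times[0], times[-1]), y0, t_eval=times,
                    args=(scenario.params, scenario.schedule),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise IntegrationError(
            f"myeloma simulation failed ({scenario.schedule}): {sol.message}")
    return SimulationResult(times=times, x1m=sol.y[0], x2m=sol.y[1],
                            x1p=sol.y[2], x2p=sol.y[3], scenario=scenario)


def fcr_trajectory(result: SimulationResult) -> np.ndarray:
    """Instantaneous shared FCR, ``k31 − Vmax/(KM + x1m + x1p)``, along
    a simulated trajectory (day⁻¹); falls as total plasma IgG falls."""
    p = result.scenario.params
    return p.k31 - p.Vmax / (p.KM + result.total_plasma)
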