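"""Macro constants of IgG turnover — fractional catabolic rate (FCR),
terminal half-life (T½), fractional/absolute recycling rates — as
functions of the micro parameters, plus their estimation directly from
tracer timecourse data and the classical reciprocal-plot fit.

The FCR is the fraction of plasma IgG catabolized per day,
``FCR = k31 − Vmax/(KM + x1E)``: it rises with the endogenous plasma
quantity ``x1E`` because recycling capacity saturates.  The terminal
half-life is ``−ln 2 / λ2`` with ``λ2`` the slow eigenvalue of the
linear tracer system, and falls with ``x1E``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import (MetabolicParameters, biexponential_constants,
                       net_elimination_rate)
from .quantities import UnitConstants, DEFAULT_CONSTANTS

__all__ = [
    "MacroConstants",
    "MacroDataset",
    "RecyclingRates",
    "TimecourseDataset",
    "fcr",
    "half_life",
    "half_life_from_fcr",
    "frr",
    "macro_constants",
    "fcr_concentration_form",
    "estimate_fcr_from_timecourse",
    "estimate_thalf_from_timecourse",
    "waldmann_reciprocal_fit",
    "FcrFromTimecourse",
]


@dataclass(frozen=True)
class TimecourseDataset:
    """One subject's tracer observations: fraction of the administered
    dose in plasma (``y1``) and in the whole body (``y2``) versus time."""

    subject_id: str
    times: np.ndarray
    y1_obs: np.ndarray
    y2_obs: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        y1 = np.asarray(self.y1_obs, dtype=float)
        y2 = np.asarray(self.y2_obs, dtype=float)
        if not (times.shape == y1.shape == y2.shape) or times.ndim != 1:
            raise ValueError("times, y1_obs, y2_obs must be 1-d arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in (("y1_obs", y1), ("y2_obs", y2)):
            bad = np.nonzero((arr <= 0) | (arr > 1.05))[0]
            if bad.size:
                raise ValueError(
                    f"{name} must lie in (0, 1.05]; row {bad[0] + 1} has value {arr[bad[0]]}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "y1_obs", y1)
        object.__setattr__(self, "y2_obs", y2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times,
                             "y1_plasma_fraction": self.y1_obs,
                             "y2_body_fraction": self.y2_obs})


@dataclass(frozen=True)
class MacroDataset:
    """Population records of plasma IgG quantity vs FCR and/or T½.

    Either macro column may contain NaN for subjects contributing only
    the other output; ``source_conc_g_per_l`` optionally retains the
    original concentration for provenance.
    """

    x1E: np.ndarray
    fcr_per_day: np.ndarray
    thalf_days: np.ndarray
    source_conc_g_per_l: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x1E, dtype=float)
        f = np.asarray(self.fcr_per_day, dtype=float)
        t = np.asarray(self.thalf_days, dtype=float)
        if not (x.shape == f.shape == t.shape) or x.ndim != 1:
            raise ValueError("x1E, fcr_per_day, thalf_days must be 1-d arrays of equal length")
        if np.any(x <= 0):
            raise ValueError("x1E must be strictly positive")
        if np.any(f[~np.isnan(f)] <= 0) or np.any(t[~np.isnan(t)] <= 0):
            raise ValueError("FCR and T½ values must be strictly positive where present")
        object.__setattr__(self, "x1E", x)
        object.__setattr__(self, "fcr_per_day", f)
        object.__setattr__(self, "thalf_days", t)

    @property
    def fcr_records(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~np.isnan(self.fcr_per_day)
        return self.x1E[m], self.fcr_per_day[m]

    @property
    def thalf_records(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~np.isnan(self.thalf_days)
        return self.x1E[m], self.thalf_days[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x1E_umol": self.x1E,
                             "fcr_per_day": self.fcr_per_day,
                             "thalf_days": self.thalf_days})


@dataclass(frozen=True)
class MacroConstants:
    """Macro constants of one subject's bi-exponential tracer decay."""

    FCR: float
    T_half: float
    lambda1: float
    lambda2: float
    A_coefficients: tuple[float, float, float, float]


class RecyclingRates(NamedTuple):
    """Fractional recycling rate (day⁻¹) and absolute recycling rate per
    kg of body weight (µmol day⁻¹ kg⁻¹)."""

    FRR: float
    ARR_per_kg: float


def fcr(params: MetabolicParameters, x1E: float) -> float:
    """Fractional catabolic rate ``k31 − Vmax/(KM + x1E)`` (day⁻¹)."""
    params.validate()
    if x1E < 0:
        raise ValueError("x1E must be non-negative")
    return net_elimination_rate(params, x1E)


def half_life(params: MetabolicParameters, x1E: float) -> float:
    """Terminal half-life (days) at endogenous plasma quantity ``x1E``."""
    return half_life_from_fcr(params.k12, params.k21, fcr(params, x1E))


def half_life_from_fcr(k12: float, k21: float, FCR: float) -> float:
    """Terminal half-life in terms of (k12, k21, FCR).

    ``T½ = 2 ln 2 / (k12 + k21 + FCR − sqrt((k12+k21+FCR)² − 4 k12 FCR))``.
    Returns ``inf`` in the degenerate limit FCR → 0.
    """
    if k12 <= 0 or k21 <= 0:
        raise ValueError("k12 and k21 must be strictly positive")
    if FCR < 0:
        raise ValueError("FCR must be non-negative")
    if FCR == 0:
        return math.inf
    s = k12 + k21 + FCR
    return 2.0 * math.log(2.0) / (s - math.sqrt(s * s - 4.0 * k12 * FCR))


def frr(params: MetabolicParameters, x1E: float,
        constants: UnitConstants = DEFAULT_CONSTANTS) -> RecyclingRates:
    """Fractional recycling rate ``FRR = k31 − FCR = Vmax/(KM + x1E)``
    and the absolute recycling rate per kg, ``FRR · x1E / w``."""
    f = params.Vmax / (params.KM + x1E)
    return RecyclingRates(FRR=float(f),
                          ARR_per_kg=float(f * x1E / constants.body_weight_w))


def fcr_concentration_form(params: MetabolicParameters, concentration_umol_per_l: float,
                           constants: UnitConstants = DEFAULT_CONSTANTS) -> float:
    """FCR as a function of the plasma *concentration* in µmol l⁻¹.

    Identical to ``fcr(params, concentration × v1)``; provided so that
    per-volume parameterizations (KM/v1, Vmax/w) round-trip exactly.
    """
    if concentration_umol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return fcr(params, concentration_umol_per_l * constants.plasma_volume_v1)


def macro_constants(params: MetabolicParameters, x1E: float) -> MacroConstants:
    """All macro constants of the subject's tracer decay at ``x1E``."""
    sol = biexponential_constants(params, x1E)
    return MacroConstants(
        FCR=fcr(params, x1E),
        T_half=-math.log(2.0) / sol.lambda2,
        lambda1=sol.lambda1,
        lambda2=sol.lambda2,
        A_coefficients=(sol.A11, sol.A12, sol.A21, sol.A22),
    )


@dataclass(frozen=True)
class FcrFromTimecourse:
    """Per-interval FCR estimates and the pooled post-distribution value."""

    interval_midpoints: np.ndarray
    interval_estimates: np.ndarray
    pooled: float
    negative_intervals_flagged: bool = False


def estimate_fcr_from_timecourse(data: TimecourseDataset,
                                 distribution_cutoff_days: float = 5.0) -> FcrFromTimecourse:
    """Estimate the FCR directly from a subject's timecourse.

    The dose leaves the body at rate ``−dy2/dt``; dividing by the dose
    fraction still in plasma gives the FCR at any t > 0.  Each
    consecutive sample pair yields ``−Δy2/Δt ÷ ȳ1`` (ȳ1 the interval mean
    of the plasma fraction); the pooled estimate averages intervals whose
    midpoint falls after the distribution cutoff, where the definition is
    no longer contaminated by plasma↔tissue exchange.
    """
    if data.times.size < 3:
        raise ValueError("need at least 3 samples to estimate the FCR")
    dt = np.diff(data.times)
    dy2 = np.diff(data.y2_obs)
    y1_mid = 0.5 * (data.y1_obs[1:] + data.y1_obs[:-1])
    estimates = -dy2 / dt / y1_mid
    midpoints = 0.5 * (data.times[1:] + data.times[:-1])
    window = midpoints > distribution_cutoff_days
    if not np.any(window):
        window = np.ones_like(midpoints, dtype=bool)
    pooled = float(np.mean(estimates[window]))
    return FcrFromTimecourse(
        interval_midpoints=midpoints,
        interval_estimates=estimates,
        pooled=pooled,
        negative_intervals_flagged=bool(np.any(estimates < 0)),
    )


def estimate_thalf_from_timecourse(data: TimecourseDataset,
                                   terminal_window: Optional[tuple[float, float]] = None) -> float:
    """Estimate T½ from the terminal slope of ``ln y1`` versus time.

    ``terminal_window`` is an (start, end) time interval; the default is
    the last half of the sampling span.  A least-squares line is fitted
    to ``ln y1`` on the window and T½ = −ln2 / slope.
    """
    if terminal_window is None:
        span = data.times[-1] - data.times[0]
        terminal_window = (data.times[0] + span / 2.0, data.times[-1])
    lo, hi = terminal_window
    m = (data.times >= lo) & (data.times <= hi)
    if np.count_nonzero(m) < 3:
        raise ValueError("need at least 3 samples in the terminal window")
    y = data.y1_obs[m]
    if np.any(y <= 0):
        raise ValueError("non-positive observations in the terminal window")
    slope = np.polyfit(data.times[m], np.log(y), 1)[0]
    return float(-math.log(2.0) / slope)


def waldmann_reciprocal_fit(arr_points: Sequence[tuple[float, float]],
                            body_weight_w: float = 70.0) -> tuple[float, float]:
    """Classical double-reciprocal estimate of (Vmax, KM) from absolute
    recycling rates.

    Since ``ARR = Vmax/(KM + x1E) · x1E/w``, plotting ``1/ARR`` against
    ``w/x1E`` is a straight line with intercept ``w/Vmax`` and slope
    ``KM·w/Vmax``.  Ordinary least squares on the reciprocal coordinates
    returns ``(Vmax, KM)`` in absolute units for the given body weight.
    """
    pts = np.asarray(arr_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least 2 (x1E_per_kg, ARR_per_kg) points")
    if np.any(pts <= 0):
        raise ValueError("all points must be strictly positive")
    x_recip = 1.0 / pts[:, 0]  # = w/x1E in per-kg coordinates
    y_recip = 1.0 / pts[:, 1]
    if np.ptp(x_recip) == 0 and pts.shape[0] > 1:
        raise ValueError("singular design: all x1E values identical")
    slope, intercept = np.polyfit(x_recip, y_recip, 1)
    if intercept <= 0:
        raise ValueError("non-positive intercept: data inconsistent with saturable recycling")
    Vmax = body_weight_w / intercept  # intercept = w/Vmax
    KM = slope * Vmax  # slope = KM/Vmax with abscissa 1/(x1E/w)
    return (float(Vmax), float(KM))
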