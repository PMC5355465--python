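"""Seeded synthetic-data generators for every input the analysis
pipeline consumes: single-subject tracer timecourses, population
FCR/T½-vs-x1E scatter, and serum M-protein treatment series.

The generators emulate the structure of the historical human data: a
bi-exponential tracer decay observed as plasma and whole-body dose
fractions over ~2–7 weeks; population macro scatter across plasma IgG
quantities spanning roughly 30–2000 µmol (about 1.5–100 g l⁻¹) with
inter-subject variation in the exchange rates; and weekly serum
electrophoresis readings during treatment.  Noise defaults are
proportional Gaussian with CV 3% for timecourses and 10% for macro
outputs — the historical counting-error structure is unknown, so these
are explicit, configurable assumptions.  Identical seeds give identical
datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (MetabolicParameters, TracerDesign, is_stable,
                       linear_tracer_solution)
from .macro import MacroDataset, TimecourseDataset, fcr, half_life
from .myeloma import ScenarioConfig, simulate

__all__ = [
    "NoiseModel",
    "PopulationSpec",
    "default_tracer_design",
    "generate_subject",
    "generate_population_macro",
    "generate_myeloma_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise model: additive (scale = SD) or proportional
    (scale = CV) zero-mean Gaussian, reproducible from ``seed``."""

    kind: str = "proportional"
    scale: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional"):
            raise ValueError("kind must be 'additive' or 'proportional'")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.scale == 0:
            return values.copy()
        eps = rng.standard_normal(values.shape)
        if self.kind == "additive":
            return values + self.scale * eps
        return values * (1.0 + self.scale * eps)


def default_tracer_design(IE: float = 15.0) -> TracerDesign:
    """Typical tracer study: small bolus, dense early sampling then
    daily out to 30 days (captures the fast distribution phase and the
    slow elimination phase)."""
    times = np.concatenate([[0.25, 0.5, 1.0], np.arange(2.0, 31.0)])
    return TracerDesign(dose_D=0.005, sample_times=times,
                        endogenous_production_IE=IE)


def generate_subject(params: MetabolicParameters, x1E: float,
                     design: TracerDesign | None = None,
                     noise: NoiseModel = NoiseModel(),
                     subject_id: str = "synthetic") -> TimecourseDataset:
    """Synthesize one subject's tracer timecourse.

    Noise-free curves come from the analytic linearized tracer solution
    at endogenous plasma quantity ``x1E``; noise is applied per the
    noise model and values are clipped into the valid observation range
    (a warning is issued if more than 20% of samples clip).
    """
    if design is None:
        design = default_tracer_design()
    x1P, x2P = linear_tracer_solution(params, x1E, design.sample_times)
    rng = np.random.default_rng(noise.seed)
    y1 = noise.apply(x1P, rng)
    y2 = noise.apply(x1P + x2P, rng)
    clipped = np.count_nonzero((y1 <= 1e-6) | (y1 > 1.05)
                               | (y2 <= 1e-6) | (y2 > 1.05))
    total = y1.size + y2.size
    if clipped / total > 0.20:
        warnings.warn(f"noise clipped {clipped}/{total} samples; "
                      "generated data may be badly distorted")
    y1 = np.clip(y1, 1e-6, 1.05)
    y2 = np.clip(y2, 1e-6, 1.05)
    return TimecourseDataset(subject_id=subject_id,
                             times=design.sample_times, y1_obs=y1, y2_obs=y2)


@dataclass(frozen=True)
class PopulationSpec:
    """Population for macro-data generation: shared elimination
    parameters, log-normal inter-subject variation about the mean
    exchange rates, and log-uniform plasma IgG quantities over a wide
    concentration range."""

    n_subjects: int = 44
    x1E_bounds: tuple = (30.0, 2000.0)
    k12_mean: float = 0.38
    k21_mean: float = 0.42
    exchange_cv: float = 0.2
    k31: float = 0.16
    Vmax: float = 40.0
    KM: float = 270.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.x1E_bounds
        if not (0 < lo < hi):
            raise ValueError("x1E_bounds must satisfy 0 < lo < hi")


def generate_population_macro(spec: PopulationSpec,
                              noise_fcr: NoiseModel = NoiseModel(scale=0.10),
                              noise_thalf: NoiseModel = NoiseModel(scale=0.10),
                              seed: int = 0,
                              max_resample: int = 1000) -> MacroDataset:
    """Synthesize a population FCR/T½-vs-x1E dataset.

    Each subject draws an ``x1E`` (log-uniform) and individual exchange
    rates (log-normal about the population means, rejection-sampled so
    every draw yields a valid parameter set), then contributes one noisy
    FCR and one noisy T½ observation on the true curves.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.x1E_bounds
    sigma = np.sqrt(np.log(1.0 + spec.exchange_cv ** 2))
    x1E_list, fcr_true, th_true = [], [], []
    for _ in range(spec.n_subjects):
        for attempt in range(max_resample):
            k12 = spec.k12_mean * np.exp(sigma * rng.standard_normal()
                                         - sigma ** 2 / 2)
            k21 = spec.k21_mean * np.exp(sigma * rng.standard_normal()
                                         - sigma ** 2 / 2)
            candidate = MetabolicParameters(k12=k12, k21=k21, k31=spec.k31,
                                            Vmax=spec.Vmax, KM=spec.KM)
            if is_stable(candidate).stable:
                break
        else:
            raise RuntimeError("resampling cap reached drawing valid parameters")
        x = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        x1E_list.append(x)
        fcr_true.append(fcr(candidate, x))
        th_true.append(half_life(candidate, x))
    fcr_noisy = noise_fcr.apply(np.array(fcr_true),
                                np.random.default_rng(noise_fcr.seed + seed))
    th_noisy = noise_thalf.apply(np.array(th_true),
                                 np.random.default_rng(noise_thalf.seed + seed + 1))
    return MacroDataset(x1E=np.array(x1E_list),
                        fcr_per_day=np.abs(fcr_noisy),
                        thalf_days=np.abs(th_noisy))


def generate_myeloma_series(scenario: ScenarioConfig,
                            noise: NoiseModel = NoiseModel(scale=0.05)) -> pd.DataFrame:
    """Synthesize a serum M-protein monitoring series: simulate the
    scenario and apply observation noise to the monoclonal and
    polyclonal concentration columns."""
    frame = simulate(scenario).concentrations()
    rng = np.random.default_rng(noise.seed)
    out = frame.copy()
    out["monoclonal"] = np.abs(noise.apply(frame["monoclonal"].to_numpy(), rng))
    out["polyclonal"] = np.abs(noise.apply(frame["polyclonal"].to_numpy(), rng))
    out["total"] = out["monoclonal"] + out["polyclonal"]
    return out
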