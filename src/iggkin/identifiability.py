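"""Structural identifiability of the IgG metabolism model for the three
observation settings seen in practice.

The linear tracer model has transfer-function matrix elements whose
coefficients are rational in the parameters; the distinct coefficients
form the invariant map Φ = (k12, k12+k21, k12·FCR, FCR+k12+k21).  From a
single subject's timecourse only (k12, k21) — and the combination
FCR = k31 − Vmax/(KM + x1E) — are uniquely determined; the elimination
parameters (k31, Vmax, KM) and x1E are not, because any alternative
quadruple with the same FCR produces identical outputs.  Observing the
FCR as a function of x1E across subjects identifies (k31, Vmax, KM);
observing T½ as a function of x1E identifies all five parameters.

The verdicts here are established numerically: an explicit witness
construction demonstrates timecourse unidentifiability, and multi-start
equation solving over wide bounds finds no alternative solutions for the
curve settings (evidence, not symbolic proof).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import MetabolicParameters, linear_tracer_solution, is_stable
from .macro import fcr, half_life

__all__ = [
    "PhiInvariants",
    "IdentifiabilityReport",
    "transfer_function_coefficients",
    "check_timecourse_identifiability",
    "check_fcr_curve_identifiability",
    "check_thalf_curve_identifiability",
    "check_nonlinear_model_identifiability",
]

IDENTIFIABLE = "globally identifiable"
UNIDENTIFIABLE = "unidentifiable"


class PhiInvariants(NamedTuple):
    """The four distinct transfer-function coefficients of the linear
    tracer model; they exhaust what ideal timecourse data can reveal."""

    phi1: float  # k12
    phi2: float  # k12 + k21
    phi3: float  # k12 * FCR
    phi4: float  # FCR + k12 + k21


@dataclass
class IdentifiabilityReport:
    """Verdict of a structural identifiability check.

    ``verdicts`` maps parameter names to 'globally identifiable' or
    'unidentifiable'; ``identifiable_combinations`` lists combinations
    (such as the FCR) determined even when components are not;
    ``witness`` holds an alternative parameter vector proving
    unidentifiability where applicable; ``evidence`` summarizes the
    numeric search; ``conclusive`` is False for degenerate inputs.
    """

    observation_setting: str
    verdicts: dict
    identifiable_combinations: list = field(default_factory=list)
    witness: Optional[dict] = None
    evidence: dict = field(default_factory=dict)
    conclusive: bool = True

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "observation_setting": self.observation_setting,
            "verdicts": self.verdicts,
            "identifiable_combinations": self.identifiable_combinations,
            "witness": self.witness,
            "evidence": self.evidence,
            "conclusive": self.conclusive,
        }, **kwargs)

    def summary_table(self) -> str:
        ident = sorted(k for k, v in self.verdicts.items() if v == IDENTIFIABLE)
        return (f"{self.observation_setting}: "
                f"structurally globally identifiable: {', '.join(ident) or 'none'}")


def transfer_function_coefficients(params: MetabolicParameters,
                                   x1E: float) -> PhiInvariants:
    """The invariant coefficient map Φ of the linear tracer model.

    Φ depends on the six quantities (k12, k21, k31, Vmax, KM, x1E) only
    through the triple (k12, k21, FCR); note the algebraic identities
    phi4 − phi2 = phi3/phi1 = FCR.
    """
    f = fcr(params, x1E)
    return PhiInvariants(
        phi1=params.k12,
        phi2=params.k12 + params.k21,
        phi3=params.k12 * f,
        phi4=f + params.k12 + params.k21,
    )


def _construct_witness(params: MetabolicParameters, x1E: float) -> tuple[MetabolicParameters, float]:
    """Build an alternative (k31, Vmax, KM, x1E) with the same FCR (and
    identical k12, k21), hence identical outputs."""
    f = fcr(params, x1E)
    x1E_alt = 2.0 * x1E + 50.0
    KM_alt = 2.0 * params.KM
    Vmax_alt = params.Vmax
    # shrink Vmax_alt until the alternative set satisfies the positivity
    # and net-elimination invariants
    for _ in range(60):
        k31_alt = f + Vmax_alt / (KM_alt + x1E_alt)
        candidate = MetabolicParameters(k12=params.k12, k21=params.k21,
                                        k31=k31_alt, Vmax=Vmax_alt, KM=KM_alt)
        if is_stable(candidate).stable:
            return candidate, x1E_alt
        Vmax_alt *= 0.5
    raise RuntimeError("failed to construct a stable witness parameter set")


def check_timecourse_identifiability(params: MetabolicParameters, x1E: float,
                                     search_budget: int = 100,
                                     times: Optional[Sequence[float]] = None) -> IdentifiabilityReport:
    """Identifiability from a single subject's timecourse.

    Reports (k12, k21) and the FCR as globally identifiable and
    (k31, Vmax, KM, x1E) as unidentifiable, and attaches a constructed
    witness — an alternative elimination parameter set with the same FCR
    — whose simulated outputs are verified to coincide with the
    original's on a 50-day grid.
    """
    params.validate()
    if times is None:
        times = np.linspace(0.0, 50.0, 201)
    witness_params, witness_x1E = _construct_witness(params, x1E)

    y1_a, y2p_a = linear_tracer_solution(params, x1E, times)
    y1_b, y2p_b = linear_tracer_solution(witness_params, witness_x1E, times)
    max_dev = float(max(np.max(np.abs(y1_a - y1_b)),
                        np.max(np.abs((y1_a + y2p_a) - (y1_b + y2p_b)))))

    phi = transfer_function_coefficients(params, x1E)
    phi_w = transfer_function_coefficients(witness_params, witness_x1E)
    return IdentifiabilityReport(
        observation_setting="timecourse",
        verdicts={"k12": IDENTIFIABLE, "k21": IDENTIFIABLE,
                  "k31": UNIDENTIFIABLE, "Vmax": UNIDENTIFIABLE,
                  "KM": UNIDENTIFIABLE, "x1E": UNIDENTIFIABLE},
        identifiable_combinations=["FCR = k31 - Vmax/(KM + x1E)"],
        witness={**witness_params.to_dict(), "x1E": witness_x1E},
        evidence={
            "phi_original": list(phi),
            "phi_witness": list(phi_w),
            "max_output_deviation": max_dev,
            "witness_fcr_matches": abs(fcr(params, x1E)
                                       - fcr(witness_params, witness_x1E)) < 1e-12,
        },
    )


def _multistart_uniqueness(residual_fn, truth: np.ndarray, names: list,
                           search_budget: int, seed: int,
                           resid_tol: float, match_tol: float) -> dict:
    """Run multi-start least squares; classify converged zero-residual
    solutions as the true vector or a distinct alternative."""
    rng = np.random.default_rng(seed)
    lower = truth * 1e-4
    upper = truth * 1e4
    n_converged = 0
    alternatives = []
    for i in range(search_budget):
        if i == 0:
            x0 = truth.copy()
        else:
            x0 = np.exp(rng.uniform(np.log(lower), np.log(upper)))
        try:
            res = least_squares(residual_fn, x0, bounds=(lower, upper),
                                x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            # polish promising candidates: the bounded trust-region step
            # stalls in the near-flat valley of the T½ objective, while
            # an unconstrained Levenberg–Marquardt refinement resolves
            # whether the candidate truly attains zero residual
            if np.sqrt(np.mean(res.fun ** 2)) < 1e-3:
                res = least_squares(residual_fn, res.x, method="lm",
                                    jac="3-point", xtol=1e-15, ftol=1e-15,
                                    gtol=1e-15, max_nfev=20000)
        except Exception:
            continue
        if np.sqrt(np.mean(res.fun ** 2)) < resid_tol and np.all(res.x > 0):
            n_converged += 1
            rel = np.abs(res.x - truth) / truth
            if np.max(rel) > match_tol:
                alternatives.append(dict(zip(names, res.x.tolist())))
    return {"n_starts": search_budget, "n_zero_residual": n_converged,
            "n_alternative_solutions": len(alternatives),
            "alternatives": alternatives[:5]}


def check_fcr_curve_identifiability(params: MetabolicParameters,
                                    x_grid: Optional[Sequence[float]] = None,
                                    search_budget: int = 100,
                                    seed: int = 0) -> IdentifiabilityReport:
    """Identifiability of (k31, Vmax, KM) from the FCR-vs-x1E curve.

    Solves ``k31 − Vmax/(KM + x) ≡ curve`` over the grid from many
    random starts in [1e-4, 1e4] × the true values; finding no distinct
    zero-residual solution is reported as numeric evidence of global
    identifiability.  Fewer than 3 distinct grid points is flagged
    inconclusive (a 2-point grid admits a one-parameter family).
    """
    params.validate()
    if x_grid is None:
        x_grid = np.array([30.0, 100.0, 300.0, 1000.0, 2000.0])
    x_grid = np.asarray(x_grid, dtype=float)
    conclusive = np.unique(x_grid).size >= 3

    target = np.array([fcr(params, x) for x in x_grid])
    truth = np.array([params.k31, params.Vmax, params.KM])

    def residual(theta):
        k31, Vmax, KM = theta
        return (k31 - Vmax / (KM + x_grid)) - target

    evidence = _multistart_uniqueness(residual, truth,
                                      ["k31", "Vmax", "KM"],
                                      search_budget if conclusive else 0,
                                      seed, resid_tol=1e-9, match_tol=1e-3)
    unique = conclusive and evidence["n_alternative_solutions"] == 0
    verdict = IDENTIFIABLE if unique else UNIDENTIFIABLE
    return IdentifiabilityReport(
        observation_setting="fcr_curve",
        verdicts={"k31": verdict, "Vmax": verdict, "KM": verdict},
        evidence=evidence,
        conclusive=conclusive,
    )


def check_thalf_curve_identifiability(params: MetabolicParameters,
                                      x_grid: Optional[Sequence[float]] = None,
                                      search_budget: int = 60,
                                      seed: int = 0) -> IdentifiabilityReport:
    """Identifiability of all five parameters from the T½-vs-x1E curve.

    The slow eigenvalue λ2(x1E) determines the coefficient functions of
    the characteristic quadratic, which pin down every parameter for
    positive values.  The numeric check refits all five parameters to
    the noise-free curve from random multi-starts and looks for distinct
    zero-residual solutions.  Fewer than 5 distinct grid points is
    flagged inconclusive.
    """
    params.validate()
    if x_grid is None:
        x_grid = np.geomspace(10.0, 2000.0, 25)
    x_grid = np.asarray(x_grid, dtype=float)
    conclusive = np.unique(x_grid).size >= 5

    target = np.array([half_life(params, x) for x in x_grid])
    truth = params.as_array()  # (k12, k21, k31, Vmax, KM)

    def residual(theta):
        k12, k21, k31, Vmax, KM = theta
        f = k31 - Vmax / (KM + x_grid)
        if np.any(f <= 0) or k12 <= 0 or k21 <= 0:
            return np.full_like(x_grid, 1e6)
        s = k12 + k21 + f
        thalf = 2.0 * np.log(2.0) / (s - np.sqrt(s * s - 4.0 * k12 * f))
        return thalf - target

    evidence = _multistart_uniqueness(residual, truth,
                                      ["k12", "k21", "k31", "Vmax", "KM"],
                                      search_budget if conclusive else 0,
                                      seed, resid_tol=1e-7, match_tol=1e-3)
    unique = conclusive and evidence["n_alternative_solutions"] == 0
    verdict = IDENTIFIABLE if unique else UNIDENTIFIABLE
    return IdentifiabilityReport(
        observation_setting="thalf_curve",
        verdicts={name: verdict for name in ("k12", "k21", "k31", "Vmax", "KM")},
        evidence=evidence,
        conclusive=conclusive,
    )


def check_nonlinear_model_identifiability(*args, **kwargs):
    """Structural identifiability of the full nonlinear coupled
    tracer+endogenous model is an open problem and is not analyzed
    here."""
    raise NotImplementedError(
        "structural identifiability of the full nonlinear coupled model "
        "has not been established and is not analyzed by this package")
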