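"""Traditional and generalized sensitivity functions (TSF/GSF) and the
Fisher information matrix for the IgG kinetics outputs.

A TSF is the partial derivative of a model output with respect to one
parameter, evaluated along the observation grid; it shows *whether* the
output responds to the parameter.  The GSF additionally accounts for
parameter correlations: for output f observed at times t_1..t_n with
error variances σ²(t_l),

    gsf_θ(t_l) = Σ_{i≤l} (1/σ²(t_i)) [F⁻¹ ∇f(t_i)] ⊙ ∇f(t_i),

where F = Σ_j (1/σ²(t_j)) ∇f(t_j) ∇f(t_j)ᵀ is the Fisher information
matrix and ⊙ selects the component for parameter θ.  By construction
every GSF equals exactly 1 at the final sample, and the interval of
steep rise marks where the data carry information about that parameter.

Timecourse outputs (y1, y2) are differentiated with respect to the
structurally identifiable triple (FCR, k12, k21) via forward sensitivity
equations; the macro outputs FCR and T½ are differentiated analytically
with respect to all five micro parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve as linalg_solve

from .kinetics import MetabolicParameters, IntegrationError
from .macro import fcr, half_life

__all__ = [
    "SensitivityCurves",
    "FisherMatrix",
    "IllConditionedFisher",
    "CONDITION_NUMBER_THRESHOLD",
    "tsf",
    "tsf_timecourse",
    "normalized_tsf",
    "fisher_information",
    "gsf",
    "gsf_timecourse",
]

#: Fisher matrices with condition number above this raise
#: :class:`IllConditionedFisher` instead of silently amplifying noise.
CONDITION_NUMBER_THRESHOLD = 1e12


class IllConditionedFisher(RuntimeError):
    """The Fisher information matrix is too ill-conditioned to invert."""

    def __init__(self, condition_number: float):
        self.condition_number = condition_number
        super().__init__(
            f"Fisher information matrix is ill-conditioned "
            f"(condition number {condition_number:.3e} > "
            f"{CONDITION_NUMBER_THRESHOLD:.0e}); GSFs are not computable")


@dataclass
class SensitivityCurves:
    """Per-parameter sensitivity curves on a shared abscissa.

    ``kind`` is 'TSF', 'normalized-TSF' or 'GSF'; ``output`` labels the
    model output (y1, y2, FCR or T_half); ``curves`` maps parameter
    names to arrays aligned with ``abscissa``.
    """

    abscissa: np.ndarray
    curves: dict
    kind: str
    output: str

    @property
    def parameter_names(self) -> list:
        return list(self.curves)

    def gradient_matrix(self) -> np.ndarray:
        """Stack curves into an (n_points, n_params) matrix."""
        return np.column_stack([self.curves[name] for name in self.curves])

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.curves)
        df.insert(0, "abscissa", self.abscissa)
        return df


@dataclass
class FisherMatrix:
    matrix: np.ndarray
    parameter_names: list
    grid: np.ndarray
    variances: np.ndarray
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = 0.5 * (m + m.T)  # enforce exact symmetry
        self.condition_number = float(np.linalg.cond(self.matrix))


_TIMECOURSE_PARAMS = ("FCR", "k12", "k21")
_MACRO_PARAMS = ("k12", "k21", "k31", "Vmax", "KM")


def tsf_timecourse(output: str, FCR: float, k12: float, k21: float,
                   grid: Sequence[float]) -> SensitivityCurves:
    """TSFs of a tracer timecourse output with respect to (FCR, k12, k21).

    Integrates the forward sensitivity system: alongside the two tracer
    states, the six partial-derivative states obey
    d/dt ∂x/∂θ = A ∂x/∂θ + (∂A/∂θ) x.  All sensitivities vanish at
    t = 0 because the initial condition is parameter-free.
    """
    if output not in ("y1", "y2"):
        raise ValueError("timecourse output must be 'y1' or 'y2'")
    grid = np.asarray(grid, dtype=float)
    A = np.array([[-(k21 + FCR), k12], [k21, -k12]])
    # ∂A/∂θ for θ = FCR, k12, k21
    dA = {
        "FCR": np.array([[-1.0, 0.0], [0.0, 0.0]]),
        "k12": np.array([[0.0, 1.0], [0.0, -1.0]]),
        "k21": np.array([[-1.0, 0.0], [1.0, 0.0]]),
    }

    def rhs(t, z):
        x = z[:2]
        out = np.empty_like(z)
        out[:2] = A @ x
        for i, name in enumerate(_TIMECOURSE_PARAMS):
            s = z[2 + 2 * i: 4 + 2 * i]
            out[2 + 2 * i: 4 + 2 * i] = A @ s + dA[name] @ x
        return out

    z0 = np.zeros(8)
    z0[0] = 1.0
    t_span = (0.0, float(grid[-1]) if grid[-1] > 0 else 1.0)
    sol = solve_ivp(rhs, t_span, z0, t_eval=grid, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise IntegrationError(f"sensitivity integration failed: {sol.message}")

    curves = {}
    for i, name in enumerate(_TIMECOURSE_PARAMS):
        s1 = sol.y[2 + 2 * i]
        s2 = sol.y[3 + 2 * i]
        curves[name] = s1 if output == "y1" else s1 + s2
    return SensitivityCurves(abscissa=grid, curves=curves, kind="TSF",
                             output=output)


def _macro_gradients(output: str, params: MetabolicParameters,
                     x_grid: np.ndarray) -> dict:
    """Analytic partials of FCR or T½ with respect to the five micro
    parameters, vectorized over the x1E grid."""
    k12, k21, k31, Vmax, KM = (params.k12, params.k21, params.k31,
                               params.Vmax, params.KM)
    denom = KM + x_grid
    F = k31 - Vmax / denom
    dF = {"k12": np.zeros_like(x_grid), "k21": np.zeros_like(x_grid),
          "k31": np.ones_like(x_grid), "Vmax": -1.0 / denom,
          "KM": Vmax / denom ** 2}
    if output == "FCR":
        # the FCR does not depend on the exchange rates, so its
        # sensitivity analysis is over (k31, Vmax, KM) only
        return {name: dF[name] for name in ("k31", "Vmax", "KM")}
    # T½ = 2 ln2 / g with g = s − r, s = k12 + k21 + F, r = sqrt(s² − 4 k12 F)
    s = k12 + k21 + F
    r = np.sqrt(s * s - 4.0 * k12 * F)
    g = s - r
    T = 2.0 * np.log(2.0) / g
    grads = {}
    for name in _MACRO_PARAMS:
        ds = dF[name] + (1.0 if name in ("k12", "k21") else 0.0)
        dk12 = 1.0 if name == "k12" else 0.0
        dr = (s * ds - 2.0 * (F * dk12 + k12 * dF[name])) / r
        grads[name] = -(T / g) * (ds - dr)
    return grads


def tsf(output: str, params: MetabolicParameters,
        grid: Sequence[float], x1E: Optional[float] = None) -> SensitivityCurves:
    """TSF curves of a model output on the given grid.

    ``output`` selects 'y1'/'y2' (tracer timecourse; grid in days,
    requires ``x1E`` to fix the FCR; parameters (FCR, k12, k21)) or
    'FCR'/'T_half' (macro curves; grid in µmol of x1E; parameters
    (k12, k21, k31, Vmax, KM), computed analytically).
    """
    params.validate()
    grid = np.asarray(grid, dtype=float)
    if output in ("y1", "y2"):
        if x1E is None:
            raise ValueError("x1E is required for timecourse outputs")
        return tsf_timecourse(output, fcr(params, x1E),
                              params.k12, params.k21, grid)
    if output in ("FCR", "T_half"):
        curves = _macro_gradients(output, params, grid)
        return SensitivityCurves(abscissa=grid, curves=curves, kind="TSF",
                                 output=output)
    raise ValueError(f"unknown output {output!r}")


def normalized_tsf(curves: SensitivityCurves,
                   parameter_values: dict) -> SensitivityCurves:
    """Scale each TSF by its parameter value, giving the sensitivity to
    proportional parameter variation (useful when parameter magnitudes
    span orders of magnitude)."""
    if curves.kind != "TSF":
        raise ValueError("normalized_tsf expects TSF curves")
    scaled = {name: np.asarray(curve) * parameter_values[name]
              for name, curve in curves.curves.items()}
    return SensitivityCurves(abscissa=curves.abscissa, curves=scaled,
                             kind="normalized-TSF", output=curves.output)


def fisher_information(gradients: np.ndarray, variances: Sequence[float],
                       parameter_names: Optional[list] = None,
                       grid: Optional[np.ndarray] = None) -> FisherMatrix:
    """Fisher information matrix from per-sample gradient vectors.

    ``gradients`` is (n_samples, n_params); the matrix is the sum of
    outer products weighted by 1/σ²(t_j).  Scaling all variances by a
    common factor rescales F but leaves the GSFs unchanged.
    """
    G = np.asarray(gradients, dtype=float)
    var = np.asarray(variances, dtype=float)
    if G.ndim != 2 or var.shape != (G.shape[0],):
        raise ValueError("gradients must be (n_samples, n_params) with one variance per sample")
    if np.any(var <= 0):
        raise ValueError("variances must be strictly positive")
    F = (G / var[:, None]).T @ G
    names = parameter_names or [f"theta{i}" for i in range(G.shape[1])]
    return FisherMatrix(matrix=F, parameter_names=names,
                        grid=grid if grid is not None else np.arange(G.shape[0]),
                        variances=var)


def _gsf_from_gradients(G: np.ndarray, names: list, variances: np.ndarray,
                        sample_grid: np.ndarray, output: str) -> SensitivityCurves:
    fisher = fisher_information(G, variances, parameter_names=names,
                                grid=sample_grid)
    if fisher.condition_number > CONDITION_NUMBER_THRESHOLD:
        raise IllConditionedFisher(fisher.condition_number)
    # per-sample contribution (1/σ²) (F⁻¹ g_i) ⊙ g_i, accumulated
    solved = linalg_solve(fisher.matrix, G.T, assume_a="sym")  # (p, n)
    contrib = solved.T * G / variances[:, None]
    cumulative = np.cumsum(contrib, axis=0)
    curves = {name: cumulative[:, j] for j, name in enumerate(names)}
    return SensitivityCurves(abscissa=sample_grid, curves=curves,
                             kind="GSF", output=output)


def gsf_timecourse(output: str, FCR: float, k12: float, k21: float,
                   sample_grid: Sequence[float],
                   variances: Optional[Sequence[float]] = None) -> SensitivityCurves:
    """GSFs of a tracer timecourse output for a subject given directly by
    the identifiable triple (FCR, k12, k21)."""
    sample_grid = np.asarray(sample_grid, dtype=float)
    if variances is None:
        variances = np.ones_like(sample_grid)
    variances = np.asarray(variances, dtype=float)
    curves = tsf_timecourse(output, FCR, k12, k21, sample_grid)
    return _gsf_from_gradients(curves.gradient_matrix(),
                               curves.parameter_names, variances,
                               sample_grid, output)


def gsf(output: str, params: MetabolicParameters,
        sample_grid: Sequence[float], variances: Optional[Sequence[float]] = None,
        x1E: Optional[float] = None) -> SensitivityCurves:
    """GSF curves of a model output on a discrete sample grid.

    Equal error variances (the default, σ² = 1) cancel between the
    Fisher matrix and the cumulative sum.  Raises
    :class:`IllConditionedFisher` when the Fisher matrix condition
    number exceeds ``CONDITION_NUMBER_THRESHOLD``.
    """
    sample_grid = np.asarray(sample_grid, dtype=float)
    if variances is None:
        variances = np.ones_like(sample_grid)
    variances = np.asarray(variances, dtype=float)

    tsf_curves = tsf(output, params, sample_grid, x1E=x1E)
    return _gsf_from_gradients(tsf_curves.gradient_matrix(),
                               tsf_curves.parameter_names, variances,
                               sample_grid, output)
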