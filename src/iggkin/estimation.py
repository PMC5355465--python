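"""Weighted nonlinear least-squares estimation of IgG kinetic parameters.

Two fitting problems are supported:

* per-subject tracer timecourse fits in the structurally identifiable
  parameterization (FCR, k12, k21), with the plasma and whole-body
  outputs fitted simultaneously;
* pooled population fits of (k31, Vmax, KM, k12, k21) to FCR-vs-x1E and
  T½-vs-x1E data jointly, with the T½ residuals down-weighted to
  account for the very different scales of the two outputs.

Standard errors come from the Gauss–Newton covariance
σ̂² (JᵀJ)⁻¹ of the *unconstrained* local quadratic model at the optimum
(even when positivity bounds are active), so confidence intervals can
legitimately cross zero for poorly determined parameters; σ̂² = SSR/(n−p)
and intervals use Student-t quantiles with n − p degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .kinetics import DEFAULT_PARAMETERS, MetabolicParameters, linear_solution_from_macro
from .macro import MacroDataset, TimecourseDataset, estimate_fcr_from_timecourse

__all__ = [
    "FitResult",
    "PopulationSummary",
    "EstimationError",
    "fit_timecourse",
    "fit_macro_joint",
    "fit_macro_fixed",
    "summarize_population",
]


class EstimationError(RuntimeError):
    """Optimization failed to converge; carries best-found diagnostics."""


@dataclass
class FitResult:
    """Point estimates with uncertainty for one least-squares fit."""

    parameter_names: list
    estimates: np.ndarray
    standard_errors: np.ndarray
    confidence_intervals: np.ndarray  # (p, 2), 95% by default
    correlation_matrix: np.ndarray
    rmse: float
    residual_variance: float
    n_observations: int
    degrees_of_freedom: int
    weights: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.parameter_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.parameter_names.index(name)])

    def correlation(self, a: str, b: str) -> float:
        i, j = self.parameter_names.index(a), self.parameter_names.index(b)
        return float(self.correlation_matrix[i, j])

    def to_dict(self) -> dict:
        return {
            "parameters": dict(zip(self.parameter_names, self.estimates.tolist())),
            "standard_errors": dict(zip(self.parameter_names,
                                        self.standard_errors.tolist())),
            "confidence_intervals": {
                name: self.confidence_intervals[i].tolist()
                for i, name in enumerate(self.parameter_names)},
            "correlation_matrix": self.correlation_matrix.tolist(),
            "rmse": self.rmse,
            "residual_variance": self.residual_variance,
            "n_observations": self.n_observations,
            "degrees_of_freedom": self.degrees_of_freedom,
            "weights": self.weights,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary_table(self) -> str:
        lines = [f"{'parameter':>10} {'estimate':>12} {'SE':>12} {'95% CI':>26}"]
        for i, name in enumerate(self.parameter_names):
            lo, hi = self.confidence_intervals[i]
            lines.append(f"{name:>10} {self.estimates[i]:>12.4g} "
                         f"{self.standard_errors[i]:>12.3g} "
                         f"({lo:>10.4g}, {hi:>10.4g})")
        lines.append(f"RMSE = {self.rmse:.4g}  (n = {self.n_observations})")
        return "\n".join(lines)


@dataclass
class PopulationSummary:
    """Two-stage population summary: per-parameter mean and median of
    per-subject estimates."""

    parameter_names: list
    mean: dict
    median: dict
    n_subjects: int


def _uncertainty(jac: np.ndarray, residuals: np.ndarray,
                 confidence: float = 0.95):
    """Gauss–Newton covariance, SEs, t-based CIs and correlation matrix
    at a least-squares optimum (residuals and jac already weighted)."""
    n, p = jac.shape[0], jac.shape[1]
    dof = max(n - p, 1)
    ssr = float(residuals @ residuals)
    sigma2 = ssr / dof
    JtJ = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
        regularized = False
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JtJ)
        regularized = True
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(se, se)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
    return cov, se, corr, sigma2, ssr, tq, regularized


def _log_uniform_starts(reference: np.ndarray, n_starts: int, seed: int,
                        span: float = 1e3) -> np.ndarray:
    rng = np.random.default_rng(seed)
    lo = np.log(reference / span)
    hi = np.log(reference * span)
    return np.exp(rng.uniform(lo, hi, size=(n_starts, reference.size)))


def fit_timecourse(data: TimecourseDataset,
                   init: Optional[Sequence[float]] = None,
                   n_starts: int = 3, seed: int = 0) -> FitResult:
    """Fit (FCR, k12, k21) to one subject's tracer timecourse.

    Minimizes the unweighted sum of squared residuals of the stacked
    plasma (y1) and whole-body (y2) outputs using the analytic
    bi-exponential solution.  The first start is data-driven (pooled FCR
    estimate from the whole-body slope, mid-range exchange rates);
    further starts are drawn log-uniformly if needed.
    """
    if data.times.size * 2 < 6:
        raise ValueError("need at least 6 observations across both outputs")
    y_obs = np.concatenate([data.y1_obs, data.y2_obs])

    def residual(theta):
        f, k12, k21 = theta
        x1P, x2P = linear_solution_from_macro(k12, k21, f, data.times)
        return np.concatenate([x1P, x1P + x2P]) - y_obs

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        fcr0 = estimate_fcr_from_timecourse(data).pooled
        fcr0 = min(max(fcr0, 1e-3), 2.0)
        starts = [np.array([fcr0, 0.4, 0.4])]
    starts.extend(_log_uniform_starts(np.array([0.08, 0.4, 0.4]),
                                      n_starts, seed))

    lower = np.full(3, 1e-6)
    upper = np.full(3, 1e3)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(residual, x0, bounds=(lower, upper),
                                x_scale="jac", xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15 or (
                abs(res.cost - best.cost) <= 1e-15
                and np.linalg.norm(res.x) < np.linalg.norm(best.x)):
            best = res
        # a zero-residual (noise-free) optimum cannot be improved
        if best.cost < 1e-18:
            break
    if best is None:
        raise EstimationError("timecourse fit failed from every start")

    cov, se, corr, sigma2, ssr, tq, reg = _uncertainty(best.jac, best.fun)
    names = ["FCR", "k12", "k21"]
    ci = np.column_stack([best.x - tq * se, best.x + tq * se])
    return FitResult(
        parameter_names=names,
        estimates=best.x.copy(),
        standard_errors=se,
        confidence_intervals=ci,
        correlation_matrix=corr,
        rmse=float(np.sqrt(ssr / y_obs.size)),
        residual_variance=sigma2,
        n_observations=int(y_obs.size),
        degrees_of_freedom=int(y_obs.size - 3),
        weights={"y1": 1.0, "y2": 1.0},
        diagnostics={"subject_id": data.subject_id, "cost": float(best.cost),
                     "covariance_regularized": reg,
                     "optimizer_status": int(best.status)},
    )


_MACRO_NAMES = ["k31", "Vmax", "KM", "k12", "k21"]


def _macro_model(theta_full: np.ndarray, x_fcr: np.ndarray,
                 x_thalf: np.ndarray) -> Optional[tuple[np.ndarray, np.ndarray]]:
    k31, Vmax, KM, k12, k21 = theta_full
    if min(k31, Vmax, KM, k12, k21) <= 0:
        return None
    f_fcr = k31 - Vmax / (KM + x_fcr)
    f_th = k31 - Vmax / (KM + x_thalf)
    if np.any(f_fcr <= 0) or np.any(f_th <= 0):
        return None
    s = k12 + k21 + f_th
    thalf = 2.0 * np.log(2.0) / (s - np.sqrt(s * s - 4.0 * k12 * f_th))
    return f_fcr, thalf


def _resolve_weights(data: MacroDataset, weight_rule) -> tuple[float, float, dict]:
    """Weight of each T½ residual relative to the (unit-weight) FCR
    residuals.

    'inverse_variance' (default): residual standard deviations are taken
    proportional to the typical size of each output, so the T½ residual
    variance is (mean T½ / mean FCR)² times the FCR residual variance
    and the T½ weight is the reciprocal, (mean FCR / mean T½)².
    'literal_reciprocal': the transposed rule (mean T½ / mean FCR)².
    A numeric value is used as-is.
    """
    _, f_obs = data.fcr_records
    _, t_obs = data.thalf_records
    ratio = (np.mean(f_obs) / np.mean(t_obs)) ** 2
    if weight_rule == "inverse_variance":
        w_t = ratio
    elif weight_rule == "literal_reciprocal":
        w_t = 1.0 / ratio
    elif isinstance(weight_rule, (int, float)):
        w_t = float(weight_rule)
    else:
        raise ValueError(f"unknown weight rule {weight_rule!r}")
    info = {"w_fcr": 1.0, "w_thalf": w_t, "rule": str(weight_rule),
            "implied_variance_ratio": 1.0 / ratio}
    return 1.0, w_t, info


def _fit_macro(data: MacroDataset, free: list, fixed: dict,
               weight_rule, n_starts: int, seed: int,
               reference: MetabolicParameters) -> FitResult:
    x_fcr, f_obs = data.fcr_records
    x_th, t_obs = data.thalf_records
    if x_fcr.size < 5 or x_th.size < 5:
        raise ValueError("need at least 5 FCR and 5 T½ records")
    for x in (x_fcr, x_th):
        if np.max(x) / np.min(x) < 10.0:
            raise ValueError("x1E range must span at least a 10-fold range")

    w_f, w_t, weight_info = _resolve_weights(data, weight_rule)
    sw = np.concatenate([np.full(x_fcr.size, np.sqrt(w_f)),
                         np.full(x_th.size, np.sqrt(w_t))])
    y_obs = np.concatenate([f_obs, t_obs])

    ref_full = {"k31": reference.k31, "Vmax": reference.Vmax,
                "KM": reference.KM, "k12": reference.k12,
                "k21": reference.k21}
    free_idx = [_MACRO_NAMES.index(name) for name in free]

    def expand(theta):
        full = np.array([fixed.get(n, ref_full[n]) for n in _MACRO_NAMES])
        full[free_idx] = theta
        return full

    big = 1e8

    def residual(theta):
        model = _macro_model(expand(theta), x_fcr, x_th)
        if model is None:
            return np.full(y_obs.size, big)
        return (np.concatenate(model) - y_obs) * sw

    ref_free = np.array([ref_full[n] for n in free])
    starts = [ref_free] + list(_log_uniform_starts(ref_free, n_starts - 1, seed))
    lower = ref_free * 1e-4
    upper = ref_free * 1e4

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower, upper)
        try:
            res = least_squares(residual, x0, bounds=(lower, upper),
                                x_scale="jac", xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        if np.any(res.fun >= big):
            continue
        if best is None or res.cost < best.cost - 1e-15 or (
                abs(res.cost - best.cost) <= 1e-15
                and np.linalg.norm(res.x) < np.linalg.norm(best.x)):
            best = res
    if best is None:
        raise EstimationError("macro fit failed from every start")

    cov, se, corr, sigma2, ssr, tq, reg = _uncertainty(best.jac, best.fun)
    ci = np.column_stack([best.x - tq * se, best.x + tq * se])
    diagnostics = {"cost": float(best.cost), "covariance_regularized": reg,
                   "optimizer_status": int(best.status),
                   "fixed": dict(fixed)}
    if reg:
        diagnostics["warning"] = "ill-conditioned normal equations; covariance regularized"
    return FitResult(
        parameter_names=list(free),
        estimates=best.x.copy(),
        standard_errors=se,
        confidence_intervals=ci,
        correlation_matrix=corr,
        rmse=float(np.sqrt(ssr / y_obs.size)),
        residual_variance=sigma2,
        n_observations=int(y_obs.size),
        degrees_of_freedom=int(y_obs.size - len(free)),
        weights=weight_info,
        diagnostics=diagnostics,
    )


def fit_macro_joint(data: MacroDataset, weight_rule="inverse_variance",
                    n_starts: int = 20, seed: int = 0,
                    reference: MetabolicParameters = DEFAULT_PARAMETERS) -> FitResult:
    """Jointly fit (k31, Vmax, KM, k12, k21) to pooled FCR and T½ data.

    FCR residuals carry unit weight; T½ residuals are weighted per
    ``weight_rule`` (see :func:`_resolve_weights`).  Multi-start bounded
    trust-region least squares guards against the strong correlations
    between the exchange parameters.
    """
    return _fit_macro(data, list(_MACRO_NAMES), {}, weight_rule,
                      n_starts, seed, reference)


def fit_macro_fixed(data: MacroDataset, fixed: dict,
                    weight_rule="inverse_variance", n_starts: int = 20,
                    seed: int = 0,
                    reference: MetabolicParameters = DEFAULT_PARAMETERS) -> FitResult:
    """Fit the macro data with some parameters frozen (typically k12 and
    k21 fixed to their timecourse-derived population means)."""
    unknown = set(fixed) - set(_MACRO_NAMES)
    if unknown:
        raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
    free = [n for n in _MACRO_NAMES if n not in fixed]
    return _fit_macro(data, free, dict(fixed), weight_rule, n_starts,
                      seed, reference)


def summarize_population(results: Sequence[FitResult]) -> PopulationSummary:
    """Arithmetic mean and sample median of each parameter across
    per-subject fits (a two-stage population summary)."""
    if not results:
        raise ValueError("need at least one fit result")
    names = results[0].parameter_names
    for r in results[1:]:
        if r.parameter_names != names:
            raise ValueError("inconsistent parameter sets across results")
    stacked = np.vstack([r.estimates for r in results])
    return PopulationSummary(
        parameter_names=list(names),
        mean={n: float(np.mean(stacked[:, i])) for i, n in enumerate(names)},
        median={n: float(np.median(stacked[:, i])) for i, n in enumerate(names)},
        n_subjects=len(results),
    )
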