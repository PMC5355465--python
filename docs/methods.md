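# Methods

## Model

Endogenous IgG metabolism is described by a two-compartment model in
which plasma IgG `x1` (µmol) exchanges with a peripheral pool `x2` at
rates `k21` (plasma→tissue) and `k12` (tissue→plasma), enters
intracellular endosomes at rate `k31`, and is rescued from degradation
by FcRn at the saturable fractional rate `Vmax/(KM + x1)`:

    dx1/dt = −(k21 + k31 − Vmax/(KM + x1)) x1 + k12 x2 + I(t)
    dx2/dt = k21 x1 − k12 x2.

The endosomal compartment itself is not modelled; recycling appears as a
reduction of the elimination rate. At constant production `I0` the
positive equilibrium has the closed form implemented in
`kinetics.steady_state`, with `x̂2 = (k21/k12) x̂1`. Linearizing about
the equilibrium and applying the Routh–Hurwitz criterion shows the
equilibrium is stable for every admissible parameter set; admissibility
means all parameters strictly positive and `k31 − Vmax/KM > 0` (net
elimination positive at all plasma levels). `kinetics.is_stable` is the
single validator every operation calls, and names the first violated
condition.

### Tracer kinetics and linearization

A tracer study administers a radiolabelled bolus `D` (µmol) on top of
the endogenous steady state and observes the fractions of the dose in
plasma (`y1`) and in the whole body (`y2`). Labelled and unlabelled IgG
share the recycling machinery, so the exact description is a coupled
4-state system whose saturable term depends on total plasma IgG. For
doses much smaller than the endogenous plasma quantity `x1E` the term is
effectively `Vmax/(KM + x1E)` and the tracer follows a *linear*
two-compartment system whose solution is bi-exponential with
eigenvalues `λ1 < λ2 < 0` (`λ1λ2 = k12·FCR`,
`λ1+λ2 = −(k12+k21+FCR)`). With positive `k21` the discriminant
`(k12−FCR)² + k21² + 2k21(k12+FCR)` is strictly positive, so the
repeated-eigenvalue branch is unreachable for valid parameters; the
confluent `t·e^{λt}` form is nevertheless implemented behind the same
interface for degenerate inputs supplied directly.

`kinetics.linearization_error` quantifies the approximation as the
maximum over sample times of `|y1_nonlinear − y1_linear|/y1_linear`,
i.e. the worst-case relative deviation of the plasma curve. At a
realistic dose (0.01 µmol against 5 µmol endogenous plasma IgG) it is
~4×10⁻⁵; at 10 µmol it is ~3×10⁻², a thousandfold dose raising the
discrepancy by roughly three orders of magnitude. The full coupled
system (endogenous state re-equilibrating) is the default; a
frozen-endogenous variant is available because large-dose simulations
are sensitive to that choice in principle, though the two differ by
<10⁻⁶ at tracer-scale doses.

### Macro constants

`FCR = k31 − Vmax/(KM + x1E)` is the fraction of plasma IgG catabolized
per day; it increases with `x1E` toward the asymptote `k31`. The
terminal half-life is `T½ = −ln2/λ2`; expressed through
`(k12, k21, FCR)` it is `2 ln2 / (s − sqrt(s² − 4 k12 FCR))` with
`s = k12+k21+FCR`, and it decreases with `x1E`. The fractional
recycling rate is the complement `FRR = k31 − FCR = Vmax/(KM + x1E)`;
the classical double-reciprocal plot of the absolute recycling rate per
kg against `w/x1E` is linear with intercept `w/Vmax` and slope
`KM/Vmax`, and `macro.waldmann_reciprocal_fit` implements that route as
unweighted ordinary least squares, the historical method having used no
weights.

Direct estimation from a timecourse follows the classical definitions:
the FCR at any `t > 0` is the rate the dose leaves the body divided by
the dose fraction in plasma, implemented per consecutive sample pair as
`−Δy2/Δt ÷ ȳ1` and pooled over intervals whose midpoint lies beyond a
distribution cutoff (default 5 days — early intervals are dominated by
plasma↔tissue exchange, for which the definition is biased); T½ comes
from the least-squares slope of `ln y1` on a terminal window (default:
the last half of the sampling span; both defaults are configurable
because the historical extraction windows were never recorded).

## Units

Internal units are µmol, days and µmol/day throughout. Conversions to
serum concentrations use a molar mass of 0.15 g/µmol (150 kDa), an
average plasma volume of 3 l and an average body weight of 70 kg,
carried in one explicit `UnitConstants` value object (per-subject
plasma volumes are out of scope; the historical analyses used a single
average).

## Structural identifiability

The linear tracer model's transfer-function matrix has the four
distinct coefficients `Φ = (k12, k12+k21, k12·FCR, FCR+k12+k21)`, which
exhaust what ideal timecourse data can reveal. Hence:

| observation              | globally identifiable          |
|--------------------------|--------------------------------|
| single timecourse        | k12, k21 (and the FCR)         |
| FCR vs x1E               | k31, Vmax, KM                  |
| T½ vs x1E                | k12, k21, k31, Vmax, KM        |

The package establishes these verdicts numerically rather than
symbolically. For the timecourse setting it *constructs* a witness: an
alternative `(k31, Vmax, KM, x1E)` with the same FCR (shrinking the
alternative `Vmax` until the admissibility constraint holds) whose
simulated outputs are verified to coincide with the original's. For the
curve settings it runs multi-start bounded least squares (starts
log-uniform in `[10⁻⁴, 10⁴]` × the true values) and reports whether any
distinct zero-residual solution exists — evidence, not proof. The T½
objective has a curved, nearly flat valley (Fisher condition number
~10¹⁶ at realistic parameters), so bounded trust-region steps stall
there; promising candidates are therefore polished with an
unconstrained Levenberg–Marquardt refinement, after which a genuine
solution reaches residuals near machine zero while valley points do
not. The zero-residual threshold (RMS < 10⁻⁷ days) sits far below the
residual any point more than ~10⁻⁵ away (relative) from the true vector
can attain on this curve, so the classification cannot mistake valley
points for alternative solutions. Identifiability of the full
*nonlinear* coupled tracer model is an open problem and deliberately
not analyzed; the corresponding stub raises `NotImplementedError`.

## Sensitivity analysis

Traditional sensitivity functions (TSFs) are exact: timecourse outputs
are differentiated with respect to `(FCR, k12, k21)` by integrating the
forward sensitivity equations alongside the state (tolerances 10⁻¹⁰ /
10⁻¹²), and the macro outputs FCR and T½ are differentiated
analytically with respect to the micro parameters (FCR depends only on
`k31, Vmax, KM`, so its analysis is over those three). Every TSF route
is cross-checked against central finite differences in the tests
(agreement ~10⁻⁹, asserted at 10⁻⁴).

Generalized sensitivity functions accumulate the Fisher-weighted
information `Σ_{i≤l} (1/σ²) [F⁻¹∇f(t_i)]⊙∇f(t_i)` on a discrete grid;
each curve equals exactly 1 at the final sample and its interval of
steep rise marks where the data inform that parameter. Default grids:
0.1-day spacing over the observation span for timecourses, and 10 µmol
steps from 10 to 2000 µmol for the macro curves (the grid start is
configurable; the FCR is finite at zero, but 10 µmol avoids giving the
degenerate zero-concentration point special status). Error variances
default to equal (σ² = 1) and cancel; GSFs are invariant under any
uniform rescaling of σ². The Fisher matrix is symmetrized and solved
with a stable symmetric solve rather than an explicit inverse; if its
condition number exceeds 10¹² an `IllConditionedFisher` error carrying
the condition number is raised — which is exactly what happens for the
T½ curve at the pooled parameter estimates (condition number ~6×10¹⁵),
reflecting the near-total correlation of all five parameters along that
output. For typical slow-eliminating subjects the timecourse GSFs rise
in the order `k21`, `k12`, FCR: the bolus distributes into tissue
first, returns, and is then eliminated. The FcRn-deficient,
hypercatabolic subject in the reference panel does not follow that
ordering — its elimination is as fast as its distribution — and the
tests treat it accordingly.

## Estimation

Timecourse fits minimize the unweighted sum of squared residuals of the
stacked `y1` and `y2` outputs, using the analytic bi-exponential
solution parameterized directly by the structurally identifiable triple
`(FCR, k12, k21)` — never by the unidentifiable quadruple. Starting
values are data-driven (pooled FCR estimate from the body-fraction
slope, mid-range exchange rates), with a small number of log-uniform
multi-starts as a fallback.

The pooled macro fit estimates `(k31, Vmax, KM, k12, k21)` from FCR and
T½ curves simultaneously. Because the two outputs live on scales that
differ by ~300×, T½ residuals are down-weighted: assuming residual
standard deviations proportional to the typical size of each output,
the T½ residual variance is `(mean T½ / mean FCR)²` times the FCR
residual variance (~10⁵ for typical data), and inverse-variance
weighting gives `w_T½ = (mean FCR / mean T½)²` with `w_FCR = 1`. The
transposed convention (weights equal to the variance ratio rather than
its reciprocal) is available as `weight_rule="literal_reciprocal"` for
comparison, since both conventions appear in the turnover literature;
inverse-variance is the default because it is the one that actually
equalizes the two outputs' influence. The optimizer is bounded
trust-region least squares with 20 multi-starts drawn log-uniformly
within `[10⁻³, 10³]` × a reference parameter set, tie-broken by lowest
objective then lowest parameter norm — the exchange rates are ~99.6%
correlated in this fit and multi-start guards against their local
minima.

Uncertainty everywhere comes from the Gauss–Newton covariance
`σ̂²(JᵀJ)⁻¹` with `σ̂² = SSR/(n−p)` and Student-t 95% intervals on
`n−p` degrees of freedom. Positivity is enforced through bounds rather
than log-transforms so that standard errors remain on the natural
scale, and the covariance is evaluated from the unconstrained local
quadratic model even when bounds are active — this is why confidence
intervals for poorly determined parameters (the exchange rates in the
macro fit) can legitimately cross zero. Per-subject results are
summarized across subjects by mean and median (a two-stage population
summary); full nonlinear mixed-effects modelling is out of scope.

## Myeloma simulations

Monoclonal and polyclonal IgG are kinetically identical and share the
saturable recycling term `Vmax/(KM + x1m + x1p)`, giving a 4-state
system whose clone sum exactly follows the single-species model with
summed production — a conservation property the tests verify to
<10⁻⁶ µmol over a year for all six packaged scenarios (solver LSODA,
rtol 10⁻¹⁰, atol 10⁻¹²). Monoclonal production follows the
phenomenological tumor-kill schedule
`Im(t) = (Im0 − Im_inf) e^{−k_kill t} + Im_inf`; polyclonal production
stays at the normal 15 µmol/day. Initial conditions place the total at
its steady state with each clone holding a production-proportional
share, which zeroes all four derivatives. Output is sampled weekly over
365 days by default, matching routine serum protein electrophoresis
monitoring, and converted to g/l with the standard unit constants. Two
qualitative consequences of saturable recycling are exposed and tested:
the serum M-protein's terminal half-life exceeds the production
half-life `ln2/k_kill` (metabolism slows as total IgG falls), and the
polyclonal component transiently rises above its pre-treatment level
during response. Tumor-burden modelling, polyclonal suppression and
therapeutic-antibody pharmacokinetics are explicitly out of scope.

## Synthetic data

The generators produce every input the pipeline consumes, emulating the
historical data's structure: bi-exponential tracer decay observed as
two dose-fraction outputs on a realistic design (samples at 0.25, 0.5,
1, then daily to 30 days; dose 0.005 µmol), population FCR/T½ scatter
across log-uniform plasma quantities on [30, 2000] µmol (≈1.5–100 g/l)
with log-normal inter-subject variation (CV 20%) in the exchange rates
about means 0.38/0.42 and shared elimination parameters, and weekly
M-protein series from the treatment scenarios. The error structure of
1960s radioactivity counting is unknown; noise is proportional Gaussian
by explicit assumption, CV 3% for timecourses and 10% for macro
outputs — large enough that recovery is non-trivial, small enough that
the historical fits' reported precision remains representative. All
draws are seeded and byte-reproducible.

What passing recovery tests show — and what they do not: they establish
that the estimation machinery is correct and well-calibrated *under the
assumed model and noise*. Real tracer data add plot-digitization error,
model misspecification (no endosomal compartment, a single average
plasma volume) and non-Gaussian counting error, none of which the
generator emulates; recovery on synthetic data therefore bounds, but
does not demonstrate, performance on the historical measurements.

## Numerical choices and degenerate inputs

* ODE integration: LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰ for tracer
  simulations (half-lives span 10–70 days while distribution acts on
  ~1 day), tightened to 10⁻¹⁰/10⁻¹² where µmol-level conservation is
  asserted.
* `steady_state` at `I0 = 0` returns the origin (the closed form's
  positive root collapses); `half_life_from_fcr` returns `+inf` as
  FCR → 0.
* Validation is centralized and fails fast with the violated condition
  named; readers report 1-based row numbers and the offending column.
* Problem sizes in the tests (100 synthetic subjects for recovery, 40
  macro design points, 25-point identifiability grids, 30–100
  multi-starts) were chosen so the full suite characterizes the
  estimators while running in well under a minute of numerical work per
  module.

## Known limitations

* The elimination parameters are practically near-unidentifiable from
  T½ data alone despite structural identifiability; the joint FCR+T½
  fit is the supported route.
* The per-parameter precision of timecourse fits at 3% noise is
  ~4–5% (median) for the exchange rates — an information limit of the
  30-day design, consistent with the historical standard errors.
* Steady-state initial conditions for the myeloma scenarios ignore
  tumor growth before treatment; relapse schedules (`Im_inf > Im0`) are
  permitted but the steady-state premise then deserves scrutiny.
* The model omits an explicit endosomal compartment and uses a single
  average plasma volume; both are deliberate simplifications inherited
  from the classical analyses it reimplements.
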