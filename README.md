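# iggkin

Compartmental analysis of endogenous immunoglobulin G (IgG) metabolism in
humans, with application to serum M-protein dynamics in IgG multiple
myeloma.

## The problem

IgG has an unusually long and concentration-dependent half-life because
the neonatal Fc receptor (FcRn) rescues it from lysosomal degradation by
a saturable, Michaelis–Menten-like recycling process. At high plasma IgG
the receptors saturate, a larger fraction of IgG is degraded, and the
half-life shortens; at low IgG the half-life extends. This matters
clinically: in IgG multiple myeloma the serum monoclonal IgG
("M-protein") is the standard surrogate for tumor burden, yet its
concentration-dependent metabolism distorts the mapping between tumor
kill and serum response.

`iggkin` is aimed at modellers and pharmacometricians working with
plasma-protein turnover data: it implements the standard two-compartment
model of IgG metabolism, the linearized tracer kinetics used to analyse
historical radiolabel studies, structural identifiability and
sensitivity diagnostics, weighted least-squares parameter estimation,
and clone-resolved simulations of M-protein responses during myeloma
treatment. A seeded synthetic-data generator reproduces the statistical
structure of the historical datasets, which were only ever published as
plots.

## The model

Plasma IgG `x1` (µmol) exchanges with a peripheral compartment `x2` and
is eliminated with saturable FcRn rescue:

    dx1/dt = −(k21 + k31 − Vmax/(KM + x1)) x1 + k12 x2 + I(t)
    dx2/dt = k21 x1 − k12 x2

with synthesis `I(t)` (µmol/day), exchange rates `k12`, `k21` (day⁻¹),
endosomal uptake `k31` (day⁻¹), maximum recycling rate `Vmax`
(µmol/day) and Michaelis constant `KM` (µmol). The unique positive
equilibrium is stable whenever all parameters are positive and
`k31 − Vmax/KM > 0`.

Two macro constants connect the model to data: the fractional catabolic
rate `FCR = k31 − Vmax/(KM + x1E)` and the terminal half-life
`T½ = −ln2/λ2`, with `λ2` the slow eigenvalue of the linearized tracer
system at endogenous plasma level `x1E`. A single tracer timecourse
identifies only `(k12, k21, FCR)`; the curves of FCR and T½ against
`x1E` across subjects identify the remaining elimination parameters.

## Worked example

```python
import numpy as np
from iggkin import (DEFAULT_PARAMETERS, fcr, half_life,
                    generate_subject, fit_timecourse, NoiseModel)

p = DEFAULT_PARAMETERS   # k12=0.38, k21=0.42, k31=0.16, Vmax=40, KM=270
print(f"FCR at x1E = 200 umol : {fcr(p, 200.0):.4f} /day")
print(f"T1/2 at x1E = 200 umol: {half_life(p, 200.0):.2f} days")

data = generate_subject(p, x1E=200.0, noise=NoiseModel(scale=0.03, seed=42))
print(fit_timecourse(data).summary_table())
```

prints

```
FCR at x1E = 200 umol : 0.0749 /day
T1/2 at x1E = 200 umol: 20.48 days
 parameter     estimate           SE                     95% CI
       FCR      0.07484     0.000606 (   0.07363,    0.07605)
       k12       0.3846       0.0162 (    0.3522,      0.417)
       k21       0.4265       0.0166 (    0.3934,     0.4597)
RMSE = 0.01155  (n = 64)
```

At a typical plasma quantity of 200 µmol (10 g/l) about 7.5% of plasma
IgG is catabolized per day and the half-life is ~20 days. The synthetic
subject's tracer curves (3% proportional noise) are fitted in the
structurally identifiable parameterization; all three estimates recover
the generating values well within their 95% confidence intervals, with
standard errors a few percent of the estimates — the same precision seen
in fits to the historical subjects.

A command-line interface exposes the same pipeline
(`iggkin simulate-tracer`, `fit-timecourse`, `fit-macro`,
`sensitivity`, `gsf`, `identifiability`, `simulate-myeloma`,
`generate-synthetic`); every run writes a JSON manifest recording the
inputs, seed and parameter values.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, what the synthetic-data generator does and does not
emulate, and known limitations.
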