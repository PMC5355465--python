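"""Reference parameter sets and small packaged tables.

These are published human IgG turnover values: per-subject tracer-study
estimates of (FCR, k12, k21) for seven historical subjects (A–G, four of
them with paraproteinaemias or FcRn deficiency), the pooled-population
estimates of the elimination parameters from FCR/T½-vs-concentration
data, and six treatment-response scenarios for IgG myeloma simulations.
"""

from __future__ import annotations

import pandas as pd

from .kinetics import DEFAULT_PARAMETERS, MetabolicParameters
from .myeloma import ProductionSchedule, ScenarioConfig

__all__ = [
    "subject_timecourse_estimates",
    "pooled_macro_estimates",
    "fixed_exchange_macro_estimates",
    "myeloma_scenarios",
]

# per-subject tracer timecourse estimates (subjects A-G): FCR, k12, k21
# in day^-1 with standard errors, plus the fit RMSE
_SUBJECT_ROWS = [
    # subject, FCR, SE, k12, SE, k21, SE, RMSE
    ("A", 0.0359, 0.00169, 0.130, 0.0182, 0.231, 0.0218, 0.0336),
    ("B", 0.0761, 0.00190, 0.381, 0.0539, 0.426, 0.0546, 0.0182),
    ("C", 0.125, 0.00397, 0.382, 0.0643, 0.378, 0.0516, 0.0235),
    ("D", 0.0311, 0.000863, 0.432, 0.0746, 0.347, 0.0559, 0.0136),
    ("E", 0.247, 0.00632, 0.341, 0.125, 0.140, 0.0333, 0.0197),
    ("F", 0.0728, 0.00108, 0.358, 0.0233, 0.476, 0.0268, 0.0134),
    ("G", 0.0766, 0.00149, 0.656, 0.0538, 0.965, 0.0716, 0.0222),
]


def subject_timecourse_estimates() -> pd.DataFrame:
    """Per-subject estimates of (FCR, k12, k21) from seven historical
    human tracer studies, with standard errors and fit RMSE."""
    return pd.DataFrame(
        _SUBJECT_ROWS,
        columns=["subject", "fcr", "fcr_se", "k12", "k12_se",
                 "k21", "k21_se", "rmse"],
    )


def pooled_macro_estimates() -> MetabolicParameters:
    """Parameter estimates from the joint pooled fit of FCR and T½
    versus plasma IgG quantity (all five parameters free)."""
    return MetabolicParameters(k12=0.158, k21=0.187, k31=0.159,
                               Vmax=40.0, KM=272.0)


def fixed_exchange_macro_estimates() -> MetabolicParameters:
    """Elimination parameters re-estimated from the pooled FCR/T½ data
    with the exchange rates fixed to their timecourse-derived means
    (k12 = 0.38, k21 = 0.42)."""
    return MetabolicParameters(k12=0.38, k21=0.42, k31=0.161,
                               Vmax=45.6, KM=307.0)


# myeloma treatment-response scenarios (panels A-F): monoclonal
# production falls exponentially from Im0 toward Im_inf at rate k_kill;
# polyclonal production is the normal 15 µmol/day throughout
_SCENARIO_ROWS = {
    "A": (61.0, 11.5, 0.055),
    "B": (152.0, 5.0, 0.03),
    "C": (116.0, 2.5, 0.07),
    "D": (68.0, 0.0, 0.007),
    "E": (105.0, 24.0, 0.0065),
    "F": (53.0, 5.0, 0.01),
}


def myeloma_scenarios(params: MetabolicParameters = DEFAULT_PARAMETERS) -> dict:
    """The six packaged IgG myeloma treatment-response scenarios,
    keyed 'A'–'F'."""
    return {
        panel: ScenarioConfig(
            params=params,
            schedule=ProductionSchedule(Im0=im0, Im_inf=iminf,
                                        k_kill=kkill, Ip0=15.0),
        )
        for panel, (im0, iminf, kkill) in _SCENARIO_ROWS.items()
    }
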