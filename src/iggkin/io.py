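"""Dataset readers/writers and flat-config parsing.

All tabular I/O uses headered, UTF-8, '.'-decimal CSV.  Timecourse files
carry columns ``time_days, y1_plasma_fraction, y2_body_fraction`` (plus
an optional ``subject_id``).  Macro files carry ``x1E_umol`` and/or
``conc_g_per_l`` plus optional ``fcr_per_day`` and ``thalf_days``
columns; concentrations are auto-converted to quantities at read time.
Parameter sets are flat ``key = value`` text files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .kinetics import MetabolicParameters
from .macro import MacroDataset, TimecourseDataset
from .quantities import DEFAULT_CONSTANTS, UnitConstants, conc_to_quantity

__all__ = [
    "ValidationError",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_macro_csv",
    "write_macro_csv",
    "read_params_config",
    "write_params_config",
    "write_json",
]

PathLike = Union[str, Path]


class ValidationError(ValueError):
    """Input file failed validation; message includes file and row context."""


_TIMECOURSE_COLUMNS = ["time_days", "y1_plasma_fraction", "y2_body_fraction"]


def _read_csv(path: PathLike, required: list) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {missing}; found {list(frame.columns)}")
    return frame


def read_timecourse_csv(path: PathLike) -> TimecourseDataset:
    """Read one subject's tracer timecourse; column order is free."""
    frame = _read_csv(path, _TIMECOURSE_COLUMNS)
    subject = str(frame["subject_id"].iloc[0]) if "subject_id" in frame.columns \
        else Path(path).stem
    for col in _TIMECOURSE_COLUMNS:
        bad = frame.index[frame[col].isna()]
        if len(bad):
            raise ValidationError(f"{path}: column {col} has a missing value "
                                  f"at data row {bad[0] + 1}")
    frame = frame.sort_values("time_days", kind="stable")  # row order is free
    try:
        return TimecourseDataset(subject_id=subject,
                                 times=frame["time_days"].to_numpy(float),
                                 y1_obs=frame["y1_plasma_fraction"].to_numpy(float),
                                 y2_obs=frame["y2_body_fraction"].to_numpy(float))
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_timecourse_csv(data: TimecourseDataset, path: PathLike) -> None:
    frame = data.to_frame()
    frame.insert(0, "subject_id", data.subject_id)
    frame.to_csv(path, index=False)


def read_macro_csv(path: PathLike,
                   constants: UnitConstants = DEFAULT_CONSTANTS) -> MacroDataset:
    """Read population macro records.

    Accepts ``x1E_umol``, ``conc_g_per_l`` or both (both must agree to
    1%); FCR/T½ cells may be empty for subjects contributing only one
    output.
    """
    frame = _read_csv(path, [])
    has_x = "x1E_umol" in frame.columns
    has_c = "conc_g_per_l" in frame.columns
    if not has_x and not has_c:
        raise ValidationError(f"{path}: need column x1E_umol or conc_g_per_l")
    if has_c:
        converted = np.array([conc_to_quantity(v, constants)
                              for v in frame["conc_g_per_l"].to_numpy(float)])
    if has_x and has_c:
        x = frame["x1E_umol"].to_numpy(float)
        rel = np.abs(x - converted) / np.maximum(np.abs(converted), 1e-300)
        bad = np.nonzero(rel > 0.01)[0]
        if bad.size:
            raise ValidationError(
                f"{path}: x1E_umol and conc_g_per_l disagree by more than 1% "
                f"at data row {bad[0] + 1}")
    x1E = frame["x1E_umol"].to_numpy(float) if has_x else converted

    def optional(col):
        if col in frame.columns:
            return frame[col].to_numpy(float)
        return np.full(len(frame), np.nan)

    try:
        return MacroDataset(x1E=x1E,
                            fcr_per_day=optional("fcr_per_day"),
                            thalf_days=optional("thalf_days"),
                            source_conc_g_per_l=(frame["conc_g_per_l"].to_numpy(float)
                                                 if has_c else None))
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_macro_csv(data: MacroDataset, path: PathLike) -> None:
    data.to_frame().to_csv(path, index=False)


def read_params_config(path: PathLike) -> dict:
    """Parse a flat ``key = value`` config file (also accepts ``key: value``;
    '#' starts a comment)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    config = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        try:
            config[key.strip()] = float(value.strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric value {value.strip()!r}") from exc
    return config


def write_params_config(params: MetabolicParameters, path: PathLike) -> None:
    lines = [f"{k} = {v!r}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
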