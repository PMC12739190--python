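"""The dietary-profile record and its tabular (cohort) representation.

A cohort is a :class:`pandas.DataFrame` with the seven canonical columns;
:class:`DietProfile` is the validated single-record view used by scalar
operations and by row-level validation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["DietProfile", "COHORT_COLUMNS", "validate_cohort", "write_cohort_csv",
           "read_cohort_csv"]

#: Canonical cohort CSV schema (order matters for byte-identical output).
COHORT_COLUMNS = ["sugar_S", "acid_A", "protective_K", "quality_Q",
                  "medas_raw", "dpi", "hei"]

_BOUNDED_COLUMNS = ["sugar_S", "acid_A", "protective_K", "quality_Q", "dpi", "hei"]


@dataclass(frozen=True)
class DietProfile:
    """One simulated individual's dietary exposures and index scores.

    sugar_S, acid_A are 0-100 risk exposures (free sugars, acidic
    beverages); protective_K, quality_Q are 0-100 protective scores
    (protective-food intake, overall diet quality).  medas_raw is the raw
    0-14 Mediterranean adherence count; dpi and hei are already on 0-100.
    """

    sugar_S: float
    acid_A: float
    protective_K: float
    quality_Q: float
    medas_raw: int
    dpi: float
    hei: float

    def __post_init__(self) -> None:
        for name in ("sugar_S", "acid_A", "protective_K", "quality_Q", "dpi", "hei"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")
        m = self.medas_raw
        if int(m) != m or not (0 <= m <= 14):
            raise ValidationError(f"medas_raw must be an integer in [0, 14], got {m!r}")
        object.__setattr__(self, "medas_raw", int(m))


def validate_cohort(frame: pd.DataFrame) -> pd.DataFrame:
    """Check a cohort frame against the DietProfile invariants.

    Returns the frame (column-ordered) unchanged; raises
    :class:`ValidationError` naming the first offending column.
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort is missing columns {missing}")
    frame = frame[COHORT_COLUMNS]
    for col in _BOUNDED_COLUMNS:
        vals = frame[col].to_numpy(dtype=float)
        if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100 or np.isnan(vals).any()):
            raise ValidationError(f"column {col!r} has values outside [0, 100]")
    m = frame["medas_raw"].to_numpy()
    if len(m) and (not np.array_equal(m, np.round(m)) or m.min() < 0 or m.max() > 14):
        raise ValidationError("column 'medas_raw' must contain integers in [0, 14]")
    return frame


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort (optionally with extra columns such as ``ddrs``).

    Floats are fixed at six decimal places so reruns with the same seed are
    byte-identical.
    """
    frame.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort_csv`."""
    frame = pd.read_csv(path)
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    validate_cohort(frame)
    return frame[COHORT_COLUMNS + extra]
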