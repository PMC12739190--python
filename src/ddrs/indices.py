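"""Normalization of the three dietary indices onto a common 0-100 scale.

MEDAS is a 14-item count (0-14) and is rescaled linearly; DPI and HEI are
natively 0-100 and pass through with range validation only.
"""
from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .profiles import DietProfile

__all__ = ["IndexVector", "INDEX_NAMES", "normalize_medas", "validate_indices",
           "index_frame"]

#: Column/report order of the three indices.
INDEX_NAMES = ("medas_norm", "dpi", "hei")

MEDAS_MAX = 14


@dataclass(frozen=True)
class IndexVector:
    """The three index values of one profile, all on the 0-100 scale."""

    medas_norm: float
    dpi: float
    hei: float

    def __post_init__(self) -> None:
        for name in INDEX_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.medas_norm, self.dpi, self.hei)


def normalize_medas(raw) -> float:
    """Rescale a raw MEDAS count (integer 0-14) to the 0-100 scale.

    Uses the exact rational 100/14; no rounding is applied.
    """
    arr = np.asarray(raw)
    if not (np.issubdtype(arr.dtype, np.integer)
            or (np.issubdtype(arr.dtype, np.floating) and np.array_equal(arr, np.round(arr)))
            or isinstance(raw, Integral)):
        raise ValidationError(f"MEDAS raw score must be an integer, got {raw!r}")
    if arr.size and (arr.min() < 0 or arr.max() > MEDAS_MAX):
        raise ValidationError(f"MEDAS raw score must lie in [0, {MEDAS_MAX}], got {raw!r}")
    out = arr * (100.0 / MEDAS_MAX)
    return float(out) if out.ndim == 0 else out


def validate_indices(profile: DietProfile) -> IndexVector:
    """Extract and validate the index triple of a profile.

    MEDAS is rescaled; DPI and HEI pass through unchanged (their native
    range is already 0-100).  Idempotent on valid input.
    """
    return IndexVector(
        medas_norm=normalize_medas(profile.medas_raw),
        dpi=profile.dpi,
        hei=profile.hei,
    )


def index_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized `validate_indices`: the three normalized index columns.

    Returns a frame with columns ``medas_norm, dpi, hei`` aligned with the
    cohort's rows.
    """
    for col in ("dpi", "hei"):
        v = cohort[col].to_numpy(dtype=float)
        if len(v) and (v.min() < 0 or v.max() > 100):
            raise ValidationError(f"column {col!r} has values outside [0, 100]")
    return pd.DataFrame({
        "medas_norm": normalize_medas(cohort["medas_raw"].to_numpy()),
        "dpi": cohort["dpi"].to_numpy(dtype=float),
        "hei": cohort["hei"].to_numpy(dtype=float),
    }, index=cohort.index)
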