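"""The Dental Diet Risk Score (DDRS).

DDRS is an affine composite of four 0-100 dietary components:

    DDRS = w_S*S + w_A*A + w_K*(100 - K) + w_Q*(100 - Q)

with default weights (0.40, 0.20, 0.25, 0.15).  S (free sugars) and A
(acidic beverages) enter directly as risks; K (protective foods) and Q
(overall diet quality) enter inverted as protections.  With weights summing
to one the score is bounded in [0, 100]: 0 is the minimal-risk corner
(no sugar/acid, maximal protection), 100 the maximal-risk corner.
"""
from __future__ import annotations

import pandas as pd

from .config import WeightConfig
from .profiles import DietProfile

__all__ = ["compute_ddrs", "score_cohort", "scored_cohort", "risk_terms"]


def compute_ddrs(profile: DietProfile, weights: WeightConfig | None = None) -> float:
    """Score a single profile; result is in [0, 100] for unit-sum weights."""
    w = weights if weights is not None else WeightConfig()
    return (w.w_S * profile.sugar_S
            + w.w_A * profile.acid_A
            + w.w_K * (100.0 - profile.protective_K)
            + w.w_Q * (100.0 - profile.quality_Q))


def risk_terms(cohort: pd.DataFrame, weights: WeightConfig | None = None) -> pd.DataFrame:
    """The four weighted risk-direction terms whose sum is the DDRS.

    Columns ``S, A, K, Q`` hold w_S*S, w_A*A, w_K*(100-K), w_Q*(100-Q);
    they are the addends used by the variance decomposition.
    """
    w = weights if weights is not None else WeightConfig()
    return pd.DataFrame({
        "S": w.w_S * cohort["sugar_S"].to_numpy(dtype=float),
        "A": w.w_A * cohort["acid_A"].to_numpy(dtype=float),
        "K": w.w_K * (100.0 - cohort["protective_K"].to_numpy(dtype=float)),
        "Q": w.w_Q * (100.0 - cohort["quality_Q"].to_numpy(dtype=float)),
    }, index=cohort.index)


def score_cohort(cohort: pd.DataFrame, weights: WeightConfig | None = None) -> pd.Series:
    """Vectorized DDRS over a cohort frame; order-preserving.

    An empty cohort yields an empty series.
    """
    terms = risk_terms(cohort, weights)
    return pd.Series(terms.to_numpy().sum(axis=1), index=cohort.index, name="ddrs")


def scored_cohort(cohort: pd.DataFrame, weights: WeightConfig | None = None) -> pd.DataFrame:
    """Return a copy of the cohort with a ``ddrs`` column appended."""
    out = cohort.copy()
    out["ddrs"] = score_cohort(cohort, weights)
    return out
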