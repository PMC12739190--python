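"""Inferential statistics: correlations, variance decomposition, contrasts.

Pearson correlations carry Fisher-z confidence intervals and t-based
p-values; the variance of the composite score is decomposed into covariance
shares of its four weighted terms (exact under correlation, sums to 100 by
bilinearity); two-group contrasts use Welch's t-test and pooled-SD Cohen's d.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import WeightConfig
from .exceptions import DegenerateInputError, InsufficientDataError
from .score import risk_terms

__all__ = ["CorrelationResult", "VarianceShares", "GroupContrast",
           "pearson_with_ci", "variance_decomposition", "group_contrast",
           "correlation_table"]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its Fisher-z confidence interval."""

    index_name: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        assert -1.0 <= self.ci_low <= self.r <= self.ci_high <= 1.0
        assert 0.0 <= self.p_value <= 1.0


@dataclass(frozen=True)
class VarianceShares:
    """Percent of Var(DDRS) attributed to each weighted term (sums to 100)."""

    share_S: float
    share_A: float
    share_K: float
    share_Q: float

    def as_dict(self) -> dict[str, float]:
        return {"S": self.share_S, "A": self.share_A,
                "K": self.share_K, "Q": self.share_Q}

    @property
    def total(self) -> float:
        return self.share_S + self.share_A + self.share_K + self.share_Q


@dataclass(frozen=True)
class GroupContrast:
    """Welch t-test and pooled-SD Cohen's d between two DDRS samples."""

    t_statistic: float
    p_value: float
    cohens_d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Sample Pearson r with Fisher-z CI and two-sided t-test p-value.

    The CI is ``tanh(atanh(r) +- z_crit / sqrt(n - 3))``; the p-value uses
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.  At perfect
    correlation the p-value is exactly 0 and the interval degenerates to r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation is undefined for a constant sequence")

    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        ci_low = ci_high = r
        p = 0.0
    else:
        zcrit = sps.norm.ppf(0.5 + level / 2.0)
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult("", r, ci_low, ci_high, p, n)


def correlation_table(ddrs, indices: pd.DataFrame, level: float = 0.95) -> list[CorrelationResult]:
    """Correlate DDRS with each column of an index frame (report order kept)."""
    out = []
    for name in indices.columns:
        res = pearson_with_ci(np.asarray(ddrs, dtype=float),
                              indices[name].to_numpy(dtype=float), level)
        out.append(CorrelationResult(name, res.r, res.ci_low, res.ci_high,
                                     res.p_value, res.n))
    return out


def variance_decomposition(cohort: pd.DataFrame,
                           weights: WeightConfig | None = None) -> VarianceShares:
    """Covariance shares of the four weighted terms in Var(DDRS).

    With DDRS = sum_i term_i, share_i = 100 * Cov(term_i, DDRS) / Var(DDRS).
    Shares are exact under arbitrary correlation between terms and sum to
    100 by bilinearity of the covariance.
    """
    if len(cohort) < 2:
        raise InsufficientDataError("variance decomposition needs at least 2 profiles")
    terms = risk_terms(cohort, weights).to_numpy()
    ddrs = terms.sum(axis=1)
    var = float(np.var(ddrs, ddof=1))
    if var <= 0.0:
        raise DegenerateInputError("DDRS variance is zero; decomposition undefined")
    centered = ddrs - ddrs.mean()
    covs = (terms - terms.mean(axis=0)).T @ centered / (len(ddrs) - 1)
    shares = 100.0 * covs / var
    return VarianceShares(*map(float, shares))


def group_contrast(ddrs_a, ddrs_b) -> GroupContrast:
    """Contrast two DDRS samples: Welch's t and pooled-SD Cohen's d.

    Cohen's d uses the pooled standard deviation with the (n1 + n2 - 2)
    denominator; the t-test does not assume equal variances.
    """
    a = np.asarray(ddrs_a, dtype=float)
    b = np.asarray(ddrs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    pooled_var = (((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
                  / (a.size + b.size - 2))
    pooled_sd = float(np.sqrt(pooled_var))
    d = 0.0 if pooled_sd == 0.0 else float((a.mean() - b.mean()) / pooled_sd)
    t = 0.0 if np.isnan(t) else float(t)
    p = 1.0 if np.isnan(p) else float(p)
    return GroupContrast(t, p, d, float(a.mean()), float(b.mean()),
                         int(a.size), int(b.size))
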