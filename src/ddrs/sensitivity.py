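"""Weight-perturbation sensitivity: tornado analysis and the sugar-weight experiment.

Two perturbation semantics are provided.

* :func:`perturb_weights` multiplies one weight by a factor and rescales the
  other three proportionally so the four weights again sum to one; the score
  stays bounded in [0, 100].  This is the *renormalized* mode.
* The default tornado / sugar-weight analyses perturb one weight at a time
  **without** renormalizing the rest.  This is the classical one-at-a-time
  tornado convention: the change in mean score is the lever arm of that
  single weight (factor range x weight x mean term), so with comparable
  component levels the ranking follows the baseline weights and moving the
  sugar weight from 0.30 to 0.50 raises the mean score by about
  0.20 x mean(S) / mean(DDRS at 0.30) ~ 22% for near-equal term means.
  Under renormalization the mean-score change collapses to the small
  difference between component means and says nothing about a weight's
  leverage; both modes are exposed via ``renormalize``.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import COMPONENTS, WeightConfig
from .exceptions import ConfigurationError, DegenerateInputError, InfeasiblePerturbationError
from .score import score_cohort

__all__ = ["SensitivityRow", "perturb_weights", "tornado_analysis",
           "sugar_weight_experiment"]


@dataclass(frozen=True)
class SensitivityRow:
    """One tornado bar: mean DDRS under the low/high weight for a component."""

    component: str
    weight_low: float
    weight_high: float
    mean_ddrs_low: float
    mean_ddrs_high: float

    @property
    def delta_range(self) -> float:
        return abs(self.mean_ddrs_high - self.mean_ddrs_low)


def perturb_weights(base: WeightConfig, component: str, factor: float) -> WeightConfig:
    """Scale one weight by ``factor`` and renormalize the rest to unit sum.

    The target weight becomes ``factor * w``; the other three are scaled by
    the common multiplier ``(1 - factor*w) / (1 - w)`` so the result is a
    valid :class:`WeightConfig`.
    """
    if component not in COMPONENTS:
        raise ConfigurationError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    if factor <= 0:
        raise ConfigurationError(f"perturbation factor must be > 0, got {factor}")
    w = base.weight_of(component)
    new_w = factor * w
    if new_w >= 1.0:
        raise InfeasiblePerturbationError(
            f"perturbed weight for {component} would be {new_w:.3f} >= 1")
    rest = 1.0 - w
    scale = (1.0 - new_w) / rest if rest > 0 else 0.0
    vals = {c: (new_w if c == component else base.weight_of(c) * scale)
            for c in COMPONENTS}
    return WeightConfig(w_S=vals["S"], w_A=vals["A"], w_K=vals["K"], w_Q=vals["Q"])


def _one_at_a_time(base: WeightConfig, component: str, factor: float) -> dict[str, float]:
    """Raw weight map with one weight scaled and the others left untouched."""
    if factor < 0:
        raise ConfigurationError(f"perturbation factor must be >= 0, got {factor}")
    return {c: (factor * base.weight_of(c) if c == component else base.weight_of(c))
            for c in COMPONENTS}


def _mean_ddrs_raw(cohort: pd.DataFrame, wmap: dict[str, float]) -> float:
    """Mean DDRS under an arbitrary (not necessarily unit-sum) weight map."""
    s = (wmap["S"] * cohort["sugar_S"]
         + wmap["A"] * cohort["acid_A"]
         + wmap["K"] * (100.0 - cohort["protective_K"])
         + wmap["Q"] * (100.0 - cohort["quality_Q"]))
    return float(s.mean())


def tornado_analysis(cohort: pd.DataFrame, base: WeightConfig | None = None,
                     pct: float = 0.20, renormalize: bool = False) -> list[SensitivityRow]:
    """One-at-a-time +-pct weight perturbation, rows sorted by influence.

    For each component the mean DDRS is evaluated with that weight scaled
    by (1 - pct) and (1 + pct); rows are returned in descending order of
    ``delta_range``.  ``renormalize=True`` switches to the unit-sum
    semantics of :func:`perturb_weights` (see module docstring).
    """
    if len(cohort) == 0:
        raise DegenerateInputError("tornado analysis needs a non-empty cohort")
    base = base if base is not None else WeightConfig()
    rows = []
    for comp in COMPONENTS:
        if renormalize:
            w_lo = perturb_weights(base, comp, 1.0 - pct)
            w_hi = perturb_weights(base, comp, 1.0 + pct)
            m_lo = float(score_cohort(cohort, w_lo).mean())
            m_hi = float(score_cohort(cohort, w_hi).mean())
            lo, hi = w_lo.weight_of(comp), w_hi.weight_of(comp)
        else:
            lo = (1.0 - pct) * base.weight_of(comp)
            hi = (1.0 + pct) * base.weight_of(comp)
            m_lo = _mean_ddrs_raw(cohort, _one_at_a_time(base, comp, 1.0 - pct))
            m_hi = _mean_ddrs_raw(cohort, _one_at_a_time(base, comp, 1.0 + pct))
        rows.append(SensitivityRow(comp, lo, hi, m_lo, m_hi))
    return sorted(rows, key=lambda r: -r.delta_range)


def sugar_weight_experiment(cohort: pd.DataFrame, base: WeightConfig | None = None,
                            w_low: float = 0.30, w_high: float = 0.50,
                            renormalize: bool = False) -> float:
    """Percent rise in mean DDRS when the sugar weight moves from 0.30 to 0.50.

    Returns ``100 * (mean_high - mean_low) / mean_low``.  By default the
    other weights are held fixed (one-at-a-time semantics); with
    ``renormalize=True`` they are proportionally rescaled to keep the
    weights summing to one.
    """
    if len(cohort) == 0:
        raise DegenerateInputError("sugar-weight experiment needs a non-empty cohort")
    base = base if base is not None else WeightConfig()
    means = []
    for target in (w_low, w_high):
        factor = target / base.w_S
        if renormalize:
            means.append(float(score_cohort(cohort, perturb_weights(base, "S", factor)).mean()))
        else:
            means.append(_mean_ddrs_raw(cohort, _one_at_a_time(base, "S", factor)))
    mean_low, mean_high = means
    if mean_low == 0.0:
        raise DegenerateInputError("mean DDRS at the low sugar weight is zero; "
                                   "percent change undefined")
    return 100.0 * (mean_high - mean_low) / mean_low


def sensitivity_frame(rows: list[SensitivityRow]) -> pd.DataFrame:
    """Tornado rows as a tidy frame (CSV-ready)."""
    return pd.DataFrame([{
        "component": r.component,
        "weight_low": r.weight_low,
        "weight_high": r.weight_high,
        "mean_ddrs_low": r.mean_ddrs_low,
        "mean_ddrs_high": r.mean_ddrs_high,
        "delta_range": r.delta_range,
    } for r in rows])
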