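"""Scenario classification and per-group DDRS summaries.

Profiles are labelled healthy when all three normalized indices reach the
healthy threshold, unhealthy when all fall at or below the unhealthy
threshold, and mixed otherwise — a complete, mutually exclusive partition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioSpec, WeightConfig
from .indices import IndexVector, index_frame
from .score import score_cohort
from .stats import GroupContrast, group_contrast

__all__ = ["ScenarioSummary", "classify_profile", "classify_cohort",
           "summarize_scenarios", "summaries_frame"]

_LABELS = ("healthy", "unhealthy", "mixed")


@dataclass(frozen=True)
class ScenarioSummary:
    """DDRS distribution and index means within one scenario group.

    Quantiles use linear interpolation between order statistics; an empty
    group is reported with ``n = 0`` and NaN quantiles rather than raising.
    """

    scenario: str
    n: int
    median_ddrs: float
    iqr_low: float
    iqr_high: float
    mean_medas_norm: float
    mean_dpi: float
    mean_hei: float


def classify_profile(indices: IndexVector, spec: ScenarioSpec | None = None) -> str:
    """Label one profile's index triple as healthy / unhealthy / mixed."""
    spec = spec if spec is not None else ScenarioSpec()
    vals = indices.as_tuple()
    if all(v >= spec.healthy_min for v in vals):
        return "healthy"
    if all(v <= spec.unhealthy_max for v in vals):
        return "unhealthy"
    return "mixed"


def classify_cohort(cohort: pd.DataFrame, spec: ScenarioSpec | None = None) -> pd.Series:
    """Vectorized :func:`classify_profile` over a cohort frame."""
    spec = spec if spec is not None else ScenarioSpec()
    idx = index_frame(cohort).to_numpy()
    healthy = (idx >= spec.healthy_min).all(axis=1)
    unhealthy = (idx <= spec.unhealthy_max).all(axis=1)
    labels = np.where(healthy, "healthy", np.where(unhealthy, "unhealthy", "mixed"))
    return pd.Series(labels, index=cohort.index, name="scenario")


def _summary(label: str, idx: pd.DataFrame, ddrs: np.ndarray) -> ScenarioSummary:
    n = len(ddrs)
    if n == 0:
        nan = float("nan")
        return ScenarioSummary(label, 0, nan, nan, nan, nan, nan, nan)
    q25, med, q75 = np.percentile(ddrs, [25, 50, 75])
    return ScenarioSummary(
        label, n, float(med), float(q25), float(q75),
        float(idx["medas_norm"].mean()), float(idx["dpi"].mean()),
        float(idx["hei"].mean()))


def summarize_scenarios(cohort: pd.DataFrame,
                        spec: ScenarioSpec | None = None,
                        weights: WeightConfig | None = None,
                        labels: pd.Series | None = None,
                        ) -> tuple[list[ScenarioSummary], GroupContrast | None]:
    """Per-scenario DDRS summaries plus the healthy-vs-unhealthy contrast.

    ``labels`` may carry pre-assigned group labels (e.g. cohorts generated
    from the scenario presets); by default profiles are classified by the
    threshold rule.  The contrast is Welch's t / Cohen's d between the
    healthy and unhealthy groups, or None when either group has fewer than
    two members.
    """
    if labels is None:
        labels = classify_cohort(cohort, spec)
    ddrs = score_cohort(cohort, weights).to_numpy()
    idx = index_frame(cohort)
    summaries = []
    groups: dict[str, np.ndarray] = {}
    for label in _LABELS:
        mask = (labels == label).to_numpy()
        groups[label] = ddrs[mask]
        summaries.append(_summary(label, idx[mask], ddrs[mask]))
    contrast = None
    if len(groups["healthy"]) >= 2 and len(groups["unhealthy"]) >= 2:
        contrast = group_contrast(groups["healthy"], groups["unhealthy"])
    return summaries, contrast


def summaries_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Scenario summaries as a tidy frame (CSV-ready)."""
    return pd.DataFrame([{
        "scenario": s.scenario, "n": s.n,
        "median_ddrs": s.median_ddrs, "iqr_low": s.iqr_low, "iqr_high": s.iqr_high,
        "mean_medas_norm": s.mean_medas_norm, "mean_dpi": s.mean_dpi,
        "mean_hei": s.mean_hei,
    } for s in summaries])
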