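"""Model/results objects orchestrating the full DDRS study.

:class:`DDRSModel` wraps a cohort of dietary profiles together with a
weight scheme; ``fit()`` scores the cohort and computes every analysis of
the study — correlations with CIs, variance decomposition, scenario
summaries and contrast, weight sensitivity — returning a
:class:`DDRSResults` object with a ``summary()`` table, artifact writers
and plotting helpers.  :func:`run_study` and :func:`convergence_check`
are the end-to-end, seed-deterministic entry points used by the CLI.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .config import RunConfig, ScenarioSpec, WeightConfig
from .exceptions import InsufficientDataError
from .indices import index_frame
from .profiles import validate_cohort, write_cohort_csv
from .scenarios import ScenarioSummary, classify_cohort, summaries_frame, summarize_scenarios
from .score import score_cohort
from .sensitivity import (SensitivityRow, sensitivity_frame, sugar_weight_experiment,
                          tornado_analysis)
from .simulate import (clamp_fraction, generate_profiles, generate_scenario_cohort,
                       load_calibrated_config)
from .stats import CorrelationResult, GroupContrast, VarianceShares, correlation_table, \
    variance_decomposition

logger = logging.getLogger(__name__)

__all__ = ["DDRSModel", "DDRSResults", "run_study", "convergence_check"]

_INDEX_LABELS = {"medas_norm": "MEDAS", "dpi": "DPI", "hei": "HEI"}


class DDRSModel:
    """The Dental Diet Risk Score applied to a cohort of dietary profiles.

    Parameters
    ----------
    data : DataFrame with the seven canonical profile columns.
    weights : component weights; defaults to (0.40, 0.20, 0.25, 0.15).
    scenario_spec : thresholds for the healthy/unhealthy/mixed partition.
    """

    def __init__(self, data: pd.DataFrame, weights: WeightConfig | None = None,
                 scenario_spec: ScenarioSpec | None = None):
        self.data = validate_cohort(data).reset_index(drop=True)
        self.weights = weights if weights is not None else WeightConfig()
        self.scenario_spec = scenario_spec if scenario_spec is not None else ScenarioSpec()

    @classmethod
    def from_simulation(cls, config=None, n_profiles: int | None = None,
                        seed: int | None = None, **kwargs) -> "DDRSModel":
        """Build the model on a freshly simulated cohort.

        With ``config=None`` the frozen calibrated generator configuration
        is used (optionally overriding its sample size and seed).
        """
        if config is None:
            config = load_calibrated_config(n_profiles=n_profiles, seed=seed)
        else:
            changes = {}
            if n_profiles is not None:
                changes["n_profiles"] = n_profiles
            if seed is not None:
                changes["seed"] = seed
            if changes:
                config = config.replace(**changes)
        return cls(generate_profiles(config), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DDRSModel":
        from .profiles import read_cohort_csv
        return cls(read_cohort_csv(path), **kwargs)

    def fit(self, sensitivity_pct: float = 0.20) -> "DDRSResults":
        """Score the cohort and run all analyses."""
        if len(self.data) < 4:
            raise InsufficientDataError("fitting requires at least 4 profiles")
        ddrs = score_cohort(self.data, self.weights)
        indices = index_frame(self.data)
        correlations = correlation_table(ddrs.to_numpy(), indices)
        shares = variance_decomposition(self.data, self.weights)
        labels = classify_cohort(self.data, self.scenario_spec)
        scen_summaries, contrast = summarize_scenarios(
            self.data, self.scenario_spec, self.weights, labels=labels)
        tornado = tornado_analysis(self.data, self.weights, pct=sensitivity_pct)
        sugar_rise = sugar_weight_experiment(self.data, self.weights)
        return DDRSResults(
            model=self, ddrs=ddrs, indices=indices,
            correlations=correlations, variance_shares=shares,
            scenario_labels=labels, scenario_summaries=scen_summaries,
            scenario_contrast=contrast, sensitivity=tornado,
            sugar_weight_rise_pct=sugar_rise, sensitivity_pct=sensitivity_pct)


@dataclass
class DDRSResults:
    """Results of a fitted :class:`DDRSModel`."""

    model: DDRSModel
    ddrs: pd.Series
    indices: pd.DataFrame
    correlations: list[CorrelationResult]
    variance_shares: VarianceShares
    scenario_labels: pd.Series
    scenario_summaries: list[ScenarioSummary]
    scenario_contrast: GroupContrast | None
    sensitivity: list[SensitivityRow]
    sugar_weight_rise_pct: float
    sensitivity_pct: float = 0.20

    @property
    def nobs(self) -> int:
        return len(self.ddrs)

    def correlation(self, index_name: str) -> CorrelationResult:
        for c in self.correlations:
            if c.index_name == index_name:
                return c
        raise KeyError(index_name)

    # ---- tables ---------------------------------------------------------
    def correlation_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "index": _INDEX_LABELS.get(c.index_name, c.index_name),
            "r": c.r, "ci_low": c.ci_low, "ci_high": c.ci_high,
            "p_value": c.p_value, "n": c.n,
        } for c in self.correlations])

    def shares_frame(self) -> pd.DataFrame:
        d = self.variance_shares.as_dict()
        names = {"S": "sugar", "A": "acidic beverages",
                 "K": "protective foods", "Q": "overall quality"}
        return pd.DataFrame([{"component": c, "label": names[c], "share_pct": d[c]}
                             for c in ("S", "A", "K", "Q")])

    def summary(self) -> str:
        """Human-readable study summary (statsmodels-flavoured text table)."""
        w = self.model.weights
        lines = [
            "Dental Diet Risk Score — study summary",
            "=" * 54,
            f"profiles: {self.nobs}    weights: S={w.w_S:.2f} A={w.w_A:.2f} "
            f"K={w.w_K:.2f} Q={w.w_Q:.2f}",
            f"DDRS mean {self.ddrs.mean():.1f}  sd {self.ddrs.std(ddof=1):.1f}  "
            f"median {self.ddrs.median():.1f}",
            "",
            "Correlations with dietary indices (Pearson, Fisher-z 95% CI)",
            "-" * 54,
        ]
        for c in self.correlations:
            label = _INDEX_LABELS.get(c.index_name, c.index_name)
            p = "<0.001" if c.p_value < 1e-3 else f"{c.p_value:.3f}"
            lines.append(f"  {label:<6} r = {c.r:+.2f}  "
                         f"[{c.ci_low:+.2f}, {c.ci_high:+.2f}]  p {p}")
        lines += ["", "Variance decomposition of DDRS (covariance shares)", "-" * 54]
        for _, row in self.shares_frame().iterrows():
            lines.append(f"  {row['label']:<18} {row['share_pct']:5.1f} %")
        lines += ["", f"Scenario groups (healthy >= {self.model.scenario_spec.healthy_min:g}, "
                      f"unhealthy <= {self.model.scenario_spec.unhealthy_max:g})", "-" * 54]
        for s in self.scenario_summaries:
            if s.n:
                lines.append(f"  {s.scenario:<10} n={s.n:<6} median DDRS "
                             f"{s.median_ddrs:5.1f}  IQR ({s.iqr_low:.1f}, {s.iqr_high:.1f})")
            else:
                lines.append(f"  {s.scenario:<10} n=0      (empty)")
        if self.scenario_contrast is not None:
            ct = self.scenario_contrast
            p = "<0.001" if ct.p_value < 1e-3 else f"{ct.p_value:.3f}"
            lines.append(f"  healthy vs unhealthy: t = {ct.t_statistic:.1f}, "
                         f"p {p}, Cohen's d = {ct.cohens_d:.2f}")
        lines += ["", f"Weight sensitivity (one-at-a-time ±{100 * self.sensitivity_pct:.0f}%)",
                  "-" * 54]
        for r in self.sensitivity:
            lines.append(f"  {r.component}: mean DDRS {r.mean_ddrs_low:.1f} → "
                         f"{r.mean_ddrs_high:.1f}  (range {r.delta_range:.1f})")
        lines.append(f"  sugar weight 0.30 → 0.50: {self.sugar_weight_rise_pct:+.1f} % "
                     "change in mean DDRS")
        return "\n".join(lines)

    # ---- plots (optional; require matplotlib) ---------------------------
    def plot_correlations(self, path=None):
        """Scatter DDRS against each index with a regression line."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
        for ax, c in zip(axes, self.correlations):
            x = self.indices[c.index_name].to_numpy()
            y = self.ddrs.to_numpy()
            ax.scatter(x, y, s=4, alpha=0.2)
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="red")
            ax.set_xlabel(_INDEX_LABELS.get(c.index_name, c.index_name))
            ax.set_title(f"r = {c.r:.2f}")
        axes[0].set_ylabel("DDRS")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    def plot_tornado(self, path=None):
        """Horizontal-bar tornado of the one-at-a-time weight perturbations."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        rows = list(reversed(self.sensitivity))
        fig, ax = plt.subplots(figsize=(6, 3.5))
        base = float(self.ddrs.mean())
        for i, r in enumerate(rows):
            ax.barh(i, r.mean_ddrs_high - r.mean_ddrs_low,
                    left=r.mean_ddrs_low, color="steelblue")
        ax.axvline(base, color="k", lw=1)
        ax.set_yticks(range(len(rows)), [r.component for r in rows])
        ax.set_xlabel("mean DDRS")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    def plot_scenarios(self, path=None):
        """Box plots of DDRS by scenario group."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        groups = [self.ddrs[self.scenario_labels == lab] for lab in
                  ("healthy", "mixed", "unhealthy")]
        ax.boxplot([g for g in groups if len(g)],
                   tick_labels=[lab for lab, g in
                                zip(("healthy", "mixed", "unhealthy"), groups) if len(g)])
        ax.set_ylabel("DDRS")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


# --------------------------------------------------------------------------
# end-to-end study runner
# --------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit stage seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class StudyReport:
    """Everything `run_study` computed, plus the scenario-preset summaries."""

    results: DDRSResults
    preset_summaries: list[ScenarioSummary]
    preset_contrast: GroupContrast | None
    convergence: pd.DataFrame | None = None
    stabilization_n: int | None = None
    manifest: dict = field(default_factory=dict)


def run_study(config: RunConfig | None = None, output_dir=None,
              figures: bool = False) -> StudyReport:
    """Run the full pipeline: simulate, score, analyze, summarize, write.

    Stages consume independent substreams spawned from ``config.seed``, so
    e.g. changing the convergence grid does not perturb the main cohort.
    When ``output_dir`` (or ``config.output_dir``) is set, all artifacts —
    the scored cohort CSV, correlation/share/scenario/sensitivity CSVs, a
    JSON report and a run manifest — are written there; reruns with the
    same config produce byte-identical CSVs.
    """
    config = config if config is not None else RunConfig()
    out = Path(output_dir) if output_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")  # fail on unwritable output before any computation
    probe.unlink()

    seed_main, seed_healthy, seed_unhealthy, seed_mixed, seed_conv = _spawn_seeds(config.seed, 5)

    gen = config.generator.replace(seed=seed_main)
    cohort = generate_profiles(gen)
    logger.info("generated %d profiles; clamp fractions %s",
                len(cohort), clamp_fraction(gen, cohort))
    model = DDRSModel(cohort, config.weights, config.scenario_spec)
    results = model.fit(sensitivity_pct=config.sensitivity_pct)

    # scenario-preset cohorts (the Table-4 reproduction path)
    preset_frames = {
        "healthy": generate_scenario_cohort("healthy", config.scenario_n, seed_healthy),
        "unhealthy": generate_scenario_cohort("unhealthy", config.scenario_n, seed_unhealthy),
        "mixed": generate_scenario_cohort("mixed", config.scenario_n, seed_mixed),
    }
    preset_cohort = pd.concat(preset_frames.values(), ignore_index=True)
    preset_labels = pd.Series(
        np.repeat(list(preset_frames), [len(f) for f in preset_frames.values()]),
        name="scenario")
    preset_summaries, preset_contrast = summarize_scenarios(
        preset_cohort, config.scenario_spec, config.weights, labels=preset_labels)

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": config.as_dict(),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()

    report = StudyReport(results, preset_summaries, preset_contrast, manifest=manifest)

    # ---- artifacts ------------------------------------------------------
    scored = cohort.copy()
    scored["ddrs"] = results.ddrs
    write_cohort_csv(scored, out / "cohort_scored.csv")
    results.correlation_frame().to_csv(out / "correlations.csv", index=False,
                                       float_format="%.6f", lineterminator="\n")
    results.shares_frame().to_csv(out / "variance_shares.csv", index=False,
                                  float_format="%.6f", lineterminator="\n")
    summaries_frame(preset_summaries).to_csv(out / "scenario_summaries.csv", index=False,
                                             float_format="%.6f", lineterminator="\n")
    sensitivity_frame(results.sensitivity).to_csv(out / "sensitivity.csv", index=False,
                                                  float_format="%.6f", lineterminator="\n")
    (out / "report.json").write_text(json.dumps(_report_json(report), indent=2,
                                                sort_keys=True) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if figures:
        results.plot_correlations(out / "correlations.png")
        results.plot_tornado(out / "tornado.png")
        results.plot_scenarios(out / "scenarios.png")
    return report


def _report_json(report: StudyReport) -> dict:
    res = report.results
    d = {
        "n_profiles": res.nobs,
        "correlations": {
            _INDEX_LABELS.get(c.index_name, c.index_name): {
                "r": c.r, "ci_low": c.ci_low, "ci_high": c.ci_high, "p_value": c.p_value}
            for c in res.correlations},
        "variance_shares_pct": res.variance_shares.as_dict(),
        "sugar_weight_rise_pct": res.sugar_weight_rise_pct,
        "sensitivity": [{
            "component": r.component, "delta_range": r.delta_range}
            for r in res.sensitivity],
        "scenario_presets": [{
            "scenario": s.scenario, "n": s.n, "median_ddrs": s.median_ddrs,
            "iqr": [s.iqr_low, s.iqr_high],
            "mean_indices": [s.mean_medas_norm, s.mean_dpi, s.mean_hei]}
            for s in report.preset_summaries],
    }
    if report.preset_contrast is not None:
        ct = report.preset_contrast
        d["healthy_vs_unhealthy"] = {"t": ct.t_statistic, "p_value": ct.p_value,
                                     "cohens_d": ct.cohens_d}
    if report.stabilization_n is not None:
        d["stabilization_n"] = report.stabilization_n
    return d


def convergence_check(config: RunConfig | None = None,
                      grid: Sequence[int] | None = None,
                      tol_r: float = 0.01, tol_share: float = 1.0,
                      ) -> tuple[pd.DataFrame, int | None]:
    """Monte Carlo convergence of the headline statistics over sample size.

    A single master cohort of ``max(grid)`` profiles is drawn from one
    seeded stream and the three correlations and four variance shares are
    recomputed on nested prefixes of each grid size, isolating the pure
    sample-size effect from resampling noise.  The stabilization size is
    the smallest grid point after which every successive change stays
    below tolerance (``tol_r`` for correlations, ``tol_share`` points for
    shares); None when the trace never stabilizes.
    """
    config = config if config is not None else RunConfig()
    grid = tuple(int(n) for n in (grid if grid is not None else config.convergence_grid))
    if len(grid) < 3:
        raise InsufficientDataError("convergence grid needs at least 3 points")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InsufficientDataError("convergence grid must be strictly increasing")

    seed_conv = _spawn_seeds(config.seed, 5)[4]
    master = generate_profiles(config.generator.replace(n_profiles=max(grid),
                                                        seed=seed_conv))
    rows = []
    for n in grid:
        sub = master.iloc[:n]
        ddrs = score_cohort(sub, config.weights).to_numpy()
        idx = index_frame(sub)
        shares = variance_decomposition(sub, config.weights)
        rows.append({
            "n": n,
            "r_medas": float(np.corrcoef(ddrs, idx["medas_norm"])[0, 1]),
            "r_dpi": float(np.corrcoef(ddrs, idx["dpi"])[0, 1]),
            "r_hei": float(np.corrcoef(ddrs, idx["hei"])[0, 1]),
            "share_S": shares.share_S, "share_A": shares.share_A,
            "share_K": shares.share_K, "share_Q": shares.share_Q,
        })
    trace = pd.DataFrame(rows)

    r_cols = ["r_medas", "r_dpi", "r_hei"]
    s_cols = ["share_S", "share_A", "share_K", "share_Q"]
    deltas_r = trace[r_cols].diff().abs().iloc[1:]
    deltas_s = trace[s_cols].diff().abs().iloc[1:]
    ok = (deltas_r.le(tol_r).all(axis=1) & deltas_s.le(tol_share).all(axis=1)).to_numpy()
    stab = None
    for i in range(len(ok)):
        if ok[i:].all():
            stab = int(trace["n"].iloc[i])  # all later successive changes below tol
            break
    return trace, stab
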