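"""Configuration objects: score weights, generator parameters, scenario thresholds.

All configuration classes are frozen dataclasses that validate their
invariants at construction time and round-trip through plain dictionaries
(and hence YAML) without loss.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .exceptions import ConfigurationError

__all__ = [
    "WeightConfig",
    "GeneratorConfig",
    "ScenarioSpec",
    "RunConfig",
    "COMPONENTS",
    "NOISE_ALPHA_RANGE",
    "NOISE_BETA_RANGE",
]

#: Canonical component order: sugar, acidic beverages, protective foods, quality.
COMPONENTS = ("S", "A", "K", "Q")

#: Admissible shape ranges for the per-component noise beta distributions.
NOISE_ALPHA_RANGE = (2.0, 5.0)
NOISE_BETA_RANGE = (3.0, 6.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class WeightConfig:
    """Weights of the four DDRS components.

    The score is ``w_S*S + w_A*A + w_K*(100-K) + w_Q*(100-Q)``; weights must
    be non-negative and sum to one so the score stays on the 0-100 scale.
    """

    w_S: float = 0.40
    w_A: float = 0.20
    w_K: float = 0.25
    w_Q: float = 0.15

    def __post_init__(self) -> None:
        for name in ("w_S", "w_A", "w_K", "w_Q"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0, got {getattr(self, name)}")
        total = self.w_S + self.w_A + self.w_K + self.w_Q
        _require(abs(total - 1.0) <= 1e-9, f"weights must sum to 1 within 1e-9, got {total!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_S, self.w_A, self.w_K, self.w_Q)

    def as_dict(self) -> dict[str, float]:
        return {"w_S": self.w_S, "w_A": self.w_A, "w_K": self.w_K, "w_Q": self.w_Q}

    def weight_of(self, component: str) -> float:
        if component not in COMPONENTS:
            raise ConfigurationError(f"unknown component {component!r}; expected one of {COMPONENTS}")
        return getattr(self, f"w_{component}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dietary-profile generator.

    A single latent diet-quality factor ``H ~ Beta(latent_shape_a,
    latent_shape_b)`` induces the correlation structure.  Each 0-100
    component is a convex mixture of an independent beta noise draw and the
    latent factor: risk components (S, A) load on ``1 - H``, protective
    components (K, Q) on ``H``.  DPI/HEI are the protective components plus
    clamped Gaussian noise; MEDAS is Binomial(14, p) with p tied to H.

    Noise beta shapes are restricted to alpha in [2, 5], beta in [3, 6],
    the skewed, bounded shapes typical of dietary-intake distributions.
    """

    n_profiles: int = 10_000
    seed: int = 42
    latent_shape_a: float = 2.0
    latent_shape_b: float = 2.0
    # per-component noise beta shapes, keyed S/A/K/Q
    noise_alpha: Mapping[str, float] = field(
        default_factory=lambda: {"S": 2.0, "A": 2.0, "K": 2.0, "Q": 2.0}
    )
    noise_beta: Mapping[str, float] = field(
        default_factory=lambda: {"S": 3.0, "A": 3.0, "K": 3.0, "Q": 3.0}
    )
    # latent-factor loadings in [0, 1]
    lambda_S: float = 0.68
    lambda_A: float = 0.59
    lambda_K: float = 0.73
    lambda_Q: float = 0.52
    lambda_M: float = 0.49
    # index noise scales (points on the 0-100 scale)
    sigma_dpi: float = 17.0
    sigma_hei: float = 17.0

    def __post_init__(self) -> None:
        _require(int(self.n_profiles) == self.n_profiles and self.n_profiles >= 0,
                 f"n_profiles must be a non-negative integer, got {self.n_profiles}")
        _require(self.latent_shape_a > 0 and self.latent_shape_b > 0,
                 "latent beta shapes must be positive, got "
                 f"({self.latent_shape_a}, {self.latent_shape_b})")
        object.__setattr__(self, "noise_alpha", dict(self.noise_alpha))
        object.__setattr__(self, "noise_beta", dict(self.noise_beta))
        for comp in COMPONENTS:
            _require(comp in self.noise_alpha and comp in self.noise_beta,
                     f"noise shapes missing for component {comp!r}")
            a, b = self.noise_alpha[comp], self.noise_beta[comp]
            _require(NOISE_ALPHA_RANGE[0] <= a <= NOISE_ALPHA_RANGE[1],
                     f"noise alpha for {comp} must lie in {NOISE_ALPHA_RANGE}, got {a}")
            _require(NOISE_BETA_RANGE[0] <= b <= NOISE_BETA_RANGE[1],
                     f"noise beta for {comp} must lie in {NOISE_BETA_RANGE}, got {b}")
        for name in ("lambda_S", "lambda_A", "lambda_K", "lambda_Q", "lambda_M"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")
        _require(self.sigma_dpi >= 0, f"sigma_dpi must be >= 0, got {self.sigma_dpi}")
        _require(self.sigma_hei >= 0, f"sigma_hei must be >= 0, got {self.sigma_hei}")

    def loading_of(self, component: str) -> float:
        return getattr(self, f"lambda_{component}")

    def replace(self, **changes) -> "GeneratorConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    # ---- serialization -------------------------------------------------
    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_alpha"] = dict(d["noise_alpha"])
        d["noise_beta"] = dict(d["noise_beta"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ScenarioSpec:
    """Index thresholds defining the healthy / unhealthy / mixed partition."""

    healthy_min: float = 70.0
    unhealthy_max: float = 30.0

    def __post_init__(self) -> None:
        _require(0.0 <= self.unhealthy_max < self.healthy_min <= 100.0,
                 "require 0 <= unhealthy_max < healthy_min <= 100, got "
                 f"({self.unhealthy_max}, {self.healthy_min})")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun the full study deterministically."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    scenario_spec: ScenarioSpec = field(default_factory=ScenarioSpec)
    sensitivity_pct: float = 0.20
    convergence_grid: tuple[int, ...] = tuple(range(1000, 13000, 1000))
    scenario_n: int = 2000
    output_dir: str = "ddrs_output"
    seed: int = 42

    def __post_init__(self) -> None:
        grid = tuple(int(n) for n in self.convergence_grid)
        object.__setattr__(self, "convergence_grid", grid)
        _require(all(n >= 100 for n in grid), "convergence grid entries must all be >= 100")
        _require(all(b > a for a, b in zip(grid, grid[1:])),
                 "convergence grid must be strictly increasing")
        _require(self.sensitivity_pct >= 0, "sensitivity_pct must be >= 0")
        _require(self.scenario_n >= 0, "scenario_n must be >= 0")

    def as_dict(self) -> dict:
        return {
            "generator": self.generator.as_dict(),
            "weights": self.weights.as_dict(),
            "scenario_spec": {"healthy_min": self.scenario_spec.healthy_min,
                              "unhealthy_max": self.scenario_spec.unhealthy_max},
            "sensitivity_pct": self.sensitivity_pct,
            "convergence_grid": list(self.convergence_grid),
            "scenario_n": self.scenario_n,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "weights" in d:
            d["weights"] = WeightConfig(**d["weights"])
        if "scenario_spec" in d:
            d["scenario_spec"] = ScenarioSpec(**d["scenario_spec"])
        if "convergence_grid" in d:
            d["convergence_grid"] = tuple(d["convergence_grid"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
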