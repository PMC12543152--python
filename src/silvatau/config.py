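"""Experiment and scenario configuration.

A run is fully determined by an :class:`ExperimentConfig` plus a seed.  The
config can be loaded from YAML (see :func:`load_config`); CLI flags override
individual fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .params import DEFAULT_PARAMS, ModelParams, ZONES

SCENARIOS = ("base", "toNE", "toBD", "toBE", "unmanaged")
FORCING_MODES = ("fixed", "warming")
SUPPORTED_ROTATIONS = (60, 80, 100)


class ConfigError(ValueError):
    """Raised for inconsistent or invalid run configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Management settings for one scenario run.

    ``management_start`` is the simulation-year index at which the scenario
    diverges (the analogue of calendar year 2010); the 140-year initialisation
    wave period immediately precedes it.
    """

    option: str = "base"
    rotation: int = 80
    management_start: int = 440      # spinup (300) + initialisation (140)
    replant_lag: int = 1
    thin_enabled: bool = True
    clearcut_enabled: bool = True

    def __post_init__(self):
        if self.option not in SCENARIOS:
            raise ConfigError(f"unknown management option {self.option!r}")
        if self.rotation not in SUPPORTED_ROTATIONS:
            raise ConfigError(
                f"rotation {self.rotation} not in {SUPPORTED_ROTATIONS}")
        if self.management_start < 0 or self.replant_lag < 0:
            raise ConfigError("management_start and replant_lag must be >= 0")

    @property
    def managed(self) -> bool:
        return self.option != "unmanaged"


def default_age_histogram(n_bins: int = 14, pristine_tail: float = 0.04) -> list[float]:
    """Uniform 0-140 yr age distribution plus a small >140 yr pristine tail."""
    w = (1.0 - pristine_tail) / n_bins
    return [w] * n_bins + [pristine_tail]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one experiment (grid x scenarios x forcing mode)."""

    n_cells: int = 20
    n_patches: int = 25
    zone_weights: dict[str, float] = field(
        default_factory=lambda: {z: 0.2 for z in ZONES})
    scenarios: tuple[str, ...] = SCENARIOS
    mode: str = "fixed"            # "fixed" or "warming"
    rotation: int = 80
    spinup_years: int = 300
    init_years: int = 140          # 1871-2010 analogue: waves every 10 yr
    run_years: int = 240           # post-start years in fixed mode
    warming_run_years: int = 90    # post-start years in warming mode (to "2100")
    replant_lag: int = 1
    window_length: int = 30
    age_histogram: tuple[float, ...] = tuple(default_age_histogram())
    height_threshold: float = 5.0
    trim_coverage: float = 0.99
    params: ModelParams = field(default_factory=lambda: DEFAULT_PARAMS)
    record_spinup: bool = False

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.mode not in FORCING_MODES:
            raise ConfigError(f"unknown forcing mode {self.mode!r}")
        if self.rotation not in SUPPORTED_ROTATIONS:
            raise ConfigError(f"rotation must be one of {SUPPORTED_ROTATIONS}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigError(f"unknown scenario {s!r}")
        cycles = 3 if self.mode == "fixed" else 1
        if cycles * self.rotation > self.post_years:
            raise ConfigError(
                f"tau window needs {cycles} rotation cycles "
                f"({cycles * self.rotation} yr) but the run has only "
                f"{self.post_years} post-start years")
        if self.window_length > self.rotation:
            raise ConfigError("tau window cannot exceed the rotation length")
        if abs(sum(self.age_histogram) - 1.0) > 1e-9:
            raise ConfigError("age histogram must sum to 1")

    @property
    def management_start(self) -> int:
        return self.spinup_years + self.init_years

    @property
    def post_years(self) -> int:
        return self.run_years if self.mode == "fixed" else self.warming_run_years

    @property
    def total_years(self) -> int:
        return self.management_start + self.post_years

    def scenario_config(self, option: str) -> ScenarioConfig:
        return ScenarioConfig(
            option=option, rotation=self.rotation,
            management_start=self.management_start,
            replant_lag=self.replant_lag)

    def replace(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)


def load_config(path: str | Path, **overrides) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file.

    Only flat experiment-level keys are supported in YAML; process parameters
    keep their defaults unless overridden programmatically.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    raw.update(overrides)
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "scenarios" in raw:
        raw["scenarios"] = tuple(raw["scenarios"])
    if "age_histogram" in raw:
        raw["age_histogram"] = tuple(raw["age_histogram"])
    return ExperimentConfig(**raw)
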