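"""Run configuration: YAML schema, validation and defaults.

A :class:`RunConfig` drives the command-line pipeline. Configurations are
plain YAML; every stochastic step requires the top-level ``seed``. Unknown
keys are rejected so typos fail loudly before any computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .preprocess import STEP_NAMES, PreprocessSpec
from .profiles import STUDY_SPECIES, NoiseModel
from .spectra import DEFAULT_WINDOWS, SpectralWindows, WavenumberGrid, default_grid

__all__ = ["RunConfig", "load_config"]

_NOISE_PRESETS = {"silent": NoiseModel.silent, "dried": NoiseModel.dried,
                  "ground": NoiseModel.ground}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one reproducible pipeline run."""

    seed: int
    species: tuple[str, ...] = ("maize", "barnyard_grass")
    prep: str = "ground"
    n_replicates: int = 6
    grid_low: float = 400.0
    grid_high: float = 4000.0
    grid_spacing: float = 2.0
    noise_preset: str = "ground"
    noise_overrides: dict = field(default_factory=dict)
    preprocess_steps: tuple[str, ...] = ("first_derivative", "vector_normalize")
    derivative_window: int = 9
    derivative_polyorder: int = 2
    windows: tuple[tuple[float, float], ...] = tuple(DEFAULT_WINDOWS.windows)
    cluster_k: int | None = None
    design: str = "2species"  # 2species | 3species | none
    design_step: float = 5.0
    design_n: int = 21
    mixture_replicates: int = 3
    max_components: int = 10
    test_samples: int = 6
    outdir: str = "rootspec_run"

    def grid(self) -> WavenumberGrid:
        return default_grid(self.grid_low, self.grid_high, self.grid_spacing)

    def noise(self) -> NoiseModel:
        base = _NOISE_PRESETS[self.noise_preset](seed=self.seed)
        if self.noise_overrides:
            base = dataclasses.replace(base, **self.noise_overrides)
        return base

    def preprocess(self) -> PreprocessSpec:
        return PreprocessSpec(
            steps=self.preprocess_steps,
            derivative_window=self.derivative_window,
            derivative_polyorder=self.derivative_polyorder,
            windows=SpectralWindows(self.windows),
        )


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def _validate(raw: Mapping[str, Any]) -> RunConfig:
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "seed" not in raw:
        raise ConfigError("config key 'seed' is mandatory (stochastic steps need it)")
    if not isinstance(raw["seed"], int):
        raise ConfigError("config key 'seed' must be an integer")
    data = dict(raw)
    for key in ("species", "preprocess_steps"):
        if key in data:
            data[key] = tuple(data[key])
    if "windows" in data:
        data["windows"] = tuple((float(lo), float(hi)) for lo, hi in data["windows"])
    try:
        cfg = RunConfig(**data)
    except TypeError as err:
        raise ConfigError(str(err)) from err
    if cfg.noise_preset not in _NOISE_PRESETS:
        raise ConfigError(
            f"noise_preset must be one of {sorted(_NOISE_PRESETS)}"
        )
    for step in cfg.preprocess_steps:
        if step not in STEP_NAMES:
            raise ConfigError(f"unknown preprocess step {step!r}")
    for sp in cfg.species:
        if sp not in STUDY_SPECIES:
            raise ConfigError(
                f"unknown species {sp!r}; valid: {', '.join(STUDY_SPECIES)}"
            )
    if cfg.design not in ("2species", "3species", "none"):
        raise ConfigError("design must be one of 2species, 3species, none")
    if cfg.n_replicates < 1 or cfg.mixture_replicates < 1:
        raise ConfigError("replicate counts must be >= 1")
    # exercise derived constructors so bad numeric values fail at load time
    cfg.grid()
    cfg.noise()
    cfg.preprocess()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: invalid YAML: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return _validate(raw)
    except ConfigError:
        raise
    except Exception as err:
        raise ConfigError(f"{path}: {err}") from err
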