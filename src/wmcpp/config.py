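"""Structured YAML configuration for the pipeline.

One file governs every stage::

    seed: 1
    simulate:            # synth.SimConfig fields
      n_participants: 25
      n_trials: 620
    preprocess:          # preprocess.PreprocessConfig fields
      target_sfreq_hz: 250
    analysis:            # cpp.AnalysisConfig fields
      n_bins_fine: 100
    inference:
      n_permutations: 10000
      cluster_alpha: 0.05
      exhaustive: null   # auto

Unknown keys raise ConfigError.  The top-level seed feeds the simulator and
(offset) the permutation tests unless overridden on the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .cpp import AnalysisConfig
from .errors import ConfigError
from .preprocess import PreprocessConfig
from .synth import SimConfig


@dataclass
class InferenceConfig:
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    exhaustive: bool | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)


_SECTIONS = {
    "simulate": SimConfig,
    "preprocess": PreprocessConfig,
    "analysis": AnalysisConfig,
    "inference": InferenceConfig,
}


def _build(cls, section: str, values: dict):
    spec = {f.name: f for f in dc_fields(cls)}
    unknown = [k for k in values if k not in spec]
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {unknown}")
    coerced = {}
    defaults = cls()
    for k, v in values.items():
        if isinstance(getattr(defaults, k), tuple) and isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML (or defaults when path is None)."""
    raw: dict = {}
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = [k for k in raw if k not in _SECTIONS and k != "seed"]
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {unknown}")
    cfg = PipelineConfig(seed=int(raw.get("seed", 0)))
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        setattr(cfg, name, _build(cls, name, section))
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            if key == "seed":
                cfg.seed = int(value)
            elif key == "n_permutations":
                cfg.inference.n_permutations = int(value)
            elif key == "exhaustive":
                cfg.inference.exhaustive = bool(value)
            elif key == "n_bins":
                cfg.analysis.n_bins_fine = int(value)
            else:
                raise ConfigError(f"unknown override {key!r}")
    cfg.simulate.seed = cfg.seed
    cfg.simulate.validate()
    cfg.preprocess.validate()
    cfg.analysis.validate()
    return cfg
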