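"""Run configuration (YAML) and the run manifest.

A flat YAML file controls the cohort generator and the validation settings;
unknown keys are rejected so typos fail loudly. An empty file yields the full
default study: 193 boys measured annually 8-18 y and 199 girls 8-16 y.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .simulate import CohortConfig, ConfigError, SexConfig

__all__ = ["PipelineConfig", "RunManifest", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Cohort plus analysis settings for one reproducible run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    maturity_band: float = 1.0
    hit_band: float = 0.5
    bootstrap_se: bool = False
    n_bootstrap: int = 200

    def validate(self) -> "PipelineConfig":
        self.cohort.validate()
        if self.maturity_band <= 0 or self.hit_band <= 0:
            raise ConfigError("band widths must be positive")
        return self


_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)}
_SEX_KEYS = {f.name for f in dataclasses.fields(SexConfig)}
_PIPELINE_KEYS = {"maturity_band", "hit_band", "bootstrap_se", "n_bootstrap"}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a flat YAML config; missing file/keys fall back to defaults.

    Top-level keys may be any :class:`CohortConfig` field, any pipeline
    setting, or the nested ``boys:`` / ``girls:`` mappings with
    :class:`SexConfig` fields. Unknown keys raise :class:`ConfigError`
    naming the offender.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping of key: value pairs")

    cfg = PipelineConfig()
    for key, value in raw.items():
        if key in ("boys", "girls"):
            if not isinstance(value, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            sex_cfg = getattr(cfg.cohort, key)
            for k2, v2 in value.items():
                if k2 not in _SEX_KEYS:
                    raise ConfigError(f"unknown config key '{key}.{k2}'")
                setattr(sex_cfg, k2, v2)
        elif key in _COHORT_KEYS:
            setattr(cfg.cohort, key, value)
        elif key in _PIPELINE_KEYS:
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"unknown config key '{key}'")
    return cfg.validate()


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every report."""

    seed: int
    config_hash: str
    version: str
    n_boys: int
    n_girls: int
    class_counts: dict
    exclusions: dict
    timestamp: str = ""

    def finalize(self) -> "RunManifest":
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
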