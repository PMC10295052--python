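"""Run configuration: defaults, YAML round trip, strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Unknown or invalid configuration key."""


@dataclass
class RunConfig:
    """Pipeline settings; thresholds default to the published values."""

    out_dir: str = "results"
    seed: int = 0
    # quality-control thresholds
    segment_snr_threshold_db: float = 5.0
    beat_exclusion_threshold_db: float = 5.0
    min_participants_per_age: int = 8
    alpha: float = 0.01
    n_tests: int = 24
    min_beats_per_segment: int = 20
    # environment settings
    action_halfwidth: float = 0.01
    train_max_steps: int = 1000
    train_patience: int = 100
    extract_max_steps: int = 2000
    extract_patience: int = 200
    # training scale (the published run used 3,000,000 steps; the packaged
    # default is desk scale)
    train_total_steps: int = 100_000
    # synthetic-study overrides forwarded to SynthSpec
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
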