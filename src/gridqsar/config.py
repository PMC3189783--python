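"""Run configuration with defaults fixed to the study's stated settings:
2 Angstrom grid spacing, +1 e / 1 Angstrom probe, 30 kcal/mol truncation,
attenuation 0.3."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration key/value."""


@dataclass
class RunConfig:
    grid_spacing: float = 2.0  # Angstrom
    grid_margin: float = 4.0  # Angstrom beyond the union bounding box
    probe_charge: float = 1.0  # e
    probe_radius: float = 1.0  # Angstrom
    probe_epsilon: float = 0.107  # kcal/mol LJ well depth
    alpha: float = 0.3  # similarity-index attenuation
    truncation: float = 30.0  # kcal/mol
    min_sd_comfa: float = 2.0  # kcal/mol column filter
    min_sd_comsia: float = 0.05  # column filter (similarity units)
    max_components: int = 10
    component_selection: str = "parsimony"  # or "argmax"
    favored_pct: float = 80.0
    disfavored_pct: float = 20.0
    electrostatic_exclusion: str = "column_mean"  # or "raw"
    reference_id: int = 58
    seed: int = 20110923
    mode: str = "real"  # or "synthetic"
    input_path: Optional[str] = None
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.grid_spacing <= 0:
            raise ConfigError("grid_spacing must be positive")
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")
        if self.component_selection not in ("parsimony", "argmax"):
            raise ConfigError(f"unknown component_selection {self.component_selection!r}")
        if self.electrostatic_exclusion not in ("column_mean", "raw"):
            raise ConfigError(
                f"unknown electrostatic_exclusion {self.electrostatic_exclusion!r}"
            )
        if self.mode not in ("real", "synthetic"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def manifest_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
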