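"""Pipeline configuration: thresholds, constants, paths, seed, logging."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class PipelineConfig:
    temperature: float = 300.0
    standard_volume: float = 1661.0
    pharmacophore_acceptor_threshold: float = -6.0
    pharmacophore_donor_threshold: float = -6.0
    pharmacophore_hydrophobic_threshold: float = -2.0
    pharmacophore_tolerance: float = 1.5
    clustering_threshold: float = 0.65
    rmsd_threshold: float = 2.0
    significance_alpha: float = 0.05
    root_seed: int = 0
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.standard_volume <= 0:
            raise ValidationError("standard_volume must be positive")
        for name in ("pharmacophore_acceptor_threshold",
                     "pharmacophore_donor_threshold",
                     "pharmacophore_hydrophobic_threshold"):
            if getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be negative")
        if not (0 < self.clustering_threshold <= 1):
            raise ValidationError("clustering_threshold must lie in (0, 1]")
        if self.pharmacophore_tolerance <= 0:
            raise ValidationError("pharmacophore_tolerance must be positive")
        if self.rmsd_threshold <= 0:
            raise ValidationError("rmsd_threshold must be positive")
        if not (0 < self.significance_alpha < 1):
            raise ValidationError("significance_alpha must lie in (0, 1)")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValidationError(f"unknown log_level {self.log_level!r}")


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
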