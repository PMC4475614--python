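"""Run configuration shared by the CLI subcommands.

Defaults mirror the analysis conventions used throughout the package:
3.6 Å contact cutoff, 50 lowest-energy poses, 50% effect level, the
seven-band CI classification, variable-slope dose-response fits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .synergy import CI_BANDS

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    contact_cutoff: float = 3.6
    top_k: int = 50
    region_threshold: float = 0.5
    bridge_gaps: int = 2
    effect_level: float = 50.0
    ci_bands: tuple[tuple[float, float, str], ...] = CI_BANDS
    variable_slope: bool = True
    n_boot: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.contact_cutoff <= 0:
            raise ConfigError("contact_cutoff must be positive")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if not 0 < self.region_threshold <= 1:
            raise ConfigError("region_threshold must be in (0, 1]")
        if self.bridge_gaps < 0:
            raise ConfigError("bridge_gaps must be >= 0")
        if self.n_boot < 0:
            raise ConfigError("n_boot must be >= 0")
        lo = 0.0
        for band in self.ci_bands:
            if len(band) != 3 or band[0] != lo or band[1] <= band[0]:
                raise ConfigError(f"ci_bands must tile [0, top) contiguously: {band}")
            lo = band[1]
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "ci_bands" in raw:
            raw["ci_bands"] = tuple(tuple(b) for b in raw["ci_bands"])
        return cls(**raw).validate()

    def hash(self) -> str:
        """Stable digest of the configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
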