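"""Validated run configuration for the command-line entry points."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .analysis import DEFAULT_LAI_LEVELS, DEFAULT_PDW_LEVELS, DEFAULT_PHI_LEVELS
from .scene import DEFAULT_BAND_WEIGHTS, MEAN_BLADE_AREA_M2


class GridLevels(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lai: list[float] = Field(default_factory=lambda: list(DEFAULT_LAI_LEVELS))
    phi_lamps: list[float] = Field(default_factory=lambda: list(DEFAULT_PHI_LEVELS))
    p_dw: list[float] = Field(default_factory=lambda: list(DEFAULT_PDW_LEVELS))


class CanopyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_leaves: int = 7
    target_area_m2: float = MEAN_BLADE_AREA_M2
    lai: float = 1.0


class TransportConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    photons_per_band: int = 100_000
    master_seed: int = 0
    max_bounces: int = 20


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    grid: GridLevels = Field(default_factory=GridLevels)
    canopy: CanopyConfig = Field(default_factory=CanopyConfig)
    transport: TransportConfig = Field(default_factory=TransportConfig)
    band_weights: tuple[float, float, float] = DEFAULT_BAND_WEIGHTS
    leaf_params_file: str | None = None
    output_dir: str = "out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable hash embedded in every output for provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
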