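"""Pipeline configuration: every tunable surfaced by the extraction stages.

Defaults match the owning module's documented defaults; unknown keys are
rejected so a typo in a YAML config fails loudly instead of silently using
a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # visual
    selem_radius: int = Field(default=3, ge=1)
    edge_fraction: float = Field(default=0.5, gt=0.0, lt=1.0)
    profile_row: float = Field(default=0.5, ge=0.0, le=1.0)
    open_threshold: int = Field(default=6, ge=1)
    min_run: int = Field(default=2, ge=1)
    # thermal
    binarize_threshold: float | str = 128
    R0: float | None = Field(default=None, gt=0)
    n_rings: int = Field(default=16, ge=1)
    n_wedges: int = Field(default=16, ge=1)
    # vocal voicing gate
    energy_threshold_db: float = -45.0
    periodicity_threshold: float = Field(default=0.3, ge=0.0, le=1.0)
    frame_len_ms: float = Field(default=40.0, gt=0)
    hop_ms: float = Field(default=10.0, gt=0)
    # fusion
    k_features: int = Field(default=6, ge=1)
    corr_cap: float = Field(default=0.9, ge=0.0, le=1.0)
    weight_resolution: float = Field(default=0.01, gt=0, le=1.0)
    threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    # global
    seed: int = 0

    @field_validator("binarize_threshold")
    @classmethod
    def _check_threshold(cls, v):
        if isinstance(v, str) and v != "otsu":
            raise ValueError("binarize_threshold must be a number or 'otsu'")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**data)
        except Exception as exc:  # pydantic ValidationError or TypeError
            raise ValidationError(f"bad config {path}: {exc}") from exc

    def model_params(self) -> dict:
        return {
            "k": self.k_features,
            "corr_cap": self.corr_cap,
            "resolution": self.weight_resolution,
            "threshold": self.threshold,
        }
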