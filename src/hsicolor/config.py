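"""Run configuration: a schema-validated record of every knob that affects
numeric output, echoed (with its hash) into artifacts for provenance."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError


class ColorimetryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    integration_range_nm: tuple[float, float] = (420.0, 730.0)
    delta_e: str = "cie76"

    @field_validator("delta_e")
    @classmethod
    def _check_variant(cls, v: str) -> str:
        if v not in ("cie76", "ciede2000"):
            raise ValueError("delta_e must be 'cie76' or 'ciede2000'")
        return v


class ROIConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "Right_Cheek"
    anchor_indices: tuple[int, int, int] = (2, 4, 31)
    size_px: tuple[int, int] = (75, 75)
    histogram_bins: int = 64


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fractional_sigma: float = Field(0.02, ge=0)


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.01, gt=0, lt=1)
    maximum_signal: float | None = Field(
        None, description="None = max |ordinate| over the correlated pairs"
    )


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    colorimetry: ColorimetryConfig = ColorimetryConfig()
    rois: list[ROIConfig] = Field(default_factory=lambda: [ROIConfig()])
    noise: NoiseConfig = NoiseConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON, validating the schema."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**data)
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc
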