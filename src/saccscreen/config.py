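"""Validated pipeline configuration (YAML/JSON) with calibrated defaults."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


class DetectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold_deg_s: float = Field(30.0, gt=0)
    smooth_window_ms: int = Field(5, ge=1)
    min_duration_ms: float = Field(10.0, ge=0)
    merge_gap_ms: float = Field(20.0, ge=0)
    min_amplitude_deg: float = Field(0.3, ge=0)

    @field_validator("smooth_window_ms")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("smoothing window must be odd")
        return v


class ValidityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    latency_window_ms: tuple[float, float] = (80.0, 600.0)
    min_valid_static: int = Field(32, ge=0)
    min_valid_moving: int = Field(36, ge=0)


class CvConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outer_folds: int = Field(10, ge=2)
    inner_folds: int = Field(2, ge=2)
    n_boot: int = Field(2000, ge=1)
    importance_repeats: int = Field(50, ge=1)


class PipelineConfig(BaseModel):
    """Everything needed for a reproducible simulate->analyze run.

    Group profiles default to the published-value calibration; a profile YAML
    (see :func:`saccscreen.profiles.profiles_to_yaml`) may override them.
    """

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_per_group: int = Field(16, ge=2)
    out_dir: str = "results/pipeline"
    profiles_path: str | None = None
    persist_trace_subjects: int = Field(1, ge=0)  # subjects whose raw traces are written
    detector: DetectorConfig = DetectorConfig()
    validity: ValidityConfig = ValidityConfig()
    cv: CvConfig = CvConfig()

    def load_profiles(self):
        from saccscreen.profiles import default_profiles, profiles_from_yaml

        if self.profiles_path is None:
            return default_profiles()
        return profiles_from_yaml(Path(self.profiles_path).read_text())


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML/JSON config; an empty file yields defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigError(f"invalid configuration ({keys}): {exc}") from exc


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
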