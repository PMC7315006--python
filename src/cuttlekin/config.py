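"""Pipeline configuration: one validated object, serialisable to YAML.

CLI flags override file values; every analysis output can carry the
config hash so a rerun with identical config and input is identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class CalibrationConfig(BaseModel):
    mm_per_px: float = Field(0.5, gt=0)
    fps: float = Field(90.0, gt=0)
    frame_size: tuple[int, int] = (2048, 2048)
    session_length_s: float = Field(120.0, gt=0)


class CleaningConfig(BaseModel):
    likelihood_threshold: float = Field(0.9, ge=0.0, le=1.0)
    jump_gate_px: float | None = None  # off by default
    smoothing_window: int = Field(5, ge=1)


class SegmentationConfig(BaseModel):
    alpha_max_deg: float = Field(30.0, gt=0)
    t_min_s: float = Field(1.0, ge=0)
    gap_max_s: float = Field(0.5, ge=0)
    e_on_ml: float = Field(0.5, gt=0)
    v_on_ml_s: float = Field(2.0, gt=0)


class PhaseConfig(BaseModel):
    v_still_mm_s: float = Field(5.0, gt=0)
    v_split_mm_s: float = Field(50.0, gt=0)


class StatsConfig(BaseModel):
    norm_length_ml: float = 1.0  # classical strike distance norm
    norm_angle_deg: float = 90.0  # perpendicular to prey motion


class PipelineConfig(BaseModel):
    """Full parameter set for the clean -> kinematics -> segmentation -> stats run."""

    calibration: CalibrationConfig = CalibrationConfig()
    cleaning: CleaningConfig = CleaningConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    phases: PhaseConfig = PhaseConfig()
    stats: StatsConfig = StatsConfig()
    output_dir: str = "cuttlekin_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))
        return path

    def digest(self) -> str:
        """Stable short hash of the full parameter set."""
        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
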