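"""Validated pipeline configuration.

All tunable knobs of the pipeline live in one YAML-serialisable object,
validated up front (unknown keys rejected) so a typo fails before any stage
runs. A short hash of the canonical JSON form is embedded in outputs and log
lines so every artifact can be traced to the exact configuration that made it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .grid import ChannelLayout

__all__ = ["PipelineConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LayoutConfig(_Strict):
    n_a: int = 50
    n_b: int = 50
    channel_width: float = 25.0  # um
    pitch: Optional[float] = None  # um; defaults to 2 * channel_width
    origin_x: float = 0.0
    origin_y: float = 0.0

    def to_layout(self) -> ChannelLayout:
        return ChannelLayout(
            n_a=self.n_a,
            n_b=self.n_b,
            channel_width=self.channel_width,
            pitch=self.pitch,
            origin_xy=(self.origin_x, self.origin_y),
        )


class RegistrationConfig(_Strict):
    sigma_px: float = 5.0  # boundary-detection smoothing
    allow_reflection: bool = False
    px_per_pitch: int = 10  # spot-mask rasterisation resolution
    blur_sigma: float = 2.0  # loss smoothing for the similarity fit


class PreprocessConfig(_Strict):
    q_low: float = 0.05
    q_high: float = 0.95
    size_q_low: float = 0.05
    size_q_high: float = 0.95
    dapi_quantile: float = 0.1
    dapi_marker: str = "DAPI"
    area_normalize: bool = True


class SplitConfig(_Strict):
    fallback: str = "beta"  # or "drop"
    min_cells_per_spot: int = 1


class QCConfig(_Strict):
    bin_size_px: float = 100.0


class PipelineConfig(_Strict):
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    barcode_dialect: str = "{i}x{j}"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)


def config_hash(config: PipelineConfig) -> str:
    """12-hex-digit digest of the canonical configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
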