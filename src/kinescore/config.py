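"""Validated pipeline configuration.

One config object wires the whole pipeline: window geometry, target frame
rate, descriptor selection size, quantization, confirmation rule and ridge
policy.  A stable hash of the config travels inside model files so that a
model is never applied under incompatible settings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """Adjusting parameters of the recognition/scoring pipeline.

    Defaults follow the best-performing small-descriptor regime: 5 s windows,
    1 s slide step, two MI descriptors per class, 30 fps analysis rate.
    """

    delta_t: float = Field(5.0, gt=0, description="sliding window length, s")
    dt: float = Field(1.0, gt=0, description="window slide step, s")
    fps: float = Field(30.0, gt=0, description="analysis frame rate, frames/s")
    n_d: int = Field(2, ge=1, le=630, description="selected MI descriptors per class")
    entropy_base: float = Field(2.0, gt=1.0, description="logarithm base for entropies")
    angular_bins: int = Field(18, ge=2, description="quantization bins for angles")
    nddi_bins: int = Field(20, ge=2, description="quantization bins for NDDIs")
    confirm_threshold: float = Field(0.5, ge=0.0, le=1.0)
    confirm_mode: Literal["mean", "nearest"] = "mean"
    redundancy_filter: bool = True
    redundancy_corr: float = Field(0.95, gt=0.0, le=1.0)
    ridge_cond: float = Field(1e10, gt=0)
    ridge_scale: float = Field(1e-6, gt=0)
    adaptive: bool = Field(True, description="re-estimate kernels per window")
    max_invalid_fraction: float = Field(0.1, ge=0.0, le=1.0)
    seed: int = 0

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, sort_keys=True)
        return Path(path)
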