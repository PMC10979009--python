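"""Validated pipeline configuration with YAML round-tripping.

Every stage parameter is validated up front, before any computation runs;
the configuration serializes losslessly to and from YAML, and its canonical
JSON hash is recorded in the run manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .shapeclass import ShapeClassParams
from .simgen import SimParams


class SimulateBlock(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_cells: int = 20
    class_mix: dict[str, float] = Field(default_factory=lambda: {"crescent": 1.0})
    params: SimParams = Field(default_factory=SimParams)


class SegmentParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    channel: str = "CELL"
    threshold_method: Literal["otsu", "quantile"] = "otsu"
    min_area_um2: float = 1.0
    roundness_min: float = 0.85


class FociParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    min_prominence: float = 5.0
    min_ter_fraction: float = 0.15
    refine: Literal["centroid", "gauss"] = "centroid"
    ratio_mode: Literal["pooled", "per_cell"] = "pooled"


class BackboneParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_angular_bins: int = 72
    support_median_fraction: float = 0.25
    support_max_fraction: float = 0.10
    bin_um: float = 0.13
    representative_length_um: float = 3.5


class ClusterParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    stop_snr: float = 3.0
    max_spots: int = 40
    link_radius: Literal["fwhm", "sigma"] = "fwhm"


class DemographParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    order: Literal["contrast", "input"] = "contrast"
    contrast_method: Literal["michelson", "cv"] = "michelson"


class BootstrapParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    picks_per_series: int = 100
    n_boot: int = 25


class PipelineConfig(BaseModel):
    """Full end-to-end pipeline configuration."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    output_dir: Optional[str] = None
    pixel_size_nm: float = 65.35
    psf_sigma_nm: float = 120.0
    channels: dict[str, str] = Field(
        default_factory=lambda: {"dna": "DNA", "parb": "PARB", "smc": "SMC",
                                 "cell": "CELL", "ter": "TER"}
    )
    input_paths: list[str] = Field(default_factory=list)
    channel_map: Optional[dict[str, int]] = None
    simulate: Optional[SimulateBlock] = Field(default_factory=SimulateBlock)
    segment: SegmentParams = Field(default_factory=SegmentParams)
    foci: FociParams = Field(default_factory=FociParams)
    backbone: BackboneParams = Field(default_factory=BackboneParams)
    clusters: ClusterParams = Field(default_factory=ClusterParams)
    demograph: DemographParams = Field(default_factory=DemographParams)
    shapeclass: ShapeClassParams = Field(default_factory=ShapeClassParams)
    bootstrap: BootstrapParams = Field(default_factory=BootstrapParams)

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
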