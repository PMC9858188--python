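"""Pipeline configuration: every threshold in one serializable object.

The config round-trips losslessly through YAML; unknown keys are rejected so
typos fail loudly instead of silently falling back to defaults.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cells import BrownRange, SegmentationParams
from .errors import InvalidInputError
from .scoring import DEFAULT_INTERVALS, ThresholdTable
from .stains import RUIFROK_DAB, RUIFROK_HEMATOXYLIN, StainVectors


@dataclass
class PipelineConfig:
    version: str = "0.1"
    seed: int = 0
    # tiling
    classify_tile_size: int = 256
    score_tile_size: int = 512
    min_tissue_fraction: float = 0.25
    mask_max_side: int = 2048
    hs_combine: str = "and"
    # tumor detection
    classifier_backend: str = "heuristic"
    checkpoint: str | None = None
    probability_threshold: float = 0.5
    tumor_tile_fraction: float = 0.5
    # stain measurement
    brown_hue_deg: tuple[float, float] = (8.0, 40.0)
    brown_s_min: float = 0.08
    brown_v: tuple[float, float] = (0.10, 1.0)
    od_base: str = "log10"
    stain_hematoxylin: tuple[float, float, float] = RUIFROK_HEMATOXYLIN
    stain_dab: tuple[float, float, float] = RUIFROK_DAB
    # segmentation
    min_area: int = 30
    max_area_factor: float = 3.0
    marker_min_distance: int | None = None
    expand_distance: float = 6.0
    ring_width: int = 2
    # scoring
    completeness_cutoff: float = 0.9
    integration: str = "median"
    thresholds: dict = field(
        default_factory=lambda: {
            idx: {c: list(iv) for c, iv in cls_map.items()}
            for idx, cls_map in DEFAULT_INTERVALS.items()
        }
    )

    # -- derived objects ----------------------------------------------------
    def stain_vectors(self) -> StainVectors:
        return StainVectors.from_pair(self.stain_hematoxylin, self.stain_dab)

    def brown_range(self) -> BrownRange:
        return BrownRange(
            hue_deg=tuple(self.brown_hue_deg),
            s_min=self.brown_s_min,
            v=tuple(self.brown_v),
        )

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            min_area=self.min_area,
            max_area_factor=self.max_area_factor,
            marker_min_distance=self.marker_min_distance,
            expand_distance=self.expand_distance,
        )

    def threshold_table(self) -> ThresholdTable:
        return ThresholdTable(
            intervals={
                idx: {c: tuple(iv) for c, iv in cls_map.items()}
                for idx, cls_map in self.thresholds.items()
            }
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("brown_hue_deg", "brown_v", "stain_hematoxylin", "stain_dab"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("brown_hue_deg", "brown_v", "stain_hematoxylin", "stain_dab"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
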