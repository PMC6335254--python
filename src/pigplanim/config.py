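"""Run configuration aggregating the study constants.

Defaults reproduce the study conditions — lens at 245 cm, a 0.420 m²
reference board, reference heights 69/29 cm, loading density 235 kg/m² with
no surcharge, cohort weights spanning 75-133 kg — so the reproduction
command needs no arguments. A YAML file with the same nested keys overrides
any subset.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .planimetry import SegmentationConfig
from .scene import CameraModel, REFERENCE_BOARD_AREA_M2
from .space import LegalRequirement

__all__ = ["CohortSpec", "RunConfig"]


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort parameters: size, weight span, noise, seed."""

    n_per_posture: int = 2
    weight_min_kg: float = 75.0
    weight_max_kg: float = 133.0
    shape_noise: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class BoardConfig:
    known_area_m2: float = REFERENCE_BOARD_AREA_M2
    aspect: float = 2.8


@dataclass(frozen=True)
class RunConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    board: BoardConfig = field(default_factory=BoardConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    legal: LegalRequirement = field(default_factory=LegalRequirement)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            camera=CameraModel(**raw.get("camera", {})),
            board=BoardConfig(**raw.get("board", {})),
            segmentation=SegmentationConfig(**raw.get("segmentation", {})),
            legal=LegalRequirement(**raw.get("legal", {})),
            cohort=CohortSpec(**raw.get("cohort", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
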