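"""Run configuration: schema, defaults, YAML loading, provenance hash.

Field-protocol defaults follow common practice for V2-stage maize trials:
area/shape filter thresholds of 0.3 relative to the collection means, a
4 cm merge buffer, and a row-membership buffer of one third of the row
width.  The CLI accepts centimeters for agronomic lengths (plant height,
buffer) because field protocols are written in cm; everything is stored in
meters internally.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import CameraModel


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_mode: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None
    t_area: float = 0.3
    t_shape: float = 0.3
    shape_keep: str = "above"
    dilation_radius_m: float = 0.02       # merge buffer: fragments of one plant
                                          # sit closer than this; neighbors do not
    # bit-depth band maxima keep EXG image-independent, so one fixed
    # threshold works across a flight; "per_image" uses observed maxima
    normalization: str = "bit_depth"


@dataclass(frozen=True)
class RowsConfig:
    angle_deg: float = 90.0               # per-image prior from planting practice
    row_width_m: float = 0.765
    buffer_frac: float = 1.0 / 3.0
    weed_tolerance_m: float | None = None  # default: buffer_frac * row_width
    min_members_frac: float = 0.3          # dissolve ridges sparser than this
                                           # fraction of the fullest row
    refine_iters: int = 1
    seed_mode: str = "center"
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    camera: CameraModel
    plant_height_m: float
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rows: RowsConfig = field(default_factory=RowsConfig)
    permissive_borders: bool = True
    exclude_truncated: bool = False

    @property
    def weed_tolerance_m(self) -> float:
        if self.rows.weed_tolerance_m is not None:
            return self.rows.weed_tolerance_m
        return self.rows.buffer_frac * self.rows.row_width_m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["camera"] = {
            "height_m": self.camera.height_m,
            "aov_deg": math.degrees(self.camera.aov_rad),
            "width_px": self.camera.width_px,
            "height_px": self.camera.height_px,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            cam_raw = raw["camera"]
            camera = CameraModel.from_degrees(
                float(cam_raw["height_m"]),
                float(cam_raw["aov_deg"]),
                int(cam_raw["width_px"]),
                int(cam_raw["height_px"]),
            )
            plant = raw["plant"]
            if "height_m" in plant:
                plant_height = float(plant["height_m"])
            else:
                plant_height = float(plant["height_cm"]) / 100.0
        except KeyError as exc:
            raise ConfigError(f"missing required config field: {exc}") from exc
        seg_raw = dict(raw.get("segmentation", {}))
        if "dilation_radius_cm" in seg_raw:
            seg_raw["dilation_radius_m"] = float(seg_raw.pop("dilation_radius_cm")) / 100.0
        rows_raw = dict(raw.get("rows", {}))
        if "row_width_cm" in rows_raw:
            rows_raw["row_width_m"] = float(rows_raw.pop("row_width_cm")) / 100.0
        if "weed_tolerance_cm" in rows_raw:
            rows_raw["weed_tolerance_m"] = float(rows_raw.pop("weed_tolerance_cm")) / 100.0
        try:
            seg = SegmentationConfig(**seg_raw)
            rows = RowsConfig(**rows_raw)
        except TypeError as exc:
            raise ConfigError(f"invalid config field: {exc}") from exc
        return cls(
            camera=camera,
            plant_height_m=plant_height,
            segmentation=seg,
            rows=rows,
            permissive_borders=bool(raw.get("permissive_borders", True)),
            exclude_truncated=bool(raw.get("exclude_truncated", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)
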