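"""Nadir-camera ground geometry.

A camera pointing straight down from height ``H`` with diagonal angle of
view ``v`` images a ground rectangle whose diagonal is ``2 tan(v/2) H``.
Pixel coordinates map linearly onto that rectangle in a top-left metric
frame (x east along columns, y down-image along rows), which is all the
geometry the spacing pipeline needs: no lens distortion, no oblique poses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InvalidCameraError, OutOfFrameError


@dataclass(frozen=True)
class CameraModel:
    """Nadir camera: height above ground, diagonal AOV and sensor size.

    Parameters
    ----------
    height_m : float
        Camera height above the ground plane ``H`` in meters, > 0.
    aov_rad : float
        Diagonal angle of view ``v`` in radians, in (0, pi).
    width_px, height_px : int
        Image width (columns, ``NS``) and height (rows, ``NL``) in pixels.
    """

    height_m: float
    aov_rad: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if not (self.height_m > 0) or not math.isfinite(self.height_m):
            raise InvalidCameraError(f"camera height must be > 0, got {self.height_m}")
        if not (0 < self.aov_rad < math.pi):
            raise InvalidCameraError(f"angle of view must be in (0, pi), got {self.aov_rad}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidCameraError(
                f"pixel dimensions must be positive, got {self.width_px}x{self.height_px}"
            )

    @classmethod
    def from_degrees(
        cls, height_m: float, aov_deg: float, width_px: int, height_px: int
    ) -> "CameraModel":
        return cls(height_m, math.radians(aov_deg), width_px, height_px)

    @property
    def nadir_px(self) -> tuple[float, float]:
        """Image-center pixel directly below the camera."""
        return (self.width_px / 2.0, self.height_px / 2.0)

    @property
    def gsd(self) -> float:
        """Ground sampling distance (meters per pixel along x)."""
        return ground_extent(self)[1] / self.width_px


@dataclass(frozen=True)
class GroundPoint:
    """A point in the image's top-left ground-metric frame (meters)."""

    x_m: float
    y_m: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x_m, self.y_m)


def ground_extent(cam: CameraModel) -> tuple[float, float, float]:
    """Ground rectangle covered by the image.

    Returns ``(L_diagonal, L_width, L_height)`` in meters, where
    ``L_diagonal = 2 tan(v/2) H`` and the width/height split follows the
    sensor aspect ratio, so ``L_width / L_height = NS / NL`` and
    ``L_width**2 + L_height**2 == L_diagonal**2``.
    """
    l_diag = 2.0 * math.tan(cam.aov_rad / 2.0) * cam.height_m
    aspect = math.atan2(cam.height_px, cam.width_px)
    return l_diag, l_diag * math.cos(aspect), l_diag * math.sin(aspect)


def pixel_to_metric(
    x: float, y: float, cam: CameraModel, *, permissive: bool = False
) -> GroundPoint:
    """Convert a (fractional) pixel coordinate to ground meters.

    The map is the corner-origin linear scaling ``x_m = x * L_width / NS``
    (and likewise for y): pixel (0, 0) is the top-left ground corner,
    (NS, NL) the far corner, and the image center the nadir point.

    Out-of-bounds pixels raise :class:`OutOfFrameError`; with
    ``permissive=True`` they are clamped to the frame with a warning, which
    is the sensible behavior for plants truncated at image borders.
    """
    if not (0 <= x <= cam.width_px and 0 <= y <= cam.height_px):
        if not permissive:
            raise OutOfFrameError(
                f"pixel ({x}, {y}) outside frame {cam.width_px}x{cam.height_px}"
            )
        warnings.warn(
            f"pixel ({x:.1f}, {y:.1f}) clamped to the image frame", stacklevel=2
        )
        x = min(max(x, 0.0), float(cam.width_px))
        y = min(max(y, 0.0), float(cam.height_px))
    _, l_w, l_h = ground_extent(cam)
    return GroundPoint(x * l_w / cam.width_px, y * l_h / cam.height_px)


def metric_to_pixel(p: GroundPoint, cam: CameraModel) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_metric` (used by the scene simulator)."""
    _, l_w, l_h = ground_extent(cam)
    return (p.x_m * cam.width_px / l_w, p.y_m * cam.height_px / l_h)


def metric_distance(p1: GroundPoint, p2: GroundPoint) -> float:
    """Planar Euclidean distance between two ground points, in meters."""
    return math.hypot(p1.x_m - p2.x_m, p1.y_m - p2.y_m)


def nadir_point(cam: CameraModel) -> GroundPoint:
    """Ground point directly beneath the camera (the image center)."""
    nx, ny = cam.nadir_px
    return pixel_to_metric(nx, ny, cam)
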