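"""Perspective correction of canopy centroids to stem positions.

A nadir camera sees a plant of height ``AD`` leaning radially away from
the image center: the centroid B of its projected canopy sits outward of
the true stem location A.  Modelling the canopy centroid as bisecting the
stem-to-top ground projection gives the similar-triangles displacement

    AB = AD * OB / (2H - AD)

where O is the nadir point and H the camera height.  Correction moves B
radially inward toward O by AB.  The bisection assumption (the projected
centroid halves the stem-to-top projection) is the model's core
approximation; plant height is a single field-wide scalar, reflecting
uniform early-stage growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import GeometryViolationError, InvalidInputError
from .geometry import CameraModel, GroundPoint, metric_distance, nadir_point, pixel_to_metric
from .segmentation import PlantObject


@dataclass(frozen=True)
class CorrectedPlant:
    """A plant with raw projected centroid B and corrected stem position A."""

    object_id: int
    B: GroundPoint
    A: GroundPoint
    AB: float
    theta: float
    truncated: bool = False


def displacement_magnitude(OB: float, plant_height: float, cam: CameraModel) -> float:
    """Radial displacement AB = AD*OB / (2H - AD) of the canopy centroid."""
    if plant_height < 0:
        raise InvalidInputError(f"plant height must be >= 0, got {plant_height}")
    if plant_height >= 2.0 * cam.height_m:
        raise GeometryViolationError(
            f"plant height {plant_height} m >= 2 * camera height {cam.height_m} m"
        )
    return plant_height * OB / (2.0 * cam.height_m - plant_height)


def correct_centroid(
    B: GroundPoint,
    plant_height: float,
    cam: CameraModel,
    object_id: int = 0,
    truncated: bool = False,
) -> CorrectedPlant:
    """Move a projected centroid radially toward nadir to its stem position.

    theta is the polar angle of B about the nadir point O (two-argument
    arctangent, so the correction points inward in all four quadrants);
    A = B - AB * (cos theta, sin theta).  A plant at nadir, or of zero
    height, needs no correction.
    """
    O = nadir_point(cam)
    OB = metric_distance(O, B)
    AB = displacement_magnitude(OB, plant_height, cam)
    if OB == 0.0 or AB == 0.0:
        return CorrectedPlant(object_id, B, B, 0.0, 0.0, truncated)
    theta = math.atan2(B.y_m - O.y_m, B.x_m - O.x_m)
    A = GroundPoint(B.x_m - AB * math.cos(theta), B.y_m - AB * math.sin(theta))
    return CorrectedPlant(object_id, B, A, AB, theta, truncated)


def correct_all(
    objects: list[PlantObject],
    plant_height: float,
    cam: CameraModel,
    *,
    permissive: bool = False,
) -> list[CorrectedPlant]:
    """Pixel-to-metric conversion plus centroid correction for a whole image.

    Applies one uniform plant height to every object (field-scale
    assumption); order-preserving.
    """
    out = []
    for obj in objects:
        x, y = obj.centroid_px
        B = pixel_to_metric(x, y, cam, permissive=permissive)
        out.append(correct_centroid(B, plant_height, cam, obj.object_id, obj.truncated))
    return out


def plants_table(plants: list[CorrectedPlant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "object_id": [p.object_id for p in plants],
            "Bx_m": [p.B.x_m for p in plants],
            "By_m": [p.B.y_m for p in plants],
            "Ax_m": [p.A.x_m for p in plants],
            "Ay_m": [p.A.y_m for p in plants],
            "AB_m": [p.AB for p in plants],
            "theta_rad": [p.theta for p in plants],
            "truncated": [p.truncated for p in plants],
        }
    )
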