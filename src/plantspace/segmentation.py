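"""Vegetation segmentation via the Excess Green index.

The classic EXG index ``2g - r - b`` on chromatic (sum-normalized) RGB
coordinates separates green canopy from bare soil.  Thresholding the EXG
image (Otsu or a fixed cutoff), labeling 8-connected components, filtering
outliers on area and perimeter/area shape, and merging shade-split
fragments by dilation yields one object per plant candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, InvalidInputError

#: EXG of a perfectly gray pixel; also assigned to zero-sum (dropout) pixels.
_EXG_NEUTRAL = 0.0


@dataclass(frozen=True)
class PlantObject:
    """A segmented 8-connected component.

    ``centroid_px`` is an (x, y) = (column, row) pair in continuous pixel
    coordinates with the center of pixel (r, c) at (c + 0.5, r + 0.5), so a
    single pixel at (5, 5) has centroid (5.5, 5.5).  ``shape_ratio`` is
    perimeter / area in 1/pixels.
    """

    object_id: int
    rows: np.ndarray
    cols: np.ndarray
    area: int
    perimeter: float
    centroid_px: tuple[float, float]
    truncated: bool = False

    @property
    def shape_ratio(self) -> float:
        return self.perimeter / self.area

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def compute_exg(
    image: np.ndarray,
    *,
    normalization: str = "per_image",
    bit_depth_max: float = 255.0,
) -> np.ndarray:
    """Per-pixel Excess Green index in [-1, 2].

    Each band is first scaled by its maximum brightness — by default the
    per-image band maximum, or the bit-depth maximum (``bit_depth_max``)
    with ``normalization="bit_depth"`` for image-independent scores.  The
    scaled bands are then converted to chromatic coordinates
    ``r = R*/(R*+G*+B*)`` etc. and EXG = 2g - r - b.  Pixels with zero band
    sum (sensor dropouts) score 0 and fall to the background.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise InvalidInputError(f"expected a 3-channel RGB image, got shape {arr.shape}")
    if arr.min() < 0:
        raise InvalidInputError("negative channel values")
    arr = arr[..., :3]
    if normalization == "per_image":
        maxima = arr.reshape(-1, 3).max(axis=0)
        maxima = np.where(maxima > 0, maxima, 1.0)
    elif normalization == "bit_depth":
        maxima = np.full(3, float(bit_depth_max))
    else:
        raise InvalidInputError(f"unknown normalization {normalization!r}")
    norm = arr / maxima
    total = norm.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = norm / total[..., None]
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    exg = 2.0 * g - r - b
    exg[total == 0] = _EXG_NEUTRAL
    return exg


def threshold_vegetation(
    exg: np.ndarray,
    mode: str = "otsu",
    fixed_value: float | None = None,
) -> np.ndarray:
    """Binarize an EXG image; True marks vegetation.

    ``mode="otsu"`` picks the threshold maximizing between-class variance
    of the EXG histogram; ``mode="fixed"`` uses ``fixed_value`` directly
    (the mask is EXG strictly greater than the threshold).
    """
    exg = np.asarray(exg, dtype=np.float64)
    if mode == "otsu":
        if np.ptp(exg) == 0:
            raise DegenerateHistogramError("constant EXG image: Otsu threshold undefined")
        t = threshold_otsu(exg)
    elif mode == "fixed":
        if fixed_value is None:
            raise InvalidInputError("mode='fixed' requires fixed_value")
        t = float(fixed_value)
    else:
        raise InvalidInputError(f"unknown threshold mode {mode!r}")
    return exg > t


def _make_object(object_id: int, rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> PlantObject:
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    patch = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    patch[rows - r0, cols - c0] = True
    # boundary-contour estimate with diagonal steps weighted sqrt(2); a
    # lone pixel estimates 0, replaced by its 1x1 square boundary
    perim = float(measure.perimeter(patch, neighborhood=8))
    if perim == 0.0:
        perim = 4.0
    centroid = (float(cols.mean()) + 0.5, float(rows.mean()) + 0.5)
    nl, ns = shape
    truncated = bool(r0 == 0 or c0 == 0 or r1 == nl - 1 or c1 == ns - 1)
    return PlantObject(object_id, rows, cols, int(rows.size), perim, centroid, truncated)


def extract_objects(mask: np.ndarray) -> list[PlantObject]:
    """Label 8-connected components of a binary mask as plant objects.

    Ids are assigned in raster-scan order of each component's first pixel;
    an empty mask yields an empty list.  Components touching the image
    border are flagged ``truncated``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise InvalidInputError(f"mask must be 2-D, got shape {mask.shape}")
    labels = measure.label(mask, connectivity=2)
    objects = []
    for rp in measure.regionprops(labels):
        coords = rp.coords
        objects.append(_make_object(0, coords[:, 0], coords[:, 1], mask.shape))
    objects.sort(key=lambda o: (int(o.rows[0]), int(o.cols[0])))
    return [
        PlantObject(i, o.rows, o.cols, o.area, o.perimeter, o.centroid_px, o.truncated)
        for i, o in enumerate(objects)
    ]


def filter_objects(
    objects: list[PlantObject],
    t_area: float = 0.3,
    t_shape: float = 0.3,
    shape_keep: str = "above",
) -> list[PlantObject]:
    """Drop outlier objects on area and shape, relative to collection means.

    An object survives when its area exceeds ``t_area`` times the mean area
    AND its shape statistic (perimeter/area) passes the shape test; both
    means are taken over the input collection.  ``shape_keep="above"``
    keeps ratios above ``t_shape`` times the mean; ``"below"`` inverts the
    test (keep ratios below mean / ``t_shape``), favoring compact objects —
    whether ragged or compact outliers are the noise is scene-dependent, so
    the direction is configurable.
    """
    if t_area <= 0 or t_shape <= 0:
        raise InvalidInputError("t_area and t_shape must be > 0")
    if shape_keep not in ("above", "below"):
        raise InvalidInputError(f"shape_keep must be 'above' or 'below', got {shape_keep!r}")
    if not objects:
        return []
    mean_area = float(np.mean([o.area for o in objects]))
    mean_shape = float(np.mean([o.shape_ratio for o in objects]))
    kept = []
    for o in objects:
        if o.area <= t_area * mean_area:
            continue
        if shape_keep == "above":
            if o.shape_ratio <= t_shape * mean_shape:
                continue
        else:
            if o.shape_ratio >= mean_shape / t_shape:
                continue
        kept.append(o)
    return kept


def merge_fragments(
    objects: list[PlantObject],
    dilation_radius: float,
    image_shape: tuple[int, int],
) -> list[PlantObject]:
    """Merge objects whose disk-dilated masks touch (shade-split plants).

    Every object is dilated by a disk of ``dilation_radius`` pixels; objects
    in the same connected component of the dilated union are merged into one
    (pixel sets united, area/perimeter/centroid recomputed).  Merging is
    transitive and conserves the total vegetation pixel count.
    """
    if dilation_radius < 0:
        raise InvalidInputError("dilation_radius must be >= 0")
    if len(objects) <= 1 or dilation_radius == 0:
        return list(objects)
    mask = np.zeros(image_shape, dtype=bool)
    for o in objects:
        mask[o.rows, o.cols] = True
    fat = morphology.dilation(mask, morphology.disk(int(round(dilation_radius))))
    groups = measure.label(fat, connectivity=2)
    merged: dict[int, list[PlantObject]] = {}
    for o in objects:
        key = int(groups[o.rows[0], o.cols[0]])
        merged.setdefault(key, []).append(o)
    out = []
    for members in merged.values():
        rows = np.concatenate([m.rows for m in members])
        cols = np.concatenate([m.cols for m in members])
        out.append(_make_object(0, rows, cols, image_shape))
    out.sort(key=lambda o: (int(o.rows[0]), int(o.cols[0])))
    return [
        PlantObject(i, o.rows, o.cols, o.area, o.perimeter, o.centroid_px, o.truncated)
        for i, o in enumerate(out)
    ]


def segment_image(
    image: np.ndarray,
    *,
    threshold_mode: str = "otsu",
    fixed_threshold: float | None = None,
    t_area: float = 0.3,
    t_shape: float = 0.3,
    shape_keep: str = "above",
    dilation_radius_px: float = 0.0,
    normalization: str = "per_image",
) -> list[PlantObject]:
    """Full segmentation chain: EXG → threshold → label → filter → merge."""
    exg = compute_exg(image, normalization=normalization)
    mask = threshold_vegetation(exg, mode=threshold_mode, fixed_value=fixed_threshold)
    objects = extract_objects(mask)
    objects = filter_objects(objects, t_area=t_area, t_shape=t_shape, shape_keep=shape_keep)
    if dilation_radius_px > 0:
        objects = merge_fragments(objects, dilation_radius_px, mask.shape)
    return objects


def objects_table(objects: list[PlantObject]) -> pd.DataFrame:
    """Tabulate objects (one row each) for CSV export."""
    return pd.DataFrame(
        {
            "object_id": [o.object_id for o in objects],
            "area_px": [o.area for o in objects],
            "perimeter_px": [o.perimeter for o in objects],
            "shape_ratio": [o.shape_ratio for o in objects],
            "centroid_x_px": [o.centroid_px[0] for o in objects],
            "centroid_y_px": [o.centroid_px[1] for o in objects],
            "truncated": [o.truncated for o in objects],
        }
    )
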