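"""Along-row ordering and interval distances.

Each corrected stem position is projected orthogonally onto its nearest
ridge line; the perpendicular feet are ordered by distance from a reference
point placed far before the first plant along the row direction, and the
consecutive differences are the plant-to-plant interval distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError, NoRidgeError
from .geometry import GroundPoint, metric_distance
from .localization import CorrectedPlant
from .rows import Ridge


@dataclass(frozen=True)
class SpacingResult:
    """Ordered per-ridge foot points and consecutive interval distances."""

    ridge_id: int
    ordered_ids: tuple[int, ...]
    foot_points: tuple[GroundPoint, ...]
    intervals: tuple[float, ...]
    cumulative: tuple[float, ...]
    truncated_flags: tuple[bool, ...] = field(default_factory=tuple)


def project_to_ridge(
    plant: CorrectedPlant, ridges: list[Ridge]
) -> tuple[int, GroundPoint]:
    """Nearest ridge (min perpendicular distance) and the foot of A on it.

    Ties on distance go to the lower ridge_id.
    """
    if not ridges:
        raise NoRidgeError("cannot project onto an empty ridge list")
    best = min(ridges, key=lambda r: (r.perpendicular_distance(plant.A), r.ridge_id))
    ux, uy = best.direction
    dx = plant.A.x_m - best.anchor.x_m
    dy = plant.A.y_m - best.anchor.y_m
    t = dx * ux + dy * uy
    foot = GroundPoint(best.anchor.x_m + t * ux, best.anchor.y_m + t * uy)
    return best.ridge_id, foot


def order_and_measure(
    ridge: Ridge,
    feet: list[tuple[int, GroundPoint]],
    *,
    reference_span: float | None = None,
    truncated: dict[int, bool] | None = None,
) -> SpacingResult:
    """Sort foot points along the row and return consecutive intervals.

    A reference point is placed on the ridge line far before the plants
    (``anchor - M * direction`` with M ten times the point-spread diagonal
    unless ``reference_span`` overrides it — for a non-vertical row this is
    the classic far-out x on y = kx + b); feet are sorted by ascending
    distance to it and intervals are the pairwise differences.  Coincident
    feet yield a zero interval and a duplicate-plant warning.
    """
    if truncated is None:
        truncated = {}
    if len(feet) < 2:
        warnings.warn(
            f"ridge {ridge.ridge_id}: fewer than 2 plants, no intervals", stacklevel=2
        )
        ids = tuple(i for i, _ in feet)
        pts = tuple(p for _, p in feet)
        return SpacingResult(ridge.ridge_id, ids, pts, (), (0.0,) * len(feet),
                             tuple(truncated.get(i, False) for i in ids))
    span = reference_span
    if span is None:
        xs = [p.x_m for _, p in feet]
        ys = [p.y_m for _, p in feet]
        span = 10.0 * (math.hypot(max(xs) - min(xs), max(ys) - min(ys)) + 1.0)
    if span <= 0:
        raise InvalidInputError("reference_span must be > 0")
    ux, uy = ridge.direction
    ref = GroundPoint(ridge.anchor.x_m - span * ux, ridge.anchor.y_m - span * uy)
    keyed = sorted(feet, key=lambda f: (metric_distance(ref, f[1]), f[0]))
    ids = tuple(i for i, _ in keyed)
    pts = tuple(p for _, p in keyed)
    cumulative = tuple(metric_distance(ref, p) - metric_distance(ref, pts[0]) for p in pts)
    intervals = tuple(metric_distance(pts[i], pts[i + 1]) for i in range(len(pts) - 1))
    for i, d in enumerate(intervals):
        if d == 0.0:
            warnings.warn(
                f"ridge {ridge.ridge_id}: coincident plants {ids[i]} and {ids[i + 1]} "
                "(duplicate detection?)",
                stacklevel=2,
            )
    return SpacingResult(ridge.ridge_id, ids, pts, intervals, cumulative,
                         tuple(truncated.get(i, False) for i in ids))


def measure_all(
    plants: list[CorrectedPlant],
    ridges: list[Ridge],
    *,
    reference_span: float | None = None,
) -> list[SpacingResult]:
    """Project every plant, then order and measure each ridge with members."""
    by_ridge: dict[int, list[tuple[int, GroundPoint]]] = {r.ridge_id: [] for r in ridges}
    trunc = {p.object_id: p.truncated for p in plants}
    for p in plants:
        rid, foot = project_to_ridge(p, ridges)
        by_ridge[rid].append((p.object_id, foot))
    results = []
    for r in ridges:
        feet = by_ridge[r.ridge_id]
        if not feet:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.append(
                order_and_measure(r, feet, reference_span=reference_span, truncated=trunc)
            )
    return results


def spacing_table(
    results: list[SpacingResult], *, exclude_truncated: bool = False
) -> pd.DataFrame:
    """Interval table (one row per consecutive plant pair).

    With ``exclude_truncated`` intervals touching a border-truncated plant
    are dropped, so edge effects stay out of downstream accuracy metrics.
    """
    rows = []
    for res in results:
        for i, d in enumerate(res.intervals):
            flag = False
            if res.truncated_flags:
                flag = res.truncated_flags[i] or res.truncated_flags[i + 1]
            if exclude_truncated and flag:
                continue
            rows.append(
                {
                    "ridge_id": res.ridge_id,
                    "plant_id_a": res.ordered_ids[i],
                    "plant_id_b": res.ordered_ids[i + 1],
                    "interval_m": d,
                    "touches_truncated": flag,
                }
            )
    return pd.DataFrame(
        rows, columns=["ridge_id", "plant_id_a", "plant_id_b", "interval_m", "touches_truncated"]
    )


def ridge_summary(results: list[SpacingResult]) -> pd.DataFrame:
    """Per-ridge interval summary: mean, sd and count."""
    rows = []
    for res in results:
        iv = pd.Series(res.intervals, dtype=float)
        rows.append(
            {
                "ridge_id": res.ridge_id,
                "mean_interval_m": iv.mean() if len(iv) else float("nan"),
                "sd_interval_m": iv.std(ddof=1) if len(iv) > 1 else float("nan"),
                "n_intervals": len(iv),
            }
        )
    return pd.DataFrame(rows, columns=["ridge_id", "mean_interval_m", "sd_interval_m", "n_intervals"])
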