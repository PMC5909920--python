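"""Crop row (ridge) detection by iterative buffer assignment.

Row direction and nominal row width are prior knowledge from planting
practice.  Starting from an unassigned seed plant, a candidate line is cast
through it at the known angle; all plants within a perpendicular buffer
(default one third of the row width) become members, the line is recentered
on their mean position, and the process repeats until every plant belongs
to a ridge.  Plants far from every detected ridge are weeds — in a sprayed
field, the survivors sit between the rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import GroundPoint
from .localization import CorrectedPlant

_VERTICAL_EPS = 1e-6


@dataclass(frozen=True)
class Ridge:
    """A row line in point-direction form: anchor + t * (cos a, sin a).

    ``angle`` is the row direction in [0, pi), counterclockwise from +x.
    ``offset`` is the signed perpendicular position of the line, the sort
    key for ridge ids.  Slope/intercept (``k``, ``b``) exist only for
    non-vertical rows.
    """

    ridge_id: int
    angle: float
    anchor: GroundPoint
    member_ids: tuple[int, ...] = field(default_factory=tuple)

    @property
    def direction(self) -> tuple[float, float]:
        return (math.cos(self.angle), math.sin(self.angle))

    @property
    def normal(self) -> tuple[float, float]:
        return (-math.sin(self.angle), math.cos(self.angle))

    @property
    def offset(self) -> float:
        nx, ny = self.normal
        return self.anchor.x_m * nx + self.anchor.y_m * ny

    @property
    def is_vertical(self) -> bool:
        return abs(math.cos(self.angle)) <= _VERTICAL_EPS

    @property
    def slope_intercept(self) -> tuple[float, float] | None:
        """(k, b) of y = kx + b, or None for a vertical row."""
        if self.is_vertical:
            return None
        k = math.tan(self.angle)
        return k, self.anchor.y_m - k * self.anchor.x_m

    def perpendicular_distance(self, p: GroundPoint) -> float:
        nx, ny = self.normal
        return abs(p.x_m * nx + p.y_m * ny - self.offset)


def _signed_offset(p: GroundPoint, angle: float) -> float:
    return -p.x_m * math.sin(angle) + p.y_m * math.cos(angle)


def detect_ridges(
    plants: list[CorrectedPlant],
    angle: float,
    row_width: float,
    buffer_frac: float = 1.0 / 3.0,
    *,
    refine_iters: int = 1,
    seed_mode: str = "center",
    rng: np.random.Generator | None = None,
    center: GroundPoint | None = None,
) -> list[Ridge]:
    """Assign every plant to a row line at the known row angle.

    Each round seeds a candidate line through one unassigned plant, collects
    unassigned plants within ``buffer_frac * row_width`` perpendicular
    distance, and recenters the line on the members' mean position
    (``refine_iters`` collect/recenter passes, membership usually stable
    after one).  ``seed_mode="center"`` picks the unassigned plant nearest
    the scene center for reproducibility; ``"random"`` draws from ``rng``.
    Returned ridges are sorted by perpendicular offset and renumbered.
    """
    if not plants:
        return []
    if row_width <= 0:
        raise InvalidInputError("row_width must be > 0")
    if not (0 < buffer_frac < 0.5):
        raise InvalidInputError("buffer_frac must be in (0, 0.5)")
    if seed_mode == "random" and rng is None:
        rng = np.random.default_rng(0)
    buffer_dist = buffer_frac * row_width
    offsets = np.array([_signed_offset(p.A, angle) for p in plants])
    if center is None:
        cx = float(np.mean([p.A.x_m for p in plants]))
        cy = float(np.mean([p.A.y_m for p in plants]))
    else:
        cx, cy = center.x_m, center.y_m
    center_d2 = np.array([(p.A.x_m - cx) ** 2 + (p.A.y_m - cy) ** 2 for p in plants])

    unassigned = set(range(len(plants)))
    ridges: list[Ridge] = []
    while unassigned:
        idx = sorted(unassigned)
        if seed_mode == "random":
            seed = idx[int(rng.integers(len(idx)))]
        else:
            seed = min(idx, key=lambda i: (center_d2[i], i))
        line_off = offsets[seed]
        members = [seed]
        for _ in range(max(1, refine_iters)):
            members = [i for i in idx if abs(offsets[i] - line_off) <= buffer_dist]
            new_off = float(np.mean(offsets[members]))
            if new_off == line_off:
                break
            line_off = new_off
        ax = float(np.mean([plants[i].A.x_m for i in members]))
        ay = float(np.mean([plants[i].A.y_m for i in members]))
        ridges.append(
            Ridge(0, angle, GroundPoint(ax, ay), tuple(plants[i].object_id for i in members))
        )
        unassigned.difference_update(members)

    ridges.sort(key=lambda r: r.offset)
    return [Ridge(i, r.angle, r.anchor, r.member_ids) for i, r in enumerate(ridges)]


def prune_minor_ridges(ridges: list[Ridge], min_frac: float = 0.3) -> list[Ridge]:
    """Dissolve sparse ridges that isolated weeds seeded for themselves.

    A genuine planting row collects many members; a weed sitting mid
    inter-row ends up on a line of its own (or with one neighbor).  Ridges
    with fewer than ``max(2, min_frac * fullest-row count)`` members are
    dropped, leaving their members to the distance-based weed filter.  If
    no ridge has 3+ members (tiny scenes) nothing is pruned.
    """
    if not ridges:
        return []
    top = max(len(r.member_ids) for r in ridges)
    if top < 3:
        return list(ridges)
    n_min = max(2, math.ceil(min_frac * top))
    kept = [r for r in ridges if len(r.member_ids) >= n_min]
    return [Ridge(i, r.angle, r.anchor, r.member_ids) for i, r in enumerate(kept)]


def filter_weeds_by_ridge(
    plants: list[CorrectedPlant],
    ridges: list[Ridge],
    tolerance: float,
) -> tuple[list[CorrectedPlant], list[CorrectedPlant]]:
    """Split plants into (kept, removed) by distance to the nearest ridge.

    A plant farther than ``tolerance`` from every ridge line is declared a
    weed.  The two lists partition the input; with no ridges at all,
    everything is removed (with a warning).
    """
    if tolerance <= 0:
        raise InvalidInputError("tolerance must be > 0")
    if not ridges:
        warnings.warn("no ridges detected: all plants classified as weeds", stacklevel=2)
        return [], list(plants)
    kept, removed = [], []
    for p in plants:
        d = min(r.perpendicular_distance(p.A) for r in ridges)
        (kept if d <= tolerance else removed).append(p)
    return kept, removed


def ridges_table(ridges: list[Ridge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ridge_id": [r.ridge_id for r in ridges],
            "angle_rad": [r.angle for r in ridges],
            "anchor_x_m": [r.anchor.x_m for r in ridges],
            "anchor_y_m": [r.anchor.y_m for r in ridges],
            "offset_m": [r.offset for r in ridges],
            "n_members": [len(r.member_ids) for r in ridges],
        }
    )
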