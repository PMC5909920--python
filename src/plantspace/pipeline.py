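"""End-to-end pipeline: segmentation → localization → rows → spacing.

Also hosts the truth-vs-estimate evaluation glue (matching detected ridges
to true rows by perpendicular offset) and the diagnostic overlay renderer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import localization, metrics, rows, segmentation, spacing
from .config import RunConfig
from .errors import InvalidInputError
from .geometry import nadir_point
from .localization import CorrectedPlant, plants_table
from .rows import Ridge, ridges_table
from .segmentation import PlantObject, objects_table
from .spacing import SpacingResult, spacing_table
from .synthetic import SceneTruth


@dataclass
class PipelineResult:
    """Everything one image run produces, ready for CSV export."""

    config: RunConfig
    objects: list[PlantObject]
    plants: list[CorrectedPlant]
    weeds: list[CorrectedPlant]
    ridges: list[Ridge]
    spacings: list[SpacingResult]
    warnings: list[str]

    def tables(self) -> dict[str, pd.DataFrame]:
        weed_ids = {w.object_id for w in self.weeds}
        obj = objects_table(self.objects)
        plt = plants_table(self.plants + self.weeds).sort_values("object_id")
        plt["is_weed"] = plt["object_id"].isin(weed_ids)
        out = {
            "objects": obj,
            "plants": plt.reset_index(drop=True),
            "ridges": ridges_table(self.ridges),
            "spacing": spacing_table(
                self.spacings, exclude_truncated=self.config.exclude_truncated
            ),
            "spacing_summary": spacing.ridge_summary(self.spacings),
        }
        h = self.config.config_hash()
        for df in out.values():
            df["config_hash"] = h
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        import json

        from . import __version__

        log = [
            f"plantspace version: {__version__}",
            f"config_hash: {self.config.config_hash()}",
            "config: " + json.dumps(self.config.to_dict(), sort_keys=True),
        ]
        log += [f"WARN: {w}" for w in self.warnings]
        (outdir / "run.log").write_text("\n".join(log) + "\n")

    def intervals_by_ridge(self) -> dict[int, list[float]]:
        tab = spacing_table(self.spacings, exclude_truncated=self.config.exclude_truncated)
        return {
            int(rid): grp["interval_m"].tolist()
            for rid, grp in tab.groupby("ridge_id")
        }


def run_pipeline(image: np.ndarray | str | Path, config: RunConfig) -> PipelineResult:
    """Run the full spacing pipeline on one nadir RGB image."""
    if isinstance(image, (str, Path)):
        image = iio.imread(image)
    image = np.asarray(image)
    if image.ndim != 3:
        raise InvalidInputError(f"expected an RGB image, got shape {image.shape}")
    cam = config.camera
    if image.shape[0] != cam.height_px or image.shape[1] != cam.width_px:
        raise InvalidInputError(
            f"image is {image.shape[1]}x{image.shape[0]} px but the camera says "
            f"{cam.width_px}x{cam.height_px}"
        )
    seg = config.segmentation
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        objects = segmentation.segment_image(
            image,
            threshold_mode=seg.threshold_mode,
            fixed_threshold=seg.fixed_threshold,
            t_area=seg.t_area,
            t_shape=seg.t_shape,
            shape_keep=seg.shape_keep,
            dilation_radius_px=seg.dilation_radius_m / cam.gsd,
            normalization=seg.normalization,
        )
        plants = localization.correct_all(
            objects, config.plant_height_m, cam, permissive=config.permissive_borders
        )
        rcfg = config.rows
        ridges = rows.detect_ridges(
            plants,
            math.radians(rcfg.angle_deg),
            rcfg.row_width_m,
            rcfg.buffer_frac,
            refine_iters=rcfg.refine_iters,
            seed_mode=rcfg.seed_mode,
            rng=np.random.default_rng(rcfg.seed),
            center=nadir_point(cam),
        )
        ridges = rows.prune_minor_ridges(ridges, rcfg.min_members_frac)
        kept, removed = rows.filter_weeds_by_ridge(plants, ridges, config.weed_tolerance_m)
        if removed:
            # re-detect rows on the cleaned collection so weed clusters
            # cannot drag a ridge line off the planting row
            ridges = rows.detect_ridges(
                kept,
                math.radians(rcfg.angle_deg),
                rcfg.row_width_m,
                rcfg.buffer_frac,
                refine_iters=rcfg.refine_iters,
                seed_mode=rcfg.seed_mode,
                rng=np.random.default_rng(rcfg.seed),
                center=nadir_point(cam),
            )
        spacings = spacing.measure_all(kept, ridges)
        collected.extend(str(w.message) for w in caught)
    for p in kept:
        if p.truncated:
            collected.append(f"object {p.object_id} truncated at the image border")
    for w in removed:
        collected.append(f"object {w.object_id} removed as a weed")
    return PipelineResult(config, objects, kept, removed, ridges, spacings, collected)


# ---------------------------------------------------------------------------
# evaluation against simulator truth


def match_rows(detected: list[Ridge], truth_rows: list[Ridge]) -> dict[int, int]:
    """Map detected ridge_id -> truth row id by nearest perpendicular offset.

    Greedy one-to-one matching in order of increasing offset gap; unmatched
    ridges (spurious or missed rows) are left out.
    """
    pairs = sorted(
        ((abs(d.offset - t.offset), d.ridge_id, t.ridge_id) for d in detected for t in truth_rows)
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    mapping: dict[int, int] = {}
    for _, did, tid in pairs:
        if did in used_d or tid in used_t:
            continue
        mapping[did] = tid
        used_d.add(did)
        used_t.add(tid)
    return mapping


def evaluate_against_truth(
    result: PipelineResult,
    truth: SceneTruth,
    mode: str = "rowwise",
    design_d: float | None = None,
) -> metrics.EvalReport:
    """Score one pipeline run against the simulator's ground truth.

    Detected ridges are matched to true rows by offset; intervals are then
    compared per row, pairwise (rank-matched, relative to the design
    spacing) or row-wise (unpaired means).  Inputs to the metrics are in
    meters; the report is therefore in meters too.
    """
    mapping = match_rows(result.ridges, list(truth.rows))
    est = {
        mapping[rid]: vals
        for rid, vals in result.intervals_by_ridge().items()
        if rid in mapping and vals
    }
    return metrics.evaluate_rows(est, dict(truth.intervals_by_row), mode=mode, design_d=design_d)


# ---------------------------------------------------------------------------
# diagnostic overlay


def render_overlay(image: np.ndarray, result: PipelineResult) -> np.ndarray:
    """Draw raw centroids (red), corrected stems (blue) and ridges (white)."""
    from .geometry import metric_to_pixel

    img = np.asarray(image).copy()
    cam = result.config.camera
    nl, ns = img.shape[:2]

    def _dot(p, color, r=3):
        x, y = metric_to_pixel(p, cam)
        cx, cy = int(round(x)), int(round(y))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        sel = yy**2 + xx**2 <= r * r
        rr = np.clip(cy + yy[sel], 0, nl - 1)
        cc = np.clip(cx + xx[sel], 0, ns - 1)
        img[rr, cc] = color

    for ridge in result.ridges:
        ux, uy = ridge.direction
        span = math.hypot(ns, nl) * cam.gsd
        tt = np.linspace(-span, span, 4 * max(nl, ns))
        from .geometry import GroundPoint, ground_extent

        _, l_w, l_h = ground_extent(cam)
        xs = ridge.anchor.x_m + tt * ux
        ys = ridge.anchor.y_m + tt * uy
        px = np.round(xs * cam.width_px / l_w).astype(int)
        py = np.round(ys * cam.height_px / l_h).astype(int)
        ok = (px >= 0) & (px < ns) & (py >= 0) & (py < nl)
        img[py[ok], px[ok]] = (255, 255, 255)
    for p in result.plants:
        _dot(p.B, (255, 40, 40))
        _dot(p.A, (40, 40, 255))
    for w in result.weeds:
        _dot(w.A, (255, 255, 0), r=2)
    return img
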