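"""Reference validation trials on the built-in simulator.

Two canonical designs, mirroring how such a pipeline is validated in
practice:

* ``controlled_trial`` — artificial-plant conditions: 76.5 cm rows, design
  spacings of 18/27/36 cm, camera at 2–3 m with a 72° diagonal AOV, 10 cm
  plants, mild spacing jitter, clean soil.  Scored pairwise against truth,
  reporting the relative error r = d_e / d per scene.
* ``field_trial`` — field conditions: 53 cm rows, ~20 cm intervals with
  2 cm jitter, 15 cm plants, weeds between rows and residue streaks,
  camera at 2–5 m.  Scored row-wise (unpaired means) after weed filtering,
  reporting the signed per-row bias d_t.

Scene seeds derive deterministically from one base seed, so a trial is a
pure function of that seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .config import RowsConfig, RunConfig, SegmentationConfig
from .geometry import CameraModel
from .pipeline import evaluate_against_truth, run_pipeline
from .synthetic import SceneSpec, _child_seed, render_scene

#: sensor model used by the validation trials (72° diagonal AOV, 4:3 frame)
TRIAL_AOV_DEG = 72.0
TRIAL_WIDTH_PX = 960
TRIAL_HEIGHT_PX = 720


def _camera(height_m: float) -> CameraModel:
    return CameraModel.from_degrees(height_m, TRIAL_AOV_DEG, TRIAL_WIDTH_PX, TRIAL_HEIGHT_PX)


def controlled_trial(
    base_seed: int,
    intervals: tuple[float, ...] = (0.18, 0.27, 0.36),
    heights: tuple[float, ...] = (2.0, 3.0),
    reps: int = 2,
) -> pd.DataFrame:
    """Clean-scene accuracy sweep; one row per scene with pairwise metrics.

    Columns: interval_m, height_m, seed, n_true, n_est, d_e_cm, r_pct,
    d_t_cm.  Defaults give 12 scenes (3 spacings x 2 heights x 2 reps).
    """
    rows = []
    idx = 0
    for s in intervals:
        for h in heights:
            for _ in range(reps):
                cam = _camera(h)
                spec = SceneSpec(
                    camera=cam,
                    interval=s,
                    plant_height=0.10,
                    spacing_jitter_sd=0.01,
                    lateral_jitter_sd=0.005,
                    rng_seed=_child_seed(base_seed, idx),
                )
                img, truth = render_scene(spec)
                cfg = RunConfig(camera=cam, plant_height_m=spec.plant_height)
                res = run_pipeline(img, cfg)
                rep = evaluate_against_truth(res, truth, mode="pairwise", design_d=s)
                rows.append(
                    {
                        "interval_m": s,
                        "height_m": h,
                        "seed": spec.rng_seed,
                        "n_true": rep.n_prime,
                        "n_est": rep.n,
                        "d_e_cm": rep.d_e * 100.0,
                        "r_pct": rep.r * 100.0,
                        "d_t_cm": rep.d_t * 100.0,
                    }
                )
                idx += 1
    return pd.DataFrame(rows)


def field_trial(
    base_seed: int,
    heights: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    reps: int = 3,
) -> pd.DataFrame:
    """Weedy field sweep; one row per (scene, crop row) with row-wise bias.

    Columns: height_m, seed, row_id, d_t_cm, r_pct, plus scene-level plant
    and weed bookkeeping.  Defaults give 12 scenes x ~3-11 rows each.
    """
    rows = []
    idx = 0
    for h in heights:
        for _ in range(reps):
            cam = _camera(h)
            spec = SceneSpec(
                camera=cam,
                row_width=0.53,
                interval=0.20,
                plant_height=0.15,
                spacing_jitter_sd=0.02,
                lateral_jitter_sd=0.008,
                weed_density=1.0,
                residue_density=0.5,
                rng_seed=_child_seed(base_seed, 1000 + idx),
            )
            img, truth = render_scene(spec)
            cfg = RunConfig(
                camera=cam,
                plant_height_m=spec.plant_height,
                segmentation=SegmentationConfig(
                    threshold_mode="fixed", fixed_threshold=0.1
                ),
                rows=RowsConfig(row_width_m=spec.row_width),
            )
            res = run_pipeline(img, cfg)
            rep = evaluate_against_truth(res, truth, mode="rowwise")
            for row_id, d_t, r in rep.per_row:
                rows.append(
                    {
                        "height_m": h,
                        "seed": spec.rng_seed,
                        "row_id": row_id,
                        "d_t_cm": d_t * 100.0,
                        "r_pct": r * 100.0,
                        "n_true_plants": truth.n_plants,
                        "n_weeds_rendered": len(truth.weed_points),
                        "n_kept": len(res.plants),
                        "n_weeded": len(res.weeds),
                    }
                )
            idx += 1
    return pd.DataFrame(rows)
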