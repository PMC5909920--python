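# plantspace

Plant-to-plant spacing estimation for row crops from nadir UAV RGB imagery.

Stand uniformity — how evenly plants emerge along the row — is a strong
driver of final yield in maize and other row crops, and it cannot be read
off a plant count alone. `plantspace` measures the within-row interval
distance between individual plants from a single downward-looking RGB
photograph taken by a low-flying drone, given a handful of agronomic
priors: camera height, angle of view, average plant height, and the row
direction and width used at planting.

The package is aimed at precision-agriculture researchers and agronomists
who want per-plant spacing maps at emergence (V2–V4), when plants are
small, distinct, and their height is nearly uniform.

## Method

The pipeline runs four stages on one image:

1. **Segmentation.** The Excess Green index, EXG = 2g − r − b on chromatic
   (sum-normalized) RGB coordinates, separates canopy from soil. The EXG
   image is binarized (Otsu or a fixed threshold), 8-connected components
   become candidate plants, outliers are dropped when their area or
   perimeter/area ratio falls outside thresholds relative to the
   collection mean, and shade-split fragments are merged by disk dilation.
2. **Localization.** A nadir camera at height *H* with diagonal angle of
   view *v* covers a ground diagonal 2 tan(*v*/2)·*H*; pixels map linearly
   to ground meters. A plant of height *AD* leans radially away from the
   image center, so its canopy centroid *B* sits outward of the true stem
   position *A* by

   &nbsp;&nbsp;&nbsp;&nbsp;AB = AD · OB / (2H − AD),

   where *O* is the nadir point. Each centroid is moved radially inward
   by this amount.
3. **Row detection.** With the row angle and nominal row width known from
   planting practice, lines are grown iteratively: seed an unassigned
   plant, collect all plants within a perpendicular buffer of ⅓ row
   width, recenter the line on their mean. Plants far from every detected
   row line are classified as weeds and removed.
4. **Spacing.** Stem positions are projected orthogonally onto their
   nearest row line, ordered along the row from a far reference point,
   and consecutive distances are the interval estimates.

Accuracy is quantified by the mean absolute interval error
d_e = mean |ed_i − d_i|, the relative error r = d_e / d against the design
spacing d, and the signed bias d_t; in field conditions, where estimated
and true plant counts differ, a row-wise bias d_t = mean(est) − mean(truth)
and r = d_t / mean(truth) are used instead.

A forward-model scene simulator renders row-planted scenes (plants as
opposite-leaf-pair glyphs whose centroids are displaced by the same radial
law, plus soil texture, weeds and residue) with exact ground truth, making
the whole pipeline testable end to end without field data.

## Worked example

```python
from plantspace import CameraModel, RunConfig, SceneSpec, render_scene, run_pipeline
from plantspace.pipeline import evaluate_against_truth

cam = CameraModel.from_degrees(2.0, 72.0, 960, 720)     # 2 m flight, 72 deg AOV
spec = SceneSpec(camera=cam, interval=0.18, spacing_jitter_sd=0.01, rng_seed=7)
image, truth = render_scene(spec)                        # nadir scene + ground truth

cfg = RunConfig(camera=cam, plant_height_m=0.10)
result = run_pipeline(image, cfg)
print(f"detected {len(result.plants)} plants on {len(result.ridges)} rows "
      f"(truth: {truth.n_plants} plants on {len(truth.rows)} rows)")

report = evaluate_against_truth(result, truth, mode="pairwise", design_d=spec.interval)
print(f"d_e = {report.d_e*100:.2f} cm   r = {report.r*100:.2f}%   d_t = {report.d_t*100:+.2f} cm")
```

prints

```
detected 27 plants on 3 rows (truth: 27 plants on 3 rows)
d_e = 0.07 cm   r = 0.40%   d_t = +0.00 cm
```

i.e. every simulated plant was found, assigned to the correct row, and the
18 cm design spacing was recovered with a 0.07 cm mean absolute error
(0.4 % relative); the near-zero signed bias says errors are symmetric, not
systematic.

The same pipeline is available from the shell:

```sh
plantspace simulate --config scene.yaml --out sim/
plantspace run sim/scene.png --config run.yaml --out out/ --emit-overlay
plantspace evaluate --spacing out/spacing.csv --ridges out/ridges.csv \
    --truth sim/truth.json --mode rowwise --out report.csv
```

`plantspace grid` sweeps a spacing × camera-height scenario grid
(`S_18cm_2m`, …), and `--emit-overlay` writes a diagnostic image with raw
centroids (red), corrected stems (blue) and row lines (white).

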