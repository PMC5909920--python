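# Methods

This note documents the model behind `plantspace`, the parameters that
matter, the design decisions taken where the problem was genuinely open,
and what the simulator-based validation does and does not demonstrate.

## Camera geometry

A nadir camera at height *H* (m) with **diagonal** angle of view *v*
covers a ground rectangle of diagonal L_diag = 2 tan(*v*/2)·*H*, split
into width and height by the sensor aspect ratio (L_w/L_h = NS/NL). Pixel
coordinates are continuous, origin at the top-left pixel corner; the map
to ground meters is the corner-origin linear scaling x_m = x·L_w/NS. The
nadir point is the image center (NS/2, NL/2). Some manufacturers quote
the AOV horizontally; this implementation treats *v* strictly as the
diagonal AOV and documents that choice rather than guessing per camera.
Lens distortion, rolling shutter and oblique poses are out of scope.

Out-of-frame pixel conversions raise an error by default; a permissive
mode clamps to the frame with a warning, which is the right behavior for
plants truncated at image borders (common at 1 m flights). Truncated
objects are flagged through the whole pipeline and their intervals can be
excluded from accuracy metrics via `exclude_truncated`.

## Segmentation

EXG is computed on chromatic coordinates r = R*/(R*+G*+B*) etc., after
each band is scaled by a band maximum. Two conventions are offered:

* `bit_depth` (pipeline default): the sensor saturation value (255 for
  8-bit). EXG is then a pure function of the pixel, so one fixed
  threshold behaves identically across a flight.
* `per_image`: the observed per-band maximum of the image. This makes the
  score depend on scene content — a single bright residue streak shifts
  every pixel's chromaticity and can push soil noise over a fixed
  threshold — so it is kept as an option, not the default.

Zero-sum (dropout) pixels get EXG = 0 and fall to the background. A
perfectly gray pixel scores 0; pure green 2; pure red or blue −1.

Thresholding is Otsu (between-class variance on the EXG histogram; a
constant image is rejected as degenerate) or a fixed cutoff. In practice
a fixed 0 works on clean dark soil; brighter, cluttered field scenes need
~0.1 to keep soil and residue out.

Components are 8-connected (diagonal-touching fragments of one plant stay
together). Object perimeter is the boundary-contour estimate with
diagonal steps weighted √2; a single-pixel object, whose estimator is
degenerate, is assigned the 1×1 square boundary length 4 so that the
perimeter/area shape statistic stays defined. Centroids use the
pixel-center-at-half convention (a lone pixel at row 5, col 5 has
centroid (5.5, 5.5)).

The outlier filter keeps objects whose area exceeds `t_area` (default
0.3) times the collection mean area and whose shape statistic passes the
analogous test with `t_shape` (default 0.3). Whether "good" plants have a
high or low perimeter/area is scene-dependent (ragged seedlings vs.
compact weeds), so the direction is configurable (`shape_keep`:
`above` keeps s > t·mean, `below` keeps s < mean/t). Filtering is
relative to the input collection, hence not idempotent — a second pass
sees different means. This is intentional and matches how the thresholds
are specified.

Fragment merging dilates the vegetation mask by a disk of radius
`dilation_radius_m` (default 2 cm on the ground, converted to pixels via
the camera) and unions objects that share a dilated component; merging is
transitive and conserves pixel counts. The radius encodes prior
knowledge: pieces of one shade-split plant sit closer than this, distinct
neighbors at agronomic spacings do not. Radii approaching half the
planting interval will fuse neighbors.

## Stem localization

The canopy centroid *B* of an upright plant is displaced radially outward
from nadir. Modelling the projected centroid as the midpoint of the
stem-to-top ground projection (AC = 2·AB) gives, by similar triangles,
AB = AD·OB/(2H − AD), with AD the plant height. The correction moves *B*
toward *O* by AB along the polar angle θ = atan2(B_y − O_y, B_x − O_x),
valid in all four quadrants. The midpoint assumption is the model's core
approximation: it is exact for a radially symmetric canopy and degrades
when leaves point predominantly to one side. AD is a single field-wide
scalar — defensible at V2–V4 when growth is uniform; per-plant heights
are out of scope. The correction requires AD < 2H (and the simulator's
forward model AD < H); it vanishes at nadir, for flat objects, and as
H → ∞ (AB → AD·OB/2H).

## Row detection

Row angle and width are per-image priors from planting practice, not
estimated (Hough/vanishing-point detectors are deliberately not used).
The iterative construction: pick an unassigned seed plant, cast a line
through it at the row angle, collect unassigned plants within a
perpendicular buffer of `buffer_frac`·w (default ⅓ of the row width w),
recenter the line on the members' mean, repeat until all plants are
assigned. The default does one collect–recenter pass per ridge;
`refine_iters` allows re-collecting around the updated line until
membership stabilizes. Seeding defaults to the unassigned plant nearest
the scene center (deterministic); seeded random choice is available, and
on well-separated rows the recovered offsets are stable across seedings
to within the buffer width.

Vertical rows make y = kx + b undefined, so all internal line math is in
point-direction form; slope/intercept are only exported when
|cos angle| > 1e−6. A wrong row-angle prior is surfaced through the mean
member-to-line residual rather than auto-corrected.

Weed filtering is two-staged. First, ridges much sparser than the fullest
row (fewer than max(2, `min_members_frac`·top) members; default fraction
0.3) are dissolved — an isolated weed collects a line of its own, and a
planting row does not. Scenes where no ridge has 3+ members are left
untouched. Second, plants farther than `weed_tolerance_m` (default:
the membership buffer ⅓·w) from every surviving ridge are removed as
weeds, and rows are re-detected on the cleaned collection so a weed
cluster cannot drag a line off its row. Weeds growing *within* the row
remain indistinguishable from crop and are a known limitation. Two or
more aligned weeds in the same inter-row gap of a short-row scene can
still pass for a row; with realistic row lengths the member-count prune
removes them.

## Spacing

Each stem is projected orthogonally onto the nearest ridge (ties to the
lower ridge id). Orderings use a reference point far "before" the row:
anchor − M·direction with M = 10 × the point-spread diagonal (an
orientation-safe generalization of evaluating y = kx + b at a large
negative x, which fails for vertical rows). Feet are sorted by ascending
distance to the reference; consecutive differences are the intervals.
Coincident feet produce a zero interval plus a duplicate-plant warning.
Intervals are between consecutive *detected* plants, so a missed plant
produces one interval that spans the gap — visible as overestimation in
the row-wise bias, which is exactly what the unpaired row-wise metric is
for.

## Accuracy metrics

Pairwise (controlled conditions, counts match): d_e = mean |ed_i − d_i|,
d_t = mean (ed_i − d_i), r = d_e/d with d the design spacing. Estimated
and true intervals are matched by along-row rank within each row;
unmatched trailing intervals are dropped from the pairwise form. Row-wise
(field conditions, counts differ): d_t = mean(est) − mean(truth) per row,
r = d_t/mean(truth). Library functions return r as a fraction; all
reports print percent. d_e ≥ |d_t| always; both scale linearly with the
input units.

## Scene simulator

The simulator is the package's validation instrument. It places stems on
parallel rows at the design spacing, with optional Gaussian along-row
jitter (truth intervals are the realized stem distances, not the design
value) and lateral jitter off the line. Each plant is rendered as an
opposite pair of elliptical leaf lobes plus a stem disk at a seeded
random orientation — the V2 leaf arrangement. The pixel-offset set is
point-symmetric, so the glyph's raster centroid is exactly its center,
and that center is placed at the canopy position B obtained by inverting
the correction law (OB = OA·(2H − AD)/(2(H − AD)), which makes
AB = AD·OB/(2H − AD) hold exactly). Perspective therefore enters only as
the radial centroid displacement plus nothing else: the pipeline under
test consumes centroids, and full projective rendering would add cost
without exercising any additional code path.

Soil, weed and residue appearance: texture is modelled as multiplicative
luminance noise (8 % sd) plus a small per-channel chromatic jitter (2 DN)
— EXG is invariant to brightness, so this reproduces the real-world
property that soil texture does not flicker across a vegetation
threshold, while independent per-channel noise would. Default colors give
soil EXG ≈ −0.06, plants ≈ +0.7, weeds ≈ +0.5 and residue ≈ +0.02, so
both the Otsu and fixed-threshold paths are exercised, and residue
correctly becomes a contaminant only for thresholds near 0. Weeds are
placed in the central band of the inter-row gap (0.36–0.64 of the row
width from a ridge): surviving weeds concentrate between rows after
broadcast herbicide, and in-row weeds are the acknowledged unsolved case.
Glyph centers are quantized to the pixel grid (≤ 0.5 px), which is why
exact forward/inverse closure is asserted on the stored true canopy
centroids while pixel-level recovery is asserted statistically.

What the simulator does **not** emulate: 3-D leaf geometry and
self-shadowing, illumination gradients, real soil spectra, wind blur,
growth-stage variation within a scene. Passing the simulated trials
demonstrates the correctness of the geometry, the inverse displacement
model, row logic and metrics under controlled clutter — not segmentation
robustness on arbitrary field imagery.

## Validation trials and problem sizes

Two reference trials (in `plantspace.experiments`, also run by
`scripts/acceptance.py`) use a 960×720 px sensor with a 72° diagonal AOV:

* controlled: 18/27/36 cm spacings × 2–3 m heights × 2 seeds = 12 scenes,
  10 cm plants, 1 cm spacing jitter, clean soil, Otsu threshold; scored
  pairwise against the design spacing. Typical result: mean r ≈ 1 %.
* field: 53 cm rows, 20 cm design interval with 2 cm jitter, 15 cm
  plants, 1 weed/m² between rows, 0.5 residue streaks/m², heights
  2–5 m × 3 seeds = 12 scenes, fixed EXG threshold 0.1; scored row-wise
  after weed filtering. Typical result: mean |d_t| ≈ 0.2 cm.

These sizes keep a full validation run to a few seconds per scene while
providing ≥ 10 independently seeded scenes per regime. All child seeds
derive from one base seed via `numpy` seed sequences; identical seed and
configuration reproduce byte-identical outputs.

Known failure modes, reproduced deliberately in the tests: at 9 cm
spacing and 1 m flight height adjacent canopies overlap and merge into
one object, under-counting plants and overestimating intervals; a wrong
(e.g. zero-degree) row-angle prior produces meaningless rows, flagged
only by the member-to-line residual diagnostic.

## Numerical conventions

Lengths are meters internally; the CLI accepts centimeter variants
(`height_cm`, `row_width_cm`, …) because field protocols are written in
cm. Ties (equidistant ridges, equal sort keys) break toward the lower
id. Determinism is a contract: object ids follow raster-scan order of
component top-left pixels, ridges are numbered by perpendicular offset,
and every output table carries a hash of the configuration for
provenance.
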