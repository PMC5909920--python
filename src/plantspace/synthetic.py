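"""Forward-model scene simulator.

Renders nadir RGB images of row-planted maize-like plants with full ground
truth, emulating two regimes: a clean indoor trial (plastic plants on bare
soil, exact spacings) and a field-like scene (narrower rows, spacing
jitter, weeds between rows, pale residue streaks).

Each plant is a star of elliptical leaf lobes in opposite pairs (the V2
leaf arrangement) around a stem disk.  The glyph's pixel offsets are
point-symmetric, so its raster centroid sits exactly on the glyph center —
which is placed not at the stem position A but at the canopy centroid B
displaced radially outward from nadir by AB = AD*OB/(2H - AD), the same
displacement law the localization module inverts.  Perspective enters only
through this radial centroid shift; full projective rendering is
deliberately out of scope, since the pipeline under test consumes
centroids, not silhouettes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptySceneError, InvalidInputError
from .geometry import CameraModel, GroundPoint, ground_extent, metric_to_pixel, nadir_point
from .rows import Ridge

# weeds survive herbicide mostly mid-inter-row; the band keeps them beyond
# the 1/3-row-width ridge buffer while staying between the rows
_WEED_BAND = (0.36, 0.64)


@dataclass(frozen=True)
class SceneSpec:
    """Scene recipe: planting design, plant morphology, clutter, noise.

    Lengths are meters on the ground; leaf dimensions are converted to
    pixels through the camera, so plants shrink in the image as the camera
    rises, as they do in real flights.
    """

    camera: CameraModel
    row_angle: float = math.pi / 2.0          # rows vertical in the image
    row_width: float = 0.765                  # common US maize row spacing
    interval: float = 0.18
    plant_height: float = 0.10
    leaf_length_m: float = 0.07
    leaf_width_m: float = 0.02
    leaf_count: int = 2                       # V2: one opposite pair
    weed_density: float = 0.0                 # weeds per m^2
    residue_density: float = 0.0              # streak fragments per m^2
    spacing_jitter_sd: float = 0.0            # m, along-row
    lateral_jitter_sd: float = 0.0            # m, off-row
    soil_rgb: tuple[float, float, float] = (130.0, 85.0, 55.0)
    plant_rgb: tuple[float, float, float] = (60.0, 140.0, 50.0)
    weed_rgb: tuple[float, float, float] = (70.0, 135.0, 60.0)
    residue_rgb: tuple[float, float, float] = (185.0, 172.0, 148.0)
    # texture is mostly brightness variation: multiplicative luminance noise
    # (EXG is invariant to it) plus a small independent chromatic jitter
    luminance_noise: float = 0.08             # fractional sd of brightness
    chroma_noise_sd: float = 2.0              # per-channel Gaussian sd, DN
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("row_width", "interval", "plant_height", "leaf_length_m", "leaf_width_m"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.weed_density < 0 or self.residue_density < 0:
            raise InvalidInputError("densities must be >= 0")


@dataclass(frozen=True)
class SceneTruth:
    """Everything the renderer knows: stems, canopy centroids, rows, weeds."""

    stems: tuple[GroundPoint, ...]
    canopy_centroids: tuple[GroundPoint, ...]
    rows: tuple[Ridge, ...]
    intervals_by_row: dict[int, list[float]] = field(default_factory=dict)
    weed_points: tuple[GroundPoint, ...] = ()

    @property
    def n_plants(self) -> int:
        return len(self.stems)


def forward_displace(A: GroundPoint, plant_height: float, cam: CameraModel) -> GroundPoint:
    """Canopy centroid B seen by the camera for a stem at A.

    Inverts the correction direction: with OB = OA*(2H - AD)/(2(H - AD))
    the resulting B satisfies AB = AD*OB/(2H - AD) exactly, so correcting B
    with the localization module returns A to machine precision.  Requires
    plant_height < camera height.
    """
    if plant_height >= cam.height_m:
        raise InvalidInputError("plant taller than camera height cannot be displaced")
    O = nadir_point(cam)
    dx, dy = A.x_m - O.x_m, A.y_m - O.y_m
    oa = math.hypot(dx, dy)
    if oa == 0.0 or plant_height == 0.0:
        return A
    ob = oa * (2.0 * cam.height_m - plant_height) / (2.0 * (cam.height_m - plant_height))
    return GroundPoint(O.x_m + dx / oa * ob, O.y_m + dy / oa * ob)


def _leaf_pair_offsets(
    phi: float, length_px: float, width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Point-symmetric pixel offsets of one opposite leaf pair plus stem disk."""
    a = max(length_px / 2.0, 1.0)
    b = max(width_px / 2.0, 0.8)
    reach = int(math.ceil(length_px + 1))
    grid = np.arange(-reach, reach + 1)
    dx, dy = np.meshgrid(grid, grid)
    u = math.cos(phi) * dx + math.sin(phi) * dy
    v = -math.sin(phi) * dx + math.cos(phi) * dy
    lobe = ((u - a) / a) ** 2 + (v / b) ** 2 <= 1.0
    stem = dx * dx + dy * dy <= b * b
    half = lobe | stem
    sel = half | half[::-1, ::-1]           # union with the point reflection
    return dy[sel].ravel(), dx[sel].ravel()


def _blob_offsets(rng: np.random.Generator, radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Irregular weed/residue blob: a few overlapping disks."""
    r = max(radius_px, 1.0)
    reach = int(math.ceil(2 * r)) + 1
    grid = np.arange(-reach, reach + 1)
    dx, dy = np.meshgrid(grid, grid)
    sel = np.zeros_like(dx, dtype=bool)
    for _ in range(rng.integers(2, 5)):
        cx, cy = rng.normal(0.0, r / 2.0, size=2)
        rr = r * rng.uniform(0.5, 1.0)
        sel |= (dx - cx) ** 2 + (dy - cy) ** 2 <= rr * rr
    return dy[sel].ravel(), dx[sel].ravel()


def _paint(
    img: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    color: tuple[float, float, float],
    spec: SceneSpec,
    rng: np.random.Generator,
) -> None:
    nl, ns = img.shape[:2]
    ok = (rows >= 0) & (rows < nl) & (cols >= 0) & (cols < ns)
    rows, cols = rows[ok], cols[ok]
    lum = 1.0 + rng.normal(0.0, spec.luminance_noise, size=(rows.size, 1))
    vals = np.array(color) * lum + rng.normal(0.0, spec.chroma_noise_sd, size=(rows.size, 3))
    img[rows, cols] = np.clip(vals, 0, 255)


def _row_offsets_in_scene(spec: SceneSpec, half_span: float, center_off: float) -> list[float]:
    k_max = int(math.floor((half_span - center_off) / spec.row_width))
    k_min = int(math.ceil((-half_span - center_off) / spec.row_width))
    return [center_off + k * spec.row_width for k in range(k_min, k_max + 1)]


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; returns (uint8 RGB image, ground truth).

    Stems are laid on parallel rows at the design spacing (plus optional
    along-row and lateral jitter), inset from the frame so that glyphs and
    their perspective displacement stay fully inside.  The same seed always
    reproduces the identical image and truth.
    """
    cam = spec.camera
    rng = np.random.default_rng(spec.rng_seed)
    _, l_w, l_h = ground_extent(cam)
    O = nadir_point(cam)
    gsd = cam.gsd

    # margin: half a glyph + worst-case displacement + slack
    max_disp = spec.plant_height * math.hypot(l_w, l_h) / 2.0 / (2.0 * cam.height_m - spec.plant_height)
    margin = spec.leaf_length_m + max_disp + 2.0 * gsd
    inner_x = (margin, l_w - margin)
    inner_y = (margin, l_h - margin)
    if inner_x[0] >= inner_x[1] or inner_y[0] >= inner_y[1]:
        raise EmptySceneError("camera footprint too small for the glyph margin")

    ux, uy = math.cos(spec.row_angle), math.sin(spec.row_angle)
    nx, ny = -uy, ux
    center_off = O.x_m * nx + O.y_m * ny
    # perpendicular half-span of the inner rectangle along the row normal
    half_span = (abs(nx) * (inner_x[1] - inner_x[0]) + abs(ny) * (inner_y[1] - inner_y[0])) / 2.0
    offsets = [center_off + k for k in _row_offsets_in_scene(spec, half_span, 0.0)]
    # along-row half-span of the inner rectangle, for weed placement
    along_span = (abs(ux) * (inner_x[1] - inner_x[0]) + abs(uy) * (inner_y[1] - inner_y[0])) / 2.0

    stems: list[GroundPoint] = []
    ridges: list[Ridge] = []
    intervals_by_row: dict[int, list[float]] = {}
    sorted_offsets = sorted(offsets)
    for rid, off in enumerate(sorted_offsets):
        # point on the row line closest to scene center
        base = GroundPoint(O.x_m + (off - center_off) * nx, O.y_m + (off - center_off) * ny)
        # admissible parameter range of base + t*u inside the inner rect
        t_lo, t_hi = -math.inf, math.inf
        for bc, u, lo, hi in ((base.x_m, ux, *inner_x), (base.y_m, uy, *inner_y)):
            if abs(u) < 1e-12:
                if not (lo <= bc <= hi):
                    t_lo, t_hi = 1.0, 0.0
                continue
            a, b = (lo - bc) / u, (hi - bc) / u
            t_lo, t_hi = max(t_lo, min(a, b)), min(t_hi, max(a, b))
        if t_hi - t_lo < spec.interval:
            continue
        row_pts: list[GroundPoint] = []
        t = t_lo
        while t <= t_hi:
            lat = rng.normal(0.0, spec.lateral_jitter_sd) if spec.lateral_jitter_sd else 0.0
            row_pts.append(
                GroundPoint(base.x_m + t * ux + lat * nx, base.y_m + t * uy + lat * ny)
            )
            gap = spec.interval
            if spec.spacing_jitter_sd:
                gap = max(spec.interval + rng.normal(0.0, spec.spacing_jitter_sd), 0.02)
            t += gap
        if len(row_pts) == 0:
            continue
        ridges.append(Ridge(rid, spec.row_angle % math.pi, base))
        intervals_by_row[rid] = [
            math.hypot(q.x_m - p.x_m, q.y_m - p.y_m)
            for p, q in zip(row_pts[:-1], row_pts[1:])
        ]
        stems.extend(row_pts)
    if not stems:
        raise EmptySceneError("no plant fits the scene at the requested spacing")

    canopy = tuple(forward_displace(a, spec.plant_height, cam) for a in stems)

    # ---- raster ----
    nl, ns = cam.height_px, cam.width_px
    lum = 1.0 + rng.normal(0.0, spec.luminance_noise, (nl, ns, 1))
    img = np.clip(
        np.array(spec.soil_rgb)[None, None, :] * lum
        + rng.normal(0.0, spec.chroma_noise_sd, (nl, ns, 3)),
        0,
        255,
    )

    area = l_w * l_h
    # residue streaks under everything else
    for _ in range(rng.poisson(spec.residue_density * area)):
        cx_m, cy_m = rng.uniform(0, l_w), rng.uniform(0, l_h)
        ang = rng.uniform(0, math.pi)
        length = rng.uniform(0.04, 0.15) / gsd
        width = rng.uniform(1.0, 3.0)
        tt = np.linspace(-length / 2, length / 2, max(int(length) * 2, 4))
        px, py = metric_to_pixel(GroundPoint(cx_m, cy_m), cam)
        for w_off in np.linspace(-width / 2, width / 2, max(int(width) * 2, 2)):
            rr = np.round(py + tt * math.sin(ang) + w_off * math.cos(ang)).astype(int)
            cc = np.round(px + tt * math.cos(ang) - w_off * math.sin(ang)).astype(int)
            _paint(img, rr, cc, spec.residue_rgb, spec, rng)

    # weeds in the central inter-row band
    weed_pts: list[GroundPoint] = []
    if spec.weed_density > 0 and len(sorted_offsets) >= 1:
        n_weeds = rng.poisson(spec.weed_density * area)
        for _ in range(n_weeds):
            if len(sorted_offsets) >= 2:
                gap_i = int(rng.integers(len(sorted_offsets) - 1))
                lo = sorted_offsets[gap_i]
            else:
                lo = sorted_offsets[0] - spec.row_width * (1 if rng.random() < 0.5 else 0)
            frac = rng.uniform(*_WEED_BAND)
            off = lo + frac * spec.row_width
            t = rng.uniform(-along_span, along_span)
            p = GroundPoint(
                O.x_m + (off - center_off) * nx + t * ux,
                O.y_m + (off - center_off) * ny + t * uy,
            )
            if not (inner_x[0] <= p.x_m <= inner_x[1] and inner_y[0] <= p.y_m <= inner_y[1]):
                continue
            weed_pts.append(p)
            px, py = metric_to_pixel(p, cam)
            radius_px = spec.leaf_length_m * rng.uniform(0.25, 0.5) / gsd
            dyy, dxx = _blob_offsets(rng, radius_px)
            _paint(
                img,
                np.round(py).astype(int) + dyy,
                np.round(px).astype(int) + dxx,
                spec.weed_rgb,
                spec,
                rng,
            )

    # plants last so canopy wins over clutter
    leaf_len_px = spec.leaf_length_m / gsd
    leaf_w_px = spec.leaf_width_m / gsd
    n_pairs = max(1, spec.leaf_count // 2)
    for b in canopy:
        px, py = metric_to_pixel(b, cam)
        cx, cy = int(round(px)), int(round(py))
        for _ in range(n_pairs):
            phi = rng.uniform(0.0, math.pi)
            dyy, dxx = _leaf_pair_offsets(phi, leaf_len_px, leaf_w_px)
            _paint(img, cy + dyy, cx + dxx, spec.plant_rgb, spec, rng)

    truth = SceneTruth(tuple(stems), canopy, tuple(ridges), intervals_by_row, tuple(weed_pts))
    return img.astype(np.uint8), truth


@dataclass(frozen=True)
class Scenario:
    """One cell of the spacing x height grid, named S_<x>cm_<y>m."""

    name: str
    spec: SceneSpec
    truth: SceneTruth
    image: np.ndarray


def _child_seed(base_seed: int, idx: int) -> int:
    return int(np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % (2**31))


def scenario_grid(
    intervals: list[float],
    heights: list[float],
    base_spec: SceneSpec,
) -> list[Scenario]:
    """Cartesian spacing x camera-height sweep, deterministically seeded."""
    if not intervals or not heights:
        raise InvalidInputError("intervals and heights must be non-empty")
    out = []
    idx = 0
    for s in intervals:
        for h in heights:
            cam = replace(base_spec.camera, height_m=h)
            spec = replace(
                base_spec,
                camera=cam,
                interval=s,
                rng_seed=_child_seed(base_spec.rng_seed, idx),
            )
            img, truth = render_scene(spec)
            name = f"S_{round(s * 100):g}cm_{h:g}m"
            out.append(Scenario(name, spec, truth, img))
            idx += 1
    return out
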