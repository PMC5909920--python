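import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantspace import CameraModel, GroundPoint, ground_extent, metric_distance, pixel_to_metric
from plantspace.errors import InvalidCameraError, OutOfFrameError
from plantspace.geometry import metric_to_pixel, nadir_point


class TestGroundExtent:
    def test_square_aspect_45deg_half_angle(self):
        cam = CameraModel.from_degrees(2.0, 90.0, 1000, 1000)
        l_d, l_w, l_h = ground_extent(cam)
        assert l_d == pytest.approx(4.0)
        assert l_w == pytest.approx(4.0 / math.sqrt(2))
        assert l_h == pytest.approx(4.0 / math.sqrt(2))

    def test_72deg_aov_diagonal(self):
        cam = CameraModel.from_degrees(1.0, 72.0, 960, 720)
        l_d, _, _ = ground_extent(cam)
        assert l_d == pytest.approx(2.0 * math.tan(math.radians(36.0)), rel=1e-12)
        assert l_d == pytest.approx(1.4531, abs=1e-4)

    def test_extent_vanishes_with_height(self):
        cam = CameraModel.from_degrees(1e-9, 72.0, 960, 720)
        assert ground_extent(cam)[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize(
        "height,aov,ns,nl",
        [(-1.0, 72.0, 960, 720), (2.0, 0.0, 960, 720), (2.0, 181.0, 960, 720),
         (2.0, 72.0, 0, 720), (2.0, 72.0, 960, -5)],
    )
    def test_invalid_camera_rejected(self, height, aov, ns, nl):
        with pytest.raises(InvalidCameraError):
            CameraModel.from_degrees(height, aov, ns, nl)

    def test_pythagorean_and_aspect_identities_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cam = CameraModel.from_degrees(
                rng.uniform(0.5, 50.0),
                rng.uniform(10.0, 170.0),
                int(rng.integers(100, 8000)),
                int(rng.integers(100, 8000)),
            )
            l_d, l_w, l_h = ground_extent(cam)
            assert l_d > 0
            assert l_w**2 + l_h**2 == pytest.approx(l_d**2, rel=1e-9)
            assert l_w / l_h == pytest.approx(cam.width_px / cam.height_px, rel=1e-9)

    def test_diagonal_increases_with_height(self):
        diags = [
            ground_extent(CameraModel.from_degrees(h, 72.0, 960, 720))[0]
            for h in (1, 2, 3, 4, 5)
        ]
        assert all(a < b for a, b in zip(diags, diags[1:]))


class TestPixelToMetric:
    def test_corner_mapping(self, cam2m):
        _, l_w, l_h = ground_extent(cam2m)
        assert pixel_to_metric(0, 0, cam2m).as_tuple() == (0.0, 0.0)
        far = pixel_to_metric(cam2m.width_px, cam2m.height_px, cam2m)
        assert far.x_m == pytest.approx(l_w)
        assert far.y_m == pytest.approx(l_h)

    def test_center_is_nadir(self, cam2m):
        _, l_w, l_h = ground_extent(cam2m)
        c = pixel_to_metric(cam2m.width_px / 2, cam2m.height_px / 2, cam2m)
        assert c.x_m == pytest.approx(l_w / 2)
        assert c.y_m == pytest.approx(l_h / 2)
        assert metric_distance(c, nadir_point(cam2m)) == 0.0

    def test_out_of_bounds_raises(self, cam2m):
        with pytest.raises(OutOfFrameError):
            pixel_to_metric(-1.0, 10.0, cam2m)

    def test_permissive_mode_clamps_with_warning(self, cam2m):
        with pytest.warns(UserWarning, match="clamped"):
            p = pixel_to_metric(cam2m.width_px + 50, 10.0, cam2m, permissive=True)
        assert p.x_m == pytest.approx(ground_extent(cam2m)[1])

    def test_round_trip_scales_linearly_with_height(self):
        a, b = (100.0, 200.0), (400.0, 650.0)
        dists = []
        for h in (1.0, 2.0, 4.0):
            cam = CameraModel.from_degrees(h, 72.0, 960, 720)
            dists.append(
                metric_distance(pixel_to_metric(*a, cam), pixel_to_metric(*b, cam))
            )
        assert dists[1] == pytest.approx(2 * dists[0], rel=1e-12)
        assert dists[2] == pytest.approx(4 * dists[0], rel=1e-12)

    def test_square_sensor_has_isotropic_gsd(self):
        cam = CameraModel.from_degrees(3.0, 72.0, 1200, 1200)
        _, l_w, l_h = ground_extent(cam)
        assert l_w / cam.width_px == pytest.approx(l_h / cam.height_px, rel=1e-12)

    def test_metric_to_pixel_inverts(self, cam2m):
        p = pixel_to_metric(123.4, 567.8, cam2m)
        x, y = metric_to_pixel(p, cam2m)
        assert (x, y) == (pytest.approx(123.4), pytest.approx(567.8))


class TestMetricDistance:
    def test_pythagorean_triple(self):
        assert metric_distance(GroundPoint(0, 0), GroundPoint(3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        p, q = GroundPoint(1.2, 3.4), GroundPoint(5.6, 7.8)
        assert metric_distance(p, p) == 0.0
        assert metric_distance(p, q) == metric_distance(q, p)

    def test_nine_cm_interval(self):
        assert metric_distance(GroundPoint(0, 0), GroundPoint(0.09, 0)) == pytest.approx(0.09)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality(self, pts):
        a, b, c = (GroundPoint(*t) for t in pts)
        assert metric_distance(a, c) <= metric_distance(a, b) + metric_distance(b, c) + 1e-9
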