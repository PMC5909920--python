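import numpy as np
import pytest

from plantspace.errors import DegenerateHistogramError, InvalidInputError
from plantspace.segmentation import (
    PlantObject,
    compute_exg,
    extract_objects,
    filter_objects,
    merge_fragments,
    objects_table,
    segment_image,
    threshold_vegetation,
)


def _img(pixels):
    return np.asarray(pixels, dtype=np.float64)


class TestComputeExg:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((0, 255, 0), 2.0), ((100, 100, 100), 0.0), ((255, 0, 0), -1.0), ((0, 0, 255), -1.0)],
    )
    def test_extreme_pixels(self, rgb, expected):
        img = _img([[rgb]])
        assert compute_exg(img, normalization="bit_depth")[0, 0] == pytest.approx(expected)

    def test_gray_pixel_with_equal_band_maxima(self):
        img = _img([[(100, 100, 100), (255, 255, 255)]])
        assert compute_exg(img)[0, 0] == pytest.approx(0.0)

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (20, 20, 3))
        exg = compute_exg(img)
        assert exg.min() >= -1.0 - 1e-12 and exg.max() <= 2.0 + 1e-12

    def test_zero_sum_pixel_is_background(self):
        img = _img([[(0, 0, 0), (10, 200, 10)]])
        assert compute_exg(img)[0, 0] == 0.0

    def test_uniform_brightness_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 120, (10, 10, 3))
        np.testing.assert_allclose(
            compute_exg(img), compute_exg(2.0 * img), atol=1e-12
        )

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_exg(np.zeros((5, 5)))


class TestThreshold:
    def test_otsu_separates_two_levels(self):
        exg = np.full((10, 10), -0.5)
        exg[:2] = 1.5
        mask = threshold_vegetation(exg, "otsu")
        assert mask.sum() == 20 and mask[:2].all()

    def test_fixed_zero_threshold(self):
        exg = np.array([[-0.1, 0.0, 0.3]])
        np.testing.assert_array_equal(
            threshold_vegetation(exg, "fixed", 0.0), [[False, False, True]]
        )

    def test_all_soil_empty_mask(self):
        exg = np.full((5, 5), -0.2)
        assert threshold_vegetation(exg, "fixed", 0.1).sum() == 0

    def test_otsu_on_constant_image_fails(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_vegetation(np.zeros((5, 5)), "otsu")

    def test_fixed_requires_value(self):
        with pytest.raises(InvalidInputError):
            threshold_vegetation(np.zeros((5, 5)), "fixed")


class TestExtractObjects:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        objs = extract_objects(mask)
        assert [o.area for o in objs] == [9, 9]
        assert objs[0].object_id == 0 and objs[1].object_id == 1

    def test_single_pixel_centroid_convention(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        (obj,) = extract_objects(mask)
        assert obj.area == 1
        assert obj.centroid_px == (5.5, 5.5)
        assert obj.perimeter > 0

    def test_diagonal_pair_is_one_component(self):
        mask = np.zeros((10, 10), bool)
        mask[3, 3] = mask[4, 4] = True
        assert len(extract_objects(mask)) == 1

    def test_empty_mask(self):
        assert extract_objects(np.zeros((5, 5), bool)) == []

    def test_border_component_flagged_truncated(self):
        mask = np.zeros((10, 10), bool)
        mask[0, 4:7] = True
        mask[5, 4:7] = True
        objs = extract_objects(mask)
        assert objs[0].truncated and not objs[1].truncated


def _fake_object(oid, area, shape_ratio):
    rows = np.zeros(area, dtype=int)
    cols = np.arange(area)
    return PlantObject(oid, rows, cols, area, shape_ratio * area, (0.0, 0.0))


class TestFilterObjects:
    def test_small_outlier_removed(self):
        objs = [_fake_object(i, a, 0.5) for i, a in enumerate([100, 100, 100, 4])]
        kept = filter_objects(objs, t_area=0.3, t_shape=0.3)
        # mean area 76, cutoff 22.8: only the area-4 object falls
        assert [o.area for o in kept] == [100, 100, 100]

    def test_single_object_survives(self):
        objs = [_fake_object(0, 50, 0.5)]
        assert filter_objects(objs) == objs

    def test_empty_input(self):
        assert filter_objects([]) == []

    def test_output_is_subset(self):
        rng = np.random.default_rng(3)
        objs = [
            _fake_object(i, int(rng.integers(1, 200)), rng.uniform(0.1, 2.0))
            for i in range(30)
        ]
        kept = filter_objects(objs)
        assert set(id(o) for o in kept) <= set(id(o) for o in objs)

    def test_shape_keep_below_inverts_direction(self):
        ragged = _fake_object(0, 100, 10.0)
        compact = _fake_object(1, 100, 0.2)
        filler = [_fake_object(i, 100, 1.0) for i in range(2, 6)]
        above = filter_objects([ragged, compact] + filler, shape_keep="above")
        below = filter_objects([ragged, compact] + filler, shape_keep="below")
        assert ragged in above and compact not in above
        assert compact in below and ragged not in below


class TestMergeFragments:
    def _two_fragments(self, gap):
        mask = np.zeros((30, 60), bool)
        mask[10:15, 10:15] = True
        mask[10:15, 15 + gap : 20 + gap] = True
        return extract_objects(mask), mask.shape

    def test_nearby_fragments_merge(self):
        objs, shape = self._two_fragments(gap=2)
        merged = merge_fragments(objs, 2, shape)
        assert len(merged) == 1
        assert merged[0].area == 50

    def test_distant_fragments_untouched(self):
        objs, shape = self._two_fragments(gap=20)
        merged = merge_fragments(objs, 2, shape)
        assert len(merged) == 2

    def test_pixel_count_conserved_and_area_monotone(self):
        rng = np.random.default_rng(5)
        mask = rng.random((50, 50)) > 0.8
        objs = extract_objects(mask)
        merged = merge_fragments(objs, 3, mask.shape)
        assert sum(o.area for o in merged) == sum(o.area for o in objs)
        assert min(o.area for o in merged) >= min(o.area for o in objs)

    def test_zero_radius_is_identity(self):
        objs, shape = self._two_fragments(gap=2)
        assert merge_fragments(objs, 0, shape) == objs


def test_pipeline_determinism_byte_identical_table(clean_scene):
    _, img, _ = clean_scene
    t1 = objects_table(segment_image(img)).to_csv(index=False)
    t2 = objects_table(segment_image(img)).to_csv(index=False)
    assert t1 == t2
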