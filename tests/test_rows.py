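import math

import numpy as np
import pytest

from plantspace import GroundPoint, detect_ridges, filter_weeds_by_ridge
from plantspace.errors import InvalidInputError
from plantspace.localization import CorrectedPlant
from plantspace.rows import Ridge, prune_minor_ridges

VERT = math.pi / 2.0


def _plant(oid, x, y):
    p = GroundPoint(x, y)
    return CorrectedPlant(oid, p, p, 0.0, 0.0)


def _two_row_layout(w=0.765, n_per_row=6, jitter=0.0, rng=None):
    plants = []
    oid = 0
    for row_x in (1.0, 1.0 + w):
        for k in range(n_per_row):
            dx = rng.uniform(-jitter, jitter) if jitter else 0.0
            plants.append(_plant(oid, row_x + dx, 0.3 + 0.18 * k))
            oid += 1
    return plants


class TestDetectRidges:
    def test_two_exact_rows_recovered(self):
        plants = _two_row_layout()
        ridges = detect_ridges(plants, VERT, 0.765)
        assert len(ridges) == 2
        assert sorted(len(r.member_ids) for r in ridges) == [6, 6]
        # each ridge passes through its members' mean position
        for r in ridges:
            xs = [p.A.x_m for p in plants if p.object_id in r.member_ids]
            assert r.perpendicular_distance(
                GroundPoint(np.mean(xs), 0.0)
            ) == pytest.approx(0.0, abs=1e-12)

    def test_single_plant_single_ridge(self):
        (ridge,) = detect_ridges([_plant(0, 0.4, 0.7)], VERT, 0.765)
        assert ridge.perpendicular_distance(GroundPoint(0.4, 0.7)) == pytest.approx(0.0)

    def test_jittered_rows_offsets_match_least_squares(self):
        rng = np.random.default_rng(9)
        w = 0.765
        plants = _two_row_layout(w=w, jitter=w / 10, rng=rng)
        ridges = detect_ridges(plants, VERT, w)
        assert len(ridges) == 2
        for r in ridges:
            xs = [p.A.x_m for p in plants if p.object_id in r.member_ids]
            # vertical-line least squares: offset = -mean(x)
            assert abs(abs(r.offset) - np.mean(xs)) < w / 10

    def test_stable_under_random_seeding(self):
        plants = _two_row_layout()
        base = sorted(r.offset for r in detect_ridges(plants, VERT, 0.765))
        for seed in range(20):
            rng = np.random.default_rng(seed)
            off = sorted(
                r.offset
                for r in detect_ridges(plants, VERT, 0.765, seed_mode="random", rng=rng)
            )
            assert len(off) == 2
            assert np.allclose(off, base, atol=0.765 / 3)

    def test_bad_parameters_rejected(self):
        p = [_plant(0, 0.1, 0.1)]
        with pytest.raises(InvalidInputError):
            detect_ridges(p, VERT, -1.0)
        with pytest.raises(InvalidInputError):
            detect_ridges(p, VERT, 0.765, buffer_frac=0.7)

    def test_empty_input(self):
        assert detect_ridges([], VERT, 0.765) == []

    def test_vertical_row_has_no_slope_intercept(self):
        (r,) = detect_ridges([_plant(0, 0.4, 0.7)], VERT, 0.765)
        assert r.is_vertical and r.slope_intercept is None
        (r45,) = detect_ridges([_plant(0, 0.4, 0.7)], math.pi / 4, 0.765)
        k, b = r45.slope_intercept
        assert k == pytest.approx(1.0)
        assert 0.7 == pytest.approx(k * 0.4 + b)


class TestWeedFilter:
    def test_partition_property(self):
        plants = _two_row_layout() + [_plant(99, 1.38, 0.9)]
        ridges = detect_ridges(plants[:-1], VERT, 0.765)
        kept, removed = filter_weeds_by_ridge(plants, ridges, 0.765 / 3)
        assert len(kept) + len(removed) == len(plants)
        assert not (set(id(p) for p in kept) & set(id(p) for p in removed))

    def test_on_ridge_kept_far_away_removed(self):
        ridges = [Ridge(0, VERT, GroundPoint(1.0, 0.0))]
        on = _plant(0, 1.0, 0.5)
        far = _plant(1, 1.0 + 3 * 0.1, 0.5)
        kept, removed = filter_weeds_by_ridge([on, far], ridges, 0.1)
        assert kept == [on] and removed == [far]

    def test_no_ridges_removes_everything_with_warning(self):
        with pytest.warns(UserWarning, match="no ridges"):
            kept, removed = filter_weeds_by_ridge([_plant(0, 1, 1)], [], 0.1)
        assert kept == [] and len(removed) == 1

    def test_midrow_weeds_all_removed_inrow_all_kept(self):
        # rows long enough that a stray weed pair cannot pass for a row
        plants = _two_row_layout(n_per_row=9)
        weeds = [_plant(100 + i, 1.0 + 0.765 / 2, 0.3 + 0.5 * i) for i in range(2)]
        ridges = detect_ridges(plants + weeds, VERT, 0.765)
        ridges = prune_minor_ridges(ridges)
        kept, removed = filter_weeds_by_ridge(plants + weeds, ridges, 0.765 / 3)
        assert {p.object_id for p in removed} == {100, 101}
        assert len(kept) == len(plants)


class TestPruneMinorRidges:
    def test_sparse_weed_ridge_dissolved(self):
        dense = Ridge(0, VERT, GroundPoint(1.0, 0.0), tuple(range(10)))
        sparse = Ridge(1, VERT, GroundPoint(1.38, 0.0), (99,))
        kept = prune_minor_ridges([dense, sparse])
        assert len(kept) == 1 and kept[0].member_ids == dense.member_ids

    def test_tiny_scenes_untouched(self):
        r1 = Ridge(0, VERT, GroundPoint(1.0, 0.0), (0,))
        r2 = Ridge(1, VERT, GroundPoint(1.8, 0.0), (1, 2))
        assert len(prune_minor_ridges([r1, r2])) == 2
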