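"""Puncta detection, axis mapping, colocalization and intensity readouts."""

import numpy as np
import pytest

from acdkit.puncta import (
    ColocParams,
    PunctaSet,
    Punctum,
    coloc_count,
    detect_puncta,
    iqr_filter,
    linear_density,
    map_to_axis,
    roi_intensity,
)
from acdkit.synthetic import make_puncta_field

from oracles import oracle_max_coloc_matching, oracle_nearest_on_polyline


def point_set(coords, channel="x"):
    return PunctaSet(
        [Punctum(centroid_px=(float(x), float(y)), area_um2=0.1, channel=channel)
         for x, y in coords],
        channel=channel,
    )


class TestDetectPuncta:
    def test_blank_image_yields_nothing(self):
        assert len(detect_puncta(np.zeros((50, 50)), threshold=0.5)) == 0

    def test_two_disjoint_squares_counted_with_exact_area(self):
        img = np.zeros((40, 40))
        img[5:8, 5:8] = 1.0
        img[20:23, 30:33] = 1.0
        ps = detect_puncta(img, threshold=0.5, pixel_size_um=0.065)
        assert len(ps) == 2
        np.testing.assert_allclose(ps.areas_um2, 9 * 0.065**2)

    def test_count_invariant_over_threshold_between_levels(self):
        img = np.zeros((60, 60))
        img[10:14, 10:14] = 1.0
        img[30:34, 40:44] = 1.0
        img[50:54, 20:24] = 1.0
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            assert len(detect_puncta(img, threshold=thr)) == 3

    def test_centroid_inside_roi_rule(self):
        img = np.zeros((30, 60))
        img[10:16, 18:24] = 1.0  # centroid x = 20.5
        roi_covering = np.array([[0, 0], [25, 0], [25, 29], [0, 29]], dtype=float)
        roi_cutting = np.array([[0, 0], [19, 0], [19, 29], [0, 29]], dtype=float)
        assert len(detect_puncta(img, roi=roi_covering, threshold=0.5)) == 1
        assert len(detect_puncta(img, roi=roi_cutting, threshold=0.5)) == 0

    def test_empty_roi_rejected(self):
        img = np.ones((20, 20))
        roi = np.array([[100, 100], [101, 100], [101, 101]], dtype=float)
        with pytest.raises(ValueError, match="ROI"):
            detect_puncta(img, roi=roi, threshold=0.5)

    def test_min_area_suppresses_single_pixels(self):
        img = np.zeros((20, 20))
        img[3, 3] = 1.0
        img[10:13, 10:13] = 1.0
        assert len(detect_puncta(img, threshold=0.5, min_area_px=4)) == 1


class TestLinearDensity:
    @pytest.mark.parametrize(
        "count,length,expected", [(10, 20.0, 2.5), (0, 30.0, 0.0), (7, 35.0, 1.0)]
    )
    def test_per_five_micron_arithmetic(self, count, length, expected):
        assert linear_density(count, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            linear_density(3, 0.0)

    def test_scaling_identity(self, rng):
        c = int(rng.integers(1, 50))
        L = float(rng.uniform(5, 60))
        assert linear_density(2 * c, L) == pytest.approx(2 * linear_density(c, L))
        assert linear_density(c, 2 * L) == pytest.approx(linear_density(c, L) / 2)


class TestMapToAxis:
    def test_centroid_on_line_start_maps_to_zero(self):
        line = np.array([[5.0, 5.0], [50.0, 5.0]])
        ps = point_set([(5.0, 5.0)])
        (m,) = map_to_axis(ps, line, pixel_size_um=0.1)
        assert m.arc_position_um == 0.0 and m.mapped

    def test_perpendicular_foot_of_straight_line_midpoint(self):
        line = np.array([[0.0, 0.0], [300.0, 0.0]])  # 30 µm at 0.1 µm/px
        ps = point_set([(150.0, 4.0)])
        (m,) = map_to_axis(ps, line, pixel_size_um=0.1)
        assert m.arc_position_um == pytest.approx(15.0)

    def test_far_centroid_flagged_unmapped(self):
        line = np.array([[0.0, 0.0], [100.0, 0.0]])
        ps = point_set([(50.0, 25.0)])
        (m,) = map_to_axis(ps, line, max_lateral_px=10.0)
        assert not m.mapped

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            map_to_axis(point_set([(0, 0)]), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_dense_sampling_oracle_on_random_polylines(self, rng):
        from shapely.geometry import LineString

        for _ in range(200):
            n_v = int(rng.integers(2, 6))
            line = rng.uniform(0, 100, size=(n_v, 2)).cumsum(axis=0) / np.arange(
                1, n_v + 1
            )[:, None]
            pt = rng.uniform(-20, 120, size=2)
            ps = point_set([tuple(pt)])
            (m,) = map_to_axis(ps, line, pixel_size_um=1.0, max_lateral_px=np.inf)
            arc_oracle, dist_oracle = oracle_nearest_on_polyline(pt, line)
            step = np.hypot(*np.diff(line, axis=0).T).sum() / 20000
            # the projection must achieve the oracle's optimal distance ...
            assert m.lateral_offset_px == pytest.approx(dist_oracle, abs=step)
            # ... and the arc position must name a point realizing it
            # (tie-robust: equidistant branches are both valid answers)
            at_arc = LineString(line).interpolate(m.arc_position_um)
            realized = np.hypot(at_arc.x - pt[0], at_arc.y - pt[1])
            assert realized == pytest.approx(dist_oracle, abs=step)


class TestColoc:
    def test_identical_points_pair_at_zero_distance(self):
        a = point_set([(10.0, 10.0)])
        pairs, count, dist = coloc_count(a, point_set([(10.0, 10.0)], "b"))
        assert count == 1 and dist[0] == 0.0

    def test_box_boundary_inclusive_per_axis(self):
        a = point_set([(0.0, 0.0)])
        at_corner = point_set([(8.0, 8.0)], "b")
        outside = point_set([(9.0, 0.0)], "b")
        assert coloc_count(a, at_corner)[1] == 1
        assert coloc_count(a, outside)[1] == 0

    def test_empty_sets_give_zero(self):
        assert coloc_count(point_set([]), point_set([]))[1] == 0

    def test_planted_pairs_recovered_and_match_max_matching_oracle(self):
        for seed in range(50):
            n_pairs = seed % 7
            a, b, planted, _ = make_puncta_field(
                n_a=12 + seed % 5, n_b=10 + seed % 4, n_pairs=n_pairs, seed=seed
            )
            pairs, count, _ = coloc_count(a, b)
            assert count == n_pairs
            oracle = oracle_max_coloc_matching(a.centroids, b.centroids, 8.0)
            assert count == oracle

    def test_symmetric_in_channel_order(self):
        a, b, _, _ = make_puncta_field(15, 12, 4, seed=3)
        assert coloc_count(a, b)[1] == coloc_count(b, a)[1]

    def test_invariant_under_joint_integer_translation(self):
        a, b, _, _ = make_puncta_field(15, 12, 4, seed=9)
        shift = np.array([17.0, -23.0])
        a2 = point_set([tuple(c + shift) for c in a.centroids])
        b2 = point_set([tuple(c + shift) for c in b.centroids], "b")
        assert coloc_count(a, b)[1] == coloc_count(a2, b2)[1]

    def test_zero_planted_pairs_counted_as_zero(self):
        a, b, _, _ = make_puncta_field(10, 10, 0, seed=1)
        assert coloc_count(a, b)[1] == 0


class TestRoiIntensity:
    def test_explicit_background_ratio(self):
        img = np.full((40, 40), 50.0)
        img[5:15, 5:15] = 200.0
        roi = np.array([[5, 5], [14, 5], [14, 14], [5, 14]], dtype=float)
        bg = np.array([[25, 25], [35, 25], [35, 35], [25, 35]], dtype=float)
        assert roi_intensity(img, roi, bg) == pytest.approx(4.0)

    def test_roi_equal_to_background_gives_unity(self):
        img = np.full((30, 30), 80.0)
        roi = np.array([[2, 2], [10, 2], [10, 10], [2, 10]], dtype=float)
        bg = np.array([[15, 15], [25, 15], [25, 25], [15, 25]], dtype=float)
        assert roi_intensity(img, roi, bg) == pytest.approx(1.0)

    def test_auto_background_recovers_planted_ratio(self, rng):
        img = 40.0 + rng.normal(0, 2.0, size=(80, 80))
        img[10:30, 10:30] = 100.0 + rng.normal(0, 2.0, size=(20, 20))
        roi = np.array([[10, 10], [29, 10], [29, 29], [10, 29]], dtype=float)
        assert roi_intensity(img, roi, "auto") == pytest.approx(100 / 40, rel=0.12)

    def test_overlapping_background_rejected(self):
        img = np.ones((20, 20))
        roi = np.array([[2, 2], [10, 2], [10, 10], [2, 10]], dtype=float)
        with pytest.raises(ValueError, match="disjoint"):
            roi_intensity(img, roi, roi)

    def test_zero_background_rejected(self):
        img = np.zeros((20, 20))
        img[2:6, 2:6] = 5.0
        roi = np.array([[2, 2], [5, 2], [5, 5], [2, 5]], dtype=float)
        bg = np.array([[10, 10], [18, 10], [18, 18], [10, 18]], dtype=float)
        with pytest.raises(ValueError, match="zero"):
            roi_intensity(img, roi, bg)


class TestIqrFilter:
    def test_single_extreme_outlier_removed(self):
        kept, removed = iqr_filter([1, 2, 3, 4, 100])
        np.testing.assert_array_equal(kept, [1, 2, 3, 4])
        np.testing.assert_array_equal(removed, [100])

    def test_all_equal_nothing_removed(self):
        kept, removed = iqr_filter([5.0] * 8)
        assert len(kept) == 8 and len(removed) == 0

    def test_symmetric_spread_is_identity(self):
        vals = np.array([10, 11, 12, 13, 14, 15], dtype=float)
        kept, removed = iqr_filter(vals)
        np.testing.assert_array_equal(kept, vals)

    def test_short_input_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, removed = iqr_filter([1.0, 2.0, 900.0])
        assert len(kept) == 3 and len(removed) == 0
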