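import numpy as np
import pytest

from oracles import (
    brute_force_lambda_merge,
    canonical_partition,
    direct_cost,
    random_rect_partition,
    rescan_stats,
)
from tmdkit.cube_io import HyperCube
from tmdkit.segmentation import (
    SegmentMap,
    TMDSegmenter,
    edge_segment,
    lambda_merge,
    mean_intensity,
    merge_cost,
    segment_stats,
)


def _cube(data):
    data = np.asarray(data, dtype=float)
    wl = np.linspace(400, 800, data.shape[2])
    return HyperCube(data=data, wavelengths=wl, units="reflectance")


class TestMeanIntensity:
    def test_constant_cube(self):
        img = mean_intensity(_cube(np.full((4, 4, 3), 0.4)))
        np.testing.assert_allclose(img, 0.4)

    def test_per_pixel_mean(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.2, 0.4, 0.6]
        assert mean_intensity(_cube(data))[0, 0] == pytest.approx(0.4)

    def test_single_band_identity(self, rng):
        data = rng.uniform(0, 1, (5, 5, 1))
        np.testing.assert_allclose(mean_intensity(_cube(data)), data[..., 0])

    def test_invalid_pixels_propagate_as_nan(self):
        cube = _cube(np.full((3, 3, 2), 0.5))
        cube.valid = np.ones((3, 3), dtype=bool)
        cube.valid[0, 0] = False
        assert np.isnan(mean_intensity(cube)[0, 0])


class TestEdgeSegment:
    @pytest.mark.parametrize("scale_level", [0, 30, 75, 99])
    def test_two_half_planes(self, scale_level):
        img = np.full((10, 10), 0.2)
        img[:, 5:] = 0.8
        seg = edge_segment(img, scale_level)
        assert seg.n_segments == 2
        # the two plateaus end in different segments
        assert seg.labels[0, 0] != seg.labels[0, 9]

    def test_constant_image_single_segment(self):
        seg = edge_segment(np.full((8, 8), 0.3), 30)
        assert seg.n_segments == 1

    def test_three_plateau_staircase_matches_components(self):
        img = np.zeros((9, 12))
        img[:, 4:8] = 0.5
        img[:, 8:] = 1.0
        seg = edge_segment(img, 0)
        assert seg.n_segments == 3
        # each plateau interior is uniformly labeled
        for sl in (slice(0, 3), slice(5, 7), slice(9, 12)):
            assert len(np.unique(seg.labels[:, sl])) == 1

    def test_higher_scale_level_never_more_segments(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        counts = [edge_segment(img, s).n_segments for s in (0, 30, 60, 90)]
        assert counts == sorted(counts, reverse=True)

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            edge_segment(np.full((4, 4), np.nan), 30)


class TestSegmentStats:
    def test_single_segment_global_mean(self, rng):
        data = rng.uniform(0, 1, (4, 5, 3))
        seg = SegmentMap(np.zeros((4, 5), dtype=int), 1)
        stats = segment_stats(seg, _cube(data))
        assert stats.areas[0] == 20
        np.testing.assert_allclose(stats.mean_spectra[0],
                                   data.reshape(-1, 3).mean(axis=0))

    def test_shared_border_count(self):
        labels = np.zeros((2, 4), dtype=int)
        labels[:, 2:] = 1
        stats = segment_stats(SegmentMap(labels, 2), _cube(np.zeros((2, 4, 2))))
        assert stats.boundary_length(0, 1) == 2
        assert stats.boundary_length(1, 0) == 2  # symmetric

    def test_checkerboard_two_by_two(self):
        labels = np.array([[0, 1], [1, 0]])
        stats = segment_stats(SegmentMap(labels, 2), _cube(np.zeros((2, 2, 1))))
        assert stats.boundary_length(0, 1) == 4

    def test_areas_sum_to_valid_pixels(self, rng):
        labels = random_rect_partition(rng)
        stats = segment_stats(SegmentMap(labels, labels.max() + 1),
                              _cube(rng.uniform(0, 1, (8, 8, 3))))
        assert stats.areas.sum() == 64

    def test_matches_rescan_oracle(self, rng):
        labels = random_rect_partition(rng)
        data = rng.uniform(0, 1, (8, 8, 3))
        stats = segment_stats(SegmentMap(labels, labels.max() + 1), _cube(data))
        areas, means, boundary = rescan_stats(labels, data)
        for i in areas:
            assert stats.areas[i] == areas[i]
            np.testing.assert_allclose(stats.mean_spectra[i], means[i])
        assert dict(stats.boundary_lengths) == boundary


class TestMergeCost:
    def test_equal_spectra_zero_cost(self):
        labels = np.zeros((2, 4), dtype=int)
        labels[:, 2:] = 1
        stats = segment_stats(SegmentMap(labels, 2), _cube(np.full((2, 4, 3), 0.5)))
        assert merge_cost(stats, 0, 1) == 0.0

    def test_hand_computed_value(self):
        # |Si|=|Sj|=2, squared spectral distance 4, boundary length 2
        labels = np.array([[0, 1], [0, 1]])
        data = np.zeros((2, 2, 1))
        data[:, 1, 0] = 2.0
        stats = segment_stats(SegmentMap(labels, 2), _cube(data))
        assert merge_cost(stats, 0, 1) == pytest.approx((2 * 2 / 4 * 4) / 2)

    def test_doubling_areas_doubles_cost(self):
        def cost_for(height):
            labels = np.zeros((height, 2), dtype=int)
            labels[:, 1] = 1
            data = np.zeros((height, 2, 1))
            data[:, 1, 0] = 1.0
            stats = segment_stats(SegmentMap(labels, 2), _cube(data))
            # normalise away the boundary-length change
            return merge_cost(stats, 0, 1) * stats.boundary_length(0, 1)

        assert cost_for(4) == pytest.approx(2 * cost_for(2))

    def test_symmetry(self, rng):
        labels = random_rect_partition(rng)
        data = rng.uniform(0, 1, (8, 8, 3))
        stats = segment_stats(SegmentMap(labels, labels.max() + 1), _cube(data))
        for (i, j) in stats.boundary_lengths:
            assert merge_cost(stats, i, j) == merge_cost(stats, j, i)

    def test_non_adjacent_rejected(self):
        labels = np.array([[0, 1, 2]])
        stats = segment_stats(SegmentMap(labels, 3), _cube(np.zeros((1, 3, 1))))
        with pytest.raises(ValueError, match="not adjacent"):
            merge_cost(stats, 0, 2)


class TestLambdaMerge:
    def test_zero_merge_level_is_identity(self, rng):
        labels = random_rect_partition(rng)
        cube = _cube(rng.uniform(0, 1, (8, 8, 3)))
        seg = SegmentMap(labels, labels.max() + 1)
        out, schedule = lambda_merge(seg, cube, merge_level=0)
        assert out.n_segments == seg.n_segments
        assert schedule.events == []

    def test_level_100_merges_everything(self, rng):
        labels = random_rect_partition(rng)
        cube = _cube(rng.uniform(0, 1, (8, 8, 3)))
        out, _ = lambda_merge(SegmentMap(labels, labels.max() + 1), cube, 100)
        assert out.n_segments == 1

    def test_four_block_toy_merges_within_pairs_only(self):
        # 2x2 blocks with means 0, 0.1 | 0.9, 1.0: a low threshold merges
        # the near pairs but never across the big contrast
        data = np.zeros((4, 4, 1))
        data[:2, 2:] = 0.1
        data[2:, :2] = 0.9
        data[2:, 2:] = 1.0
        labels = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                           [2, 2, 3, 3], [2, 2, 3, 3]])
        cube = _cube(data)
        seg = SegmentMap(labels, 4)
        # brute-force oracle fixes the expected partition
        expected = brute_force_lambda_merge(labels, data, threshold=0.05)
        out, schedule = lambda_merge(seg, cube, threshold_absolute=0.05)
        assert out.n_segments == 2
        np.testing.assert_array_equal(canonical_partition(out.labels),
                                      canonical_partition(expected))
        assert {frozenset((a, b)) for a, b, _ in schedule.events} == {
            frozenset((0, 1)), frozenset((2, 3))}

    def test_recorded_costs_below_threshold(self, rng):
        labels = random_rect_partition(rng)
        cube = _cube(rng.uniform(0, 1, (8, 8, 3)))
        out, schedule = lambda_merge(SegmentMap(labels, labels.max() + 1),
                                     cube, 75)
        for _, _, cost in schedule.events:
            assert cost < schedule.threshold

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = random_rect_partition(rng)
        data = rng.uniform(0, 1, (8, 8, 3))
        costs = []
        areas, means, boundary = rescan_stats(labels, data)
        for (i, j) in boundary:
            costs.append(direct_cost(areas, means, boundary, i, j))
        threshold = float(rng.uniform(0, 2 * max(costs))) if costs else 0.0
        expected = brute_force_lambda_merge(labels, data, threshold)
        out, _ = lambda_merge(SegmentMap(labels, labels.max() + 1),
                              _cube(data), threshold_absolute=threshold)
        np.testing.assert_array_equal(canonical_partition(out.labels),
                                      canonical_partition(expected))

    def test_mean_spectrum_conservation(self, rng):
        labels = random_rect_partition(rng)
        data = rng.uniform(0, 1, (8, 8, 3))
        cube = _cube(data)
        out, _ = lambda_merge(SegmentMap(labels, labels.max() + 1), cube, 100)
        stats = segment_stats(out, cube)
        np.testing.assert_allclose(stats.mean_spectra[0],
                                   data.reshape(-1, 3).mean(axis=0))

    def test_partition_conserves_pixels(self, rng):
        labels = random_rect_partition(rng)
        cube = _cube(rng.uniform(0, 1, (8, 8, 3)))
        for ml in (0, 25, 50, 75, 100):
            out, _ = lambda_merge(SegmentMap(labels, labels.max() + 1),
                                  cube, ml)
            assert (out.labels >= 0).all()
            stats = segment_stats(out, cube)
            assert stats.areas.sum() == 64

    def test_monotone_in_merge_level(self, rng):
        labels = random_rect_partition(rng, shape=(12, 12), max_segments=6)
        cube = _cube(rng.uniform(0, 1, (12, 12, 3)))
        counts = [
            lambda_merge(SegmentMap(labels, labels.max() + 1), cube, ml)[0]
            .n_segments
            for ml in (0, 25, 50, 75, 100)
        ]
        assert counts == sorted(counts, reverse=True)


class TestTMDSegmenter:
    def test_noiseless_phantom_segments_respect_truth(self, noiseless_phantom):
        """At SL 30 / ML 75 no segment straddles the true tumor boundary."""
        from tmdkit.calibration import calibrate

        cal = calibrate(noiseless_phantom.raw, noiseless_phantom.refs)
        est = TMDSegmenter().fit(cal)
        for s in range(est.n_segments_):
            classes = np.unique(noiseless_phantom.truth[est.labels_ == s])
            assert len(classes) == 1

    def test_sklearn_param_interface(self):
        est = TMDSegmenter(scale_level=10)
        assert est.get_params()["scale_level"] == 10
        est.set_params(merge_level=50)
        assert est.merge_level == 50
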