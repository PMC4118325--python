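"""Six-parameter stem identification pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemsense import (
    PointCloud,
    PresenceSeries,
    StemDetectionParams,
    apply_blanking,
    apply_height_cut,
    binarize_presence,
    build_tree_path,
    detect_stems,
    detect_stems_detailed,
    estimate_tree_line,
    extract_candidates,
    fill_jumps,
    match_to_truth,
)
from stemsense.errors import NoTreeLineError, OrderingError
from stemsense.lidar_detect import CandidateRun, TreeLine


def cloud_at(xs, depth=500.0, z=180.0):
    xs = np.asarray(xs, dtype=float)
    return PointCloud(xs, np.full(xs.size, depth), np.full(xs.size, z))


class TestHeightCut:
    def test_boundary_inclusive(self):
        cloud = PointCloud([0, 1], [500, 500], [210.0, 215.0])
        cut = apply_height_cut(cloud, 210.0)
        assert len(cut) == 1 and cut.z[0] == 210.0

    def test_empty_cloud(self):
        assert len(apply_height_cut(PointCloud([], [], []), 210.0)) == 0


class TestTreeLine:
    def test_constant_depth_gives_constant_line(self):
        line = estimate_tree_line(cloud_at(np.arange(0, 200), 500.0), encoder_range=100)
        assert np.allclose(line.node_depths_mm, 500.0)
        assert line.smoothed

    def test_mode_wins_over_minority_cluster(self):
        # 60 points at 500 mm vs 10 points at 300 mm in every window
        pairs = sorted(
            [(float(x), 500.0) for x in range(60)]
            + [(float(x * 6), 300.0) for x in range(10)]
        )
        cloud = PointCloud(
            [x for x, _ in pairs], [d for _, d in pairs], np.zeros(len(pairs))
        )
        line = estimate_tree_line(cloud, encoder_range=200)
        assert np.allclose(line.node_depths_mm, 500.0)

    def test_modal_tie_resolves_to_smaller_depth(self):
        # equal histogram mass in the 490 and 510 bins -> near bin wins
        xs = np.repeat(np.arange(0.0, 50.0), 2)
        depths = np.tile([490.0, 510.0], 50)
        line = estimate_tree_line(PointCloud(xs, depths, np.zeros(100)), encoder_range=100)
        assert np.allclose(line.node_depths_mm, 490.0)

    def test_empty_windows_interpolated(self):
        cloud = cloud_at(list(range(0, 20)) + list(range(180, 200)))
        line = estimate_tree_line(cloud, encoder_range=20, node_step=10)
        assert np.allclose(line.node_depths_mm, 500.0)

    def test_empty_cloud_raises(self):
        with pytest.raises(NoTreeLineError):
            estimate_tree_line(PointCloud([], [], []), encoder_range=100)


class TestTreePath:
    def test_constant_band(self):
        line = TreeLine(np.array([0.0, 100.0]), np.array([500.0, 500.0]), smoothed=True)
        path = build_tree_path(line, 50.0)
        low, high = path.bounds_at([0, 50, 100])
        assert np.allclose(low, 450.0) and np.allclose(high, 550.0)

    def test_zero_increment_degenerates_to_line(self):
        line = TreeLine(np.array([0.0, 10.0]), np.array([500.0, 520.0]), smoothed=True)
        path = build_tree_path(line, 0.0)
        low, high = path.bounds_at([5])
        assert low[0] == high[0] == pytest.approx(510.0)

    def test_linear_interpolation_between_nodes(self):
        line = TreeLine(np.array([0.0, 10.0]), np.array([500.0, 520.0]), smoothed=True)
        path = build_tree_path(line, 50.0)
        low, high = path.bounds_at([5])
        assert (low[0] + high[0]) / 2 == pytest.approx(510.0)


class TestBinarize:
    def make_path(self, depth=500.0):
        line = TreeLine(np.array([0.0, 1000.0]), np.array([depth, depth]), smoothed=True)
        return build_tree_path(line, 50.0)

    def test_single_point_marks_single_encoder(self):
        cloud = PointCloud([100.0], [500.0], [150.0])
        series = binarize_presence(cloud, self.make_path(), 190.0)
        assert series.window_sum(100, 0) == 1
        assert np.sum(series.values) == 1

    def test_point_outside_band_is_ignored(self):
        cloud = PointCloud([100.0], [600.0], [150.0])
        series = binarize_presence(cloud, self.make_path(), 190.0)
        assert np.sum(series.values) == 0

    def test_presence_is_boolean_not_count(self):
        cloud = PointCloud([200.0] * 3, [500.0] * 3, [150.0, 160.0, 170.0])
        series = binarize_presence(cloud, self.make_path(), 190.0)
        assert np.sum(series.values) == 1


class TestFillJumps:
    @pytest.mark.parametrize(
        "values, jump, expected",
        [
            ([1, 0, 1], 1, [1, 1, 1]),
            ([1, 0, 0, 1], 1, [1, 0, 0, 1]),   # gap exceeds the window
            ([1, 0, 0, 1], 2, [1, 1, 1, 1]),
            ([0, 1, 0], 1, [0, 1, 0]),         # leading/trailing never filled
        ],
    )
    def test_examples(self, values, jump, expected):
        out = fill_jumps(PresenceSeries(0, np.array(values, dtype=bool)), jump)
        assert out.values.tolist() == [bool(v) for v in expected]

    @given(st.lists(st.booleans(), max_size=80), st.integers(0, 5))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_idempotent_and_monotone(self, values, jump):
        series = PresenceSeries(0, np.array(values, dtype=bool))
        once = fill_jumps(series, jump)
        twice = fill_jumps(once, jump)
        assert np.array_equal(once.values, twice.values)
        # monotone: never removes presence
        assert np.all(once.values | ~series.values.astype(bool) | once.values)
        assert np.all(~series.values.astype(bool) | once.values)
        if jump == 0:
            assert np.array_equal(once.values, series.values.astype(bool))


class TestExtractCandidates:
    def test_odd_run(self):
        values = np.zeros(20, dtype=bool)
        values[10:15] = True
        runs = extract_candidates(PresenceSeries(0, values))
        assert runs == [CandidateRun(10, 14, 12)]

    def test_even_run_median_floors(self):
        values = np.zeros(20, dtype=bool)
        values[10:14] = True
        (run,) = extract_candidates(PresenceSeries(0, values))
        # floor convention agrees with the lower middle of the sorted indices
        assert run.median == sorted(range(10, 14))[(4 - 1) // 2] == 11

    def test_empty_series(self):
        assert extract_candidates(PresenceSeries(0, np.zeros(0, dtype=bool))) == []


class TestBlanking:
    def runs(self, medians):
        return [CandidateRun(m, m, m) for m in medians]

    def test_greedy_walk(self):
        kept = apply_blanking(self.runs([100, 150, 300]), 110)
        assert [d.position for d in kept] == [100, 300]

    def test_zero_blanking_keeps_all(self):
        kept = apply_blanking(self.runs([100, 150, 300]), 0)
        assert len(kept) == 3

    def test_rejected_candidate_does_not_reset_reference(self):
        kept = apply_blanking(self.runs([100, 209, 210]), 110)
        assert [d.position for d in kept] == [100, 210]

    def test_unsorted_rejected(self):
        with pytest.raises(OrderingError):
            apply_blanking(self.runs([200, 100]), 110)

    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=50), st.integers(1, 300))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_minimum_separation_invariant(self, medians, blanking):
        kept = apply_blanking(self.runs(sorted(medians)), blanking)
        positions = [d.position for d in kept]
        assert all(b - a >= blanking for a, b in zip(positions, positions[1:]))
        assert positions and positions[0] == sorted(medians)[0]


class TestDetectStems:
    def test_noise_free_row_recovered(self, noise_free_roi_cloud, noise_free_dataset, default_params):
        detections = detect_stems(noise_free_roi_cloud, default_params)
        assert len(detections) == len(noise_free_dataset.truth) == 20
        result = match_to_truth(detections, noise_free_dataset.truth)
        assert not result.false_positives and not result.false_negatives
        assert np.max(np.abs(result.errors)) <= 5

    def test_pipeline_equals_manual_stage_composition(self, noise_free_roi_cloud, default_params):
        p = default_params
        low = apply_height_cut(noise_free_roi_cloud, p.height_cut_mm)
        line = estimate_tree_line(
            low, p.encoder_range_counts, p.node_step_counts, p.depth_bin_mm, p.smooth_window_nodes
        )
        band = build_tree_path(line, p.path_increment_mm)
        series = binarize_presence(noise_free_roi_cloud, band, p.cut_identification_mm)
        filled = fill_jumps(series, p.jump_counts)
        runs = extract_candidates(filled)
        manual = apply_blanking(runs, p.blanking_tree_distance_counts)
        assert manual == detect_stems(noise_free_roi_cloud, p)

    def test_no_in_band_points_yields_no_detections(self, default_params):
        # all points above the cut-identification height: tree line exists,
        # presence is empty
        cloud = cloud_at(np.arange(0, 300), z=205.0)
        params = StemDetectionParams(cut_identification_mm=190.0)
        assert detect_stems(cloud, params) == []

    def test_close_pair_suppressed_by_blanking(self, default_params):
        # two presence clusters 19 counts apart collapse to one detection
        xs = np.array(sorted(list(range(100, 105)) + list(range(119, 124))), dtype=float)
        detections = detect_stems(cloud_at(xs), default_params)
        assert len(detections) == 1

    def test_consecutive_detections_respect_blanking(self, noise_free_roi_cloud, default_params):
        positions = [d.position for d in detect_stems(noise_free_roi_cloud, default_params)]
        gaps = np.diff(positions)
        assert np.all(gaps >= default_params.blanking_tree_distance_counts)
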