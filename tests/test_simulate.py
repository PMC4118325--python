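"""Synthetic nursery-row generator."""

import dataclasses
import math

import numpy as np
import pytest

from stemsense import (
    CurtainParams,
    RigConfig,
    RoiFilter,
    SceneConfig,
    StemDetectionParams,
    build_scene,
    cascade_detect,
    detect_stems,
    filter_roi,
    generate_field,
    location_stats,
    match_to_truth,
    noise_free_config,
    render_curtain_sample,
    render_lidar_scan,
    scans_to_points,
)
from stemsense.errors import InvalidArgumentError
from stemsense.simulate import Scene, scan_stride_counts


class TestSceneConfig:
    def test_rates_validated(self):
        with pytest.raises(InvalidArgumentError):
            SceneConfig(dead_fraction=1.5)
        with pytest.raises(InvalidArgumentError):
            SceneConfig(weed_rate=-1)
        with pytest.raises(InvalidArgumentError):
            SceneConfig(dead_model="zombie")

    def test_scan_stride_matches_speed_planning(self, rig):
        # 3 cm/s at 10 Hz -> a scan every 3 mm of travel
        assert scan_stride_counts(SceneConfig(), rig) == 3


class TestGenerateField:
    def test_seeded_runs_are_identical(self):
        a = generate_field(SceneConfig(seed=11, n_trees=6))
        b = generate_field(SceneConfig(seed=11, n_trees=6))
        assert a.truth == b.truth
        assert a.scans == b.scans
        assert a.curtain == b.curtain

    def test_different_seeds_differ(self):
        a = generate_field(SceneConfig(seed=1, n_trees=6))
        b = generate_field(SceneConfig(seed=2, n_trees=6))
        assert a.scans != b.scans

    def test_zero_noise_truth_layout(self, noise_free_dataset):
        positions = [t.position for t in noise_free_dataset.truth]
        assert len(positions) == 20
        assert np.all(np.diff(positions) == 200)
        assert all(t.alive for t in noise_free_dataset.truth)

    def test_logs_share_encoder_extent(self, noise_free_dataset):
        scan_encoders = [s.encoder for s in noise_free_dataset.scans]
        curtain_encoders = [r.encoder for r in noise_free_dataset.curtain]
        assert min(scan_encoders) == curtain_encoders[0] == 0
        assert curtain_encoders[-1] >= scan_encoders[-1]

    def test_all_dead_leafless_row_blocks_only_stem_beams(self):
        cfg = noise_free_config(seed=5, n_trees=6, dead_fraction=1.0,
                                shortened_stem_fraction=0.0)
        ds = generate_field(cfg)
        stem_positions = {t.position for t in ds.truth}
        assert not any(t.alive for t in ds.truth)
        for r in ds.curtain:
            near_stem = any(abs(r.encoder - p) <= 5 for p in stem_positions)
            # no foliage: LC3 (280 mm) never blocked, LC0-LC2 only at stems
            assert not r.blocked[3]
            if any(r.blocked[:3]):
                assert near_stem
        # every stem does block the three lower beams somewhere
        for p in stem_positions:
            assert any(
                all(r.blocked[:3]) for r in ds.curtain if abs(r.encoder - p) <= 5
            )


class TestRenderLidar:
    def test_stem_centre_beam_returns_stem_depth(self):
        cfg = noise_free_config(seed=0, n_trees=3)
        scene = build_scene(cfg, RigConfig())
        pos = scene.tree_positions[1]
        scan = render_lidar_scan(scene, int(round(pos)))
        # beams in the stem height window should return ~ lidar_offset - r
        stem_beams = [
            (a, r) for a, r in scan.beams
            if 0 < 560 - r * math.sin(math.radians(a)) <= 240
            and abs(r * math.cos(math.radians(a)) - 495) < 10
        ]
        assert stem_beams, "no beams hit the stem"

    def test_no_objects_returns_backdrop_only(self):
        cfg = noise_free_config(seed=0, n_trees=1)
        scene = build_scene(cfg, RigConfig())
        scan = render_lidar_scan(scene, scene.extent)  # far from the tree
        for a, rng_mm in scan.beams:
            depth = rng_mm * math.cos(math.radians(a))
            z = 560 - rng_mm * math.sin(math.radians(a))
            assert depth >= 799 or abs(z) < 1e-6  # background plane or bed top

    def test_edge_beams_return_strictly_intermediate_ranges(self):
        cfg = noise_free_config(seed=3, n_trees=1, outlier_fraction=1.0)
        scene = build_scene(cfg, RigConfig())
        pos = scene.tree_positions[0]
        clean_scene = dataclasses.replace(scene, config=noise_free_config(seed=3, n_trees=1))
        encoder = int(round(pos + scene.stem_radius + 1))  # footprint straddles the edge
        noisy = render_lidar_scan(scene, encoder)
        clean = render_lidar_scan(clean_scene, encoder)
        changed = [
            (ac, rc, rn)
            for (ac, rc), (an, rn) in zip(clean.beams, noisy.beams)
            if abs(rc - rn) > 1e-9
        ]
        assert changed, "outlier_fraction=1 must perturb edge beams"
        for angle, backdrop_range, outlier_range in changed:
            c = math.cos(math.radians(angle))
            stem_range = (500 - scene.stem_radius) / c
            assert stem_range < outlier_range < backdrop_range

    def test_outliers_degrade_localisation(self, rig):
        def sigma(outlier_fraction, seed):
            cfg = dataclasses.replace(
                noise_free_config(seed=seed),
                outlier_fraction=outlier_fraction,
                range_noise_sd_mm=5.0,
                spacing_jitter_sd_mm=3.0,
            )
            ds = generate_field(cfg)
            roi = filter_roi(scans_to_points(ds.scans, rig), RoiFilter(), rig)
            m = match_to_truth(detect_stems(roi, StemDetectionParams()), ds.truth)
            return location_stats(m.errors)[0]

        seeds = (1, 2, 3)
        clean = np.mean([sigma(0.0, s) for s in seeds])
        dirty = np.mean([sigma(1.0, s) for s in seeds])
        assert dirty >= clean


class TestRenderCurtain:
    def test_sample_matches_generated_log(self, noise_free_dataset):
        scene = noise_free_dataset.scene
        for encoder in (0, 200, 205, 1000, scene.extent):
            assert render_curtain_sample(scene, encoder) == noise_free_dataset.curtain[encoder]

    def test_low_weed_blocks_no_beams(self):
        cfg = noise_free_config(seed=0, n_trees=1)
        base = build_scene(cfg, RigConfig())
        weed = Scene(
            config=base.config, rig=base.rig,
            tree_positions=np.array([1e9]),  # move the tree out of the way
            tree_alive=np.array([True]), stem_heights=np.array([250.0]),
            blobs=np.array([[100.0, 500.0, 60.0, 40.0]]),  # top at 100 mm < LC0
            extent=base.extent,
        )
        record = render_curtain_sample(weed, 100)
        assert record.blocked == (False, False, False, False)

    def test_taller_weed_blocks_only_lc0(self):
        cfg = noise_free_config(seed=0, n_trees=1)
        base = build_scene(cfg, RigConfig())
        weed = Scene(
            config=base.config, rig=base.rig,
            tree_positions=np.array([1e9]),
            tree_alive=np.array([True]), stem_heights=np.array([250.0]),
            blobs=np.array([[100.0, 500.0, 120.0, 30.0]]),  # spans 90-150 mm
            extent=base.extent,
        )
        record = render_curtain_sample(weed, 100)
        assert record.blocked == (True, False, False, False)


class TestPipelineOnCleanScenes:
    def test_both_sensors_perfect_on_noise_free_rows(self, noise_free_dataset, rig):
        roi = filter_roi(scans_to_points(noise_free_dataset.scans, rig), RoiFilter(), rig)
        for detections in (
            detect_stems(roi, StemDetectionParams()),
            cascade_detect(noise_free_dataset.curtain, CurtainParams()),
        ):
            result = match_to_truth(detections, noise_free_dataset.truth)
            assert not result.false_positives and not result.false_negatives
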