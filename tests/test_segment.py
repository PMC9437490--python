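"""Thresholding, seeded region growing (wand) and IoU matching."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmorph.scene_sim import build_scene, render_grayscale
from gutmorph.segment import (
    SegmentationParams,
    magic_wand,
    match_to_truth,
    threshold_components,
)
from gutmorph.volio import VoxelGrid

SPACING = (50.0, 15.0, 15.0)


def grid(values):
    return VoxelGrid(np.asarray(values, dtype=np.uint8), SPACING)


def bfs_wand(values, seed, tolerance, connectivity):
    """Independent brute-force BFS over the same predicate as the wand."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dz, dy, dx))
    ref = int(values[seed])
    ok = np.abs(values.astype(np.int16) - ref) <= tolerance
    mask = np.zeros_like(ok)
    queue = deque([seed])
    mask[seed] = True
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= i < s for i, s in zip(n, values.shape)) and ok[n] and not mask[n]:
                mask[n] = True
                queue.append(n)
    return mask


class TestThresholdComponents:
    def test_uniform_volume_yields_single_component(self):
        vol = grid(np.full((5, 6, 7), 200))
        params = SegmentationParams(low=190, high=255, min_size_voxels=1)
        labels = threshold_components(vol, params)
        assert (labels.values == 1).all()

    def test_min_size_above_total_voxels_removes_everything(self):
        vol = grid(np.full((4, 4, 4), 200))
        params = SegmentationParams(low=0, high=255, min_size_voxels=65)
        labels = threshold_components(vol, params)
        assert not labels.values.any()

    def test_labels_ordered_by_size_then_anchor(self):
        vol = np.zeros((3, 10, 10), dtype=np.uint8)
        vol[1, 7:9, 7:9] = 255  # 4 voxels, later anchor
        vol[1, 1:3, 1:4] = 255  # 6 voxels
        vol[0, 0, 9] = 255  # 1 voxel
        labels = threshold_components(
            grid(vol), SegmentationParams(low=200, high=255, min_size_voxels=1)
        )
        assert labels.values[1, 1, 1] == 1  # biggest first
        assert labels.values[1, 7, 7] == 2
        assert labels.values[0, 0, 9] == 3

    def test_relabeling_is_idempotent(self):
        rng = np.random.default_rng(3)
        vol = grid(rng.integers(0, 256, size=(12, 12, 12)))
        params = SegmentationParams(low=128, high=255, min_size_voxels=2)
        a = threshold_components(vol, params)
        b = threshold_components(vol, params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mask_restricts_components(self):
        vol = grid(np.full((4, 4, 4), 210))
        mask = np.zeros((4, 4, 4), dtype=np.uint8)
        mask[:2] = 1
        labels = threshold_components(
            vol,
            SegmentationParams(low=200, high=255, min_size_voxels=1),
            mask=VoxelGrid(mask, SPACING),
        )
        assert labels.values[:2].all() and not labels.values[2:].any()

    def test_rejects_non_intensity_input(self):
        bad = VoxelGrid(np.zeros((2, 2, 2), dtype=np.uint16), SPACING)
        with pytest.raises(ValueError, match="8-bit"):
            threshold_components(bad, SegmentationParams())

    def test_noise_free_render_recovers_planted_secretory_exactly(self, small_config):
        """Thresholding a clean render reproduces the planted vesicle masks."""
        config = small_config
        import copy

        config = copy.deepcopy(config)
        config.render.noise_sd = 0.0
        scene, truth = build_scene(config, seed=2)
        img = render_grayscale(scene, config, seed=2)
        pred = threshold_components(
            img,
            SegmentationParams(low=200, high=255, min_size_voxels=1),
            mask=scene.cells,
        )
        sec_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "secretory", "vesicle_id"
        ].to_numpy()
        sec_truth = np.where(
            np.isin(scene.vesicles.values, sec_ids), scene.vesicles.values, 0
        )
        pairs, summary = match_to_truth(
            pred, VoxelGrid(sec_truth.astype(np.uint16), SPACING)
        )
        assert summary["n_true"] == len(sec_ids)
        assert summary["n_pred"] == len(sec_ids)
        assert summary["n_missed"] == 0 and summary["n_spurious"] == 0
        assert (pairs["iou"] == 1.0).all()

    def test_noisy_render_detection_rate(self, small_config):
        """With default noise, nearly all planted secretory vesicles are
        recovered at IoU >= 0.5 by the default band threshold."""
        scene, truth = build_scene(small_config, seed=4)
        img = render_grayscale(scene, small_config, seed=4)
        pred = threshold_components(img, SegmentationParams(), mask=scene.cells)
        sec_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "secretory", "vesicle_id"
        ].to_numpy()
        sec_truth = np.where(
            np.isin(scene.vesicles.values, sec_ids), scene.vesicles.values, 0
        )
        _, summary = match_to_truth(
            pred, VoxelGrid(sec_truth.astype(np.uint16), SPACING)
        )
        assert summary["n_detected"] >= 0.95 * summary["n_true"]


class TestMagicWand:
    def test_singleton_when_tolerance_zero(self):
        vol = np.full((3, 3, 3), 100, dtype=np.uint8)
        vol[1, 1, 1] = 200
        mask = magic_wand(grid(vol), (1, 1, 1), SegmentationParams(wand_tolerance=0))
        assert mask.sum() == 1 and mask[1, 1, 1]

    def test_saturating_tolerance_floods_everything(self):
        rng = np.random.default_rng(0)
        vol = grid(rng.integers(0, 256, size=(6, 6, 6)))
        mask = magic_wand(vol, (0, 0, 0), SegmentationParams(wand_tolerance=255))
        assert mask.all()

    def test_out_of_bounds_seed_raises(self):
        vol = grid(np.zeros((4, 4, 4)))
        with pytest.raises(IndexError, match="out of bounds"):
            magic_wand(vol, (4, 0, 0), SegmentationParams())

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        tolerance=st.integers(0, 60),
        connectivity=st.sampled_from([6, 26]),
    )
    def test_wand_equals_brute_force_bfs(self, seed, tolerance, connectivity):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=(8, 8, 8)).astype(np.uint8)
        voxel = tuple(rng.integers(0, 8, size=3))
        params = SegmentationParams(
            wand_tolerance=tolerance, wand_connectivity=connectivity
        )
        got = magic_wand(VoxelGrid(values, SPACING), voxel, params)
        want = bfs_wand(values, voxel, tolerance, connectivity)
        np.testing.assert_array_equal(got, want)


class TestMatchToTruth:
    def test_identical_grids_match_perfectly(self):
        labels = np.zeros((4, 6, 6), dtype=np.uint16)
        labels[1, 1:3, 1:3] = 1
        labels[2, 4:6, 4:6] = 2
        g = VoxelGrid(labels, SPACING)
        pairs, summary = match_to_truth(g, g)
        assert (pairs["iou"] == 1.0).all()
        assert summary == {
            "n_true": 2,
            "n_pred": 2,
            "n_detected": 2,
            "n_missed": 0,
            "n_spurious": 0,
        }

    def test_empty_prediction_misses_all(self):
        truth = np.zeros((3, 3, 3), dtype=np.uint16)
        truth[0, 0, 0] = 1
        truth[2, 2, 2] = 2
        pred = VoxelGrid(np.zeros_like(truth), SPACING)
        pairs, summary = match_to_truth(pred, VoxelGrid(truth, SPACING))
        assert len(pairs) == 0
        assert summary["n_detected"] == 0 and summary["n_missed"] == 2

    def test_greedy_assignment_prefers_higher_iou(self):
        """Two predictions overlap one truth object; the better one is
        matched, the other counted spurious — checked against exhaustive
        enumeration of the one-to-one pairings."""
        truth = np.zeros((1, 1, 10), dtype=np.uint16)
        truth[0, 0, 0:6] = 1
        pred = np.zeros_like(truth)
        pred[0, 0, 0:4] = 1  # IoU 4/6
        pred[0, 0, 4:6] = 2  # IoU 2/6
        pairs, summary = match_to_truth(
            VoxelGrid(pred, SPACING), VoxelGrid(truth, SPACING)
        )
        # exhaustive: pairing truth->pred1 has IoU 4/6 > truth->pred2 2/6
        assert len(pairs) == 1
        assert pairs.iloc[0]["pred_id"] == 1
        assert pairs.iloc[0]["iou"] == pytest.approx(4 / 6)
        assert summary["n_spurious"] == 1

    def test_shape_mismatch_raises(self):
        a = VoxelGrid(np.zeros((2, 2, 2), dtype=np.uint16), SPACING)
        b = VoxelGrid(np.zeros((2, 2, 3), dtype=np.uint16), SPACING)
        with pytest.raises(ValueError, match="shape"):
            match_to_truth(a, b)
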