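"""Segmentation stages against brute-force oracles and the phantom."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lungct as lc
from lungct.segment import (
    AUTO,
    RefinementError,
    SegmentationParams,
    SelectionError,
    crop_from_base,
    label_components,
    refine_mask,
    select_lung_component,
    segment_lung,
    threshold_mask,
)
from lungct.volume_io import CTVolume

from .conftest import flood_fill_components


class TestThreshold:
    def test_default_closed_range(self):
        hu = np.array([-1200.0, -500.0, -100.0, 50.0]).reshape(4, 1, 1)
        sel = threshold_mask(hu)
        np.testing.assert_array_equal(sel.ravel(), [True, True, False, False])

    def test_degenerate_range_selects_exact_value(self):
        hu = np.array([-501.0, -500.0, -499.0]).reshape(3, 1, 1)
        sel = threshold_mask(hu, lo=-500, hi=-500)
        np.testing.assert_array_equal(sel.ravel(), [False, True, False])

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2, 2)), lo=0, hi=-1)

    def test_phantom_count_matches_brute_force(self, default_phantom):
        _, vol, _, _ = default_phantom
        assert threshold_mask(vol).sum() == int((vol.voxels <= -200).sum())

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.float64, (4, 4, 4),
                      elements=st.floats(-2000, 500, allow_nan=False)),
           st.floats(-500, -100), st.floats(0, 300))
    def test_raising_hi_is_monotone(self, hu, hi, bump):
        lower = threshold_mask(hu, hi=hi)
        higher = threshold_mask(hu, hi=hi + bump)
        assert np.all(higher[lower])


class TestLabelComponents:
    def test_opposite_corners_connectivity_6(self):
        grid = np.zeros((3, 3, 1), bool)
        grid[0, 0, 0] = grid[2, 2, 0] = True
        assert label_components(grid, 6).n_components == 2

    def test_in_plane_diagonal_merges_under_26(self):
        grid = np.zeros((3, 3, 1), bool)
        grid[0, 0, 0] = grid[1, 1, 0] = True
        assert label_components(grid, 6).n_components == 2
        assert label_components(grid, 26).n_components == 1

    def test_empty_mask(self):
        lab = label_components(np.zeros((3, 3, 3), bool))
        assert lab.n_components == 0

    def test_labels_ordered_largest_first(self):
        grid = np.zeros((10, 3, 3), bool)
        grid[0:2] = True     # 18 voxels
        grid[5:9] = True     # 36 voxels
        lab = label_components(grid, 6)
        assert lab.count_of(1) == 36 and lab.count_of(2) == 18
        assert lab.labels[5, 0, 0] == 1 and lab.labels[0, 0, 0] == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        """Component partitions match an independent BFS flood fill on 50 grids."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            mask = rng.random((8, 8, 8)) < rng.uniform(0.1, 0.6)
            lab = label_components(mask, connectivity)
            ours = {frozenset(zip(*np.nonzero(lab.labels == l)))
                    for l in range(1, lab.n_components + 1)}
            oracle = set(flood_fill_components(mask, connectivity))
            assert ours == oracle


class TestSelectLungComponent:
    def test_explicit_label_absent(self):
        grid = np.zeros((3, 3, 3), bool)
        grid[1, 1, 1] = True
        with pytest.raises(SelectionError):
            select_lung_component(label_components(grid), 2)

    def test_seed_mode_returns_label_under_seed(self, default_phantom):
        spec, vol, truth, _ = default_phantom
        lab = label_components(threshold_mask(vol))
        seed = tuple(int(c[len(c) // 2]) for c in np.nonzero(truth.mask))
        label = select_lung_component(lab, seed)
        assert label == lab.labels[seed] and label > 0

    def test_seed_in_background_rejected(self):
        grid = np.zeros((3, 3, 3), bool)
        grid[0, 0, 0] = True
        with pytest.raises(SelectionError):
            select_lung_component(label_components(grid), (2, 2, 2))

    def test_auto_skips_exterior_air(self, default_phantom):
        """AUTO must pick the interior lung, not the face-touching air wrap."""
        spec, vol, truth, _ = default_phantom
        lab = label_components(threshold_mask(vol))
        label = select_lung_component(lab, AUTO)
        component = lab.labels == label
        overlap = np.logical_and(component, truth.mask).sum()
        assert overlap / truth.voxel_count > 0.95

    def test_auto_with_no_interior_component(self):
        grid = np.ones((4, 4, 4), bool)  # single component touches all faces
        with pytest.raises(SelectionError, match="seed"):
            select_lung_component(label_components(grid), AUTO)


class TestRefineMask:
    def test_erosion_of_cube(self):
        cube = np.zeros((7, 7, 7), bool)
        cube[1:6, 1:6, 1:6] = True
        out = refine_mask(cube, erosion_radius=1, dilation_radius=0)
        assert out.sum() == 27

    def test_hole_filling_closes_ring(self):
        ring = np.zeros((7, 7, 1), bool)
        ring[1:6, 1:6, 0] = True
        ring[2:5, 2:5, 0] = False
        out = refine_mask(ring, erosion_radius=0, dilation_radius=0)
        assert out[:, :, 0].sum() == 25  # solid 5x5 disk

    def test_erosion_emptying_reports_stage(self):
        dot = np.zeros((5, 5, 5), bool)
        dot[2, 2, 2] = True
        with pytest.raises(RefinementError, match="erosion"):
            refine_mask(dot, erosion_radius=2, dilation_radius=0)

    def test_dilate_after_erode_stays_within_convex_input(self):
        cube = np.zeros((9, 9, 9), bool)
        cube[2:7, 2:7, 2:7] = True
        out = refine_mask(cube, erosion_radius=1, dilation_radius=1)
        assert np.all(cube[out])

    def test_phantom_component_retains_ground_truth(self, default_phantom):
        spec, vol, truth, _ = default_phantom
        lab = label_components(threshold_mask(vol))
        label = select_lung_component(lab, AUTO)
        refined = refine_mask(lab.labels == label)
        coverage = np.logical_and(refined, truth.mask).sum() / truth.voxel_count
        assert coverage >= 0.95

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            refine_mask(np.ones((3, 3, 3), bool), erosion_radius=-1)


class TestCropFromBase:
    def test_crops_below_base(self):
        mask = np.zeros((4, 4, 60), bool)
        mask[:, :, 10:51] = True
        out = crop_from_base(mask, 20, "to_apex")
        occupied = np.nonzero(out.any(axis=(0, 1)))[0]
        assert occupied.min() == 20 and occupied.max() == 50

    def test_base_zero_is_identity(self):
        rng = np.random.default_rng(5)
        mask = rng.random((5, 5, 8)) < 0.3
        np.testing.assert_array_equal(crop_from_base(mask, 0, "full_stack"), mask)

    def test_out_of_stack_base_rejected(self):
        with pytest.raises(ValueError):
            crop_from_base(np.ones((3, 3, 3), bool), 3)

    def test_decoy_below_base_removed(self, default_phantom):
        """The abdominal gas pocket below the diaphragm must not survive the crop."""
        spec, vol, truth, _ = default_phantom
        rough = threshold_mask(vol)
        cropped = crop_from_base(rough, spec.default_base_slice)
        # everything below the base is gone...
        assert not cropped[:, :, :spec.default_base_slice].any()
        # ...but no ground-truth lung voxel was lost
        assert np.logical_and(cropped, truth.mask).sum() == \
            np.logical_and(rough, truth.mask).sum()


class TestSegmentLung:
    def test_phantom_recovery_within_tolerance(self, default_phantom, segmented_default):
        spec, vol, truth, true_volume = default_phantom
        mask = segmented_default
        assert mask.volume_mm3 == pytest.approx(true_volume, rel=0.05)
        inter = np.logical_and(mask.mask, truth.mask).sum()
        dice = 2 * inter / (mask.voxel_count + truth.voxel_count)
        assert dice >= 0.9

    def test_all_air_volume_has_no_interior_component(self):
        vol = CTVolume(np.full((32, 32, 32), -1000.0), spacing=(0.1, 0.1, 0.1))
        with pytest.raises(SelectionError):
            segment_lung(vol)

    def test_rerun_is_bitwise_identical(self, default_phantom):
        spec, vol, _, _ = default_phantom
        params = SegmentationParams(base_slice=spec.default_base_slice)
        m1 = segment_lung(vol, params)
        m2 = segment_lung(vol, params)
        np.testing.assert_array_equal(m1.mask, m2.mask)
        assert m1.selected_label == m2.selected_label

    def test_provenance_recorded(self, segmented_default, default_phantom):
        spec = default_phantom[0]
        m = segmented_default
        assert m.base_slice == spec.default_base_slice
        assert m.refine_params["hi_hu"] == -200.0
        assert m.selected_label >= 1
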