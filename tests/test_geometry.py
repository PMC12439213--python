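import math

import numpy as np
import pytest

from contourqa.errors import EmptyMaskError, GridMismatchError
from contourqa.geometry import (
    apply_caudal_cutoff,
    centre_of_mass_difference,
    dice,
    directed_surface_distances,
    evaluate_pair,
    hausdorff,
    mean_surface_distance,
    surface_voxels,
    volume_cc,
    volume_difference,
)
from contourqa.io import ImageGrid, StructureMask

from conftest import brute_hd_msd, mask_from_indices, random_mask


def cube(shape, lo, hi, spacing=(1, 1, 1), name="m"):
    vox = np.zeros(shape, bool)
    vox[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return StructureMask(ImageGrid(shape, spacing), vox, name)


class TestSurface:
    def test_solid_cube_surface_is_shell(self):
        m = cube((5, 5, 5), (1, 1, 1), (4, 4, 4))
        s = surface_voxels(m)
        assert s.voxels.sum() == 26  # 27 voxels minus the centre
        assert not s.voxels[2, 2, 2]
        # surface removal equals the erosion remainder
        assert (m.voxels & ~s.voxels).sum() == 1

    def test_single_voxel_is_its_own_surface(self):
        m = mask_from_indices([(3, 3, 3)])
        assert surface_voxels(m).voxels.sum() == 1

    def test_one_voxel_thick_plane_all_surface(self):
        m = cube((6, 6, 6), (1, 1, 3), (5, 5, 4))
        assert (surface_voxels(m).voxels == m.voxels).all()

    def test_empty_mask_errors(self, small_grid):
        with pytest.raises(EmptyMaskError, match="empty"):
            surface_voxels(StructureMask(small_grid, np.zeros((8, 8, 8), bool)))


class TestDirectedDistances:
    def test_three_four_five(self):
        a = mask_from_indices([(0, 0, 0)])
        b = mask_from_indices([(3, 4, 0)])
        d = directed_surface_distances(surface_voxels(a), surface_voxels(b))
        np.testing.assert_allclose(d, [5.0])

    def test_anisotropic_spacing(self):
        a = mask_from_indices([(0, 0, 0)], spacing=(1, 1, 2))
        b = mask_from_indices([(0, 0, 3)], spacing=(1, 1, 2))
        d = directed_surface_distances(surface_voxels(a), surface_voxels(b))
        np.testing.assert_allclose(d, [6.0])

    def test_self_distances_zero(self):
        m = cube((6, 6, 6), (1, 1, 1), (4, 4, 4))
        s = surface_voxels(m)
        assert (directed_surface_distances(s, s) == 0).all()


class TestDice:
    def test_face_slab_overlap(self):
        a = cube((8, 8, 8), (1, 1, 1), (3, 3, 3))
        b = cube((8, 8, 8), (1, 1, 2), (3, 3, 4))
        assert dice(a, b) == 0.5  # 2*4 / (8+8)

    def test_identical_and_disjoint(self):
        a = cube((8, 8, 8), (1, 1, 1), (3, 3, 3))
        c = cube((8, 8, 8), (5, 5, 5), (7, 7, 7))
        assert dice(a, a.copy()) == 1.0
        assert dice(a, c) == 0.0

    def test_both_empty_undefined(self, small_grid):
        e = StructureMask(small_grid, np.zeros((8, 8, 8), bool))
        with pytest.raises(EmptyMaskError, match="undefined DSC"):
            dice(e, e.copy())

    def test_grid_mismatch(self):
        a = cube((8, 8, 8), (1, 1, 1), (3, 3, 3))
        b = cube((8, 8, 8), (1, 1, 1), (3, 3, 3), spacing=(2, 2, 2))
        with pytest.raises(GridMismatchError):
            dice(a, b)


class TestSurfaceMetrics:
    def test_single_voxel_pair(self):
        a = mask_from_indices([(0, 0, 0)])
        b = mask_from_indices([(3, 4, 0)])
        assert hausdorff(a, b) == pytest.approx(5.0)
        assert mean_surface_distance(a, b) == pytest.approx(5.0)

    def test_identical_masks_zero(self):
        m = cube((8, 8, 8), (2, 2, 2), (6, 6, 6))
        assert hausdorff(m, m.copy()) == 0.0
        assert mean_surface_distance(m, m.copy()) == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spacing = rng.choice([(1, 1, 1), (1, 1, 2), (0.5, 0.5, 1.5)])
        grid = ImageGrid((8, 8, 8), spacing)
        a = StructureMask(grid, random_mask(rng), "a")
        b = StructureMask(grid, random_mask(rng), "b")
        hd_ref, msd_ref = brute_hd_msd(a.voxels, b.voxels, spacing)
        assert hausdorff(a, b) == pytest.approx(hd_ref, abs=1e-9)
        assert mean_surface_distance(a, b) == pytest.approx(msd_ref, abs=1e-9)

    def test_msd_bounded_by_hd_and_symmetric(self):
        rng = np.random.default_rng(11)
        grid = ImageGrid((8, 8, 8), (1, 1, 1.5))
        for _ in range(20):
            a = StructureMask(grid, random_mask(rng), "a")
            b = StructureMask(grid, random_mask(rng), "b")
            assert mean_surface_distance(a, b) <= hausdorff(a, b) + 1e-12
            assert hausdorff(a, b) == pytest.approx(hausdorff(b, a))
            assert mean_surface_distance(a, b) == pytest.approx(mean_surface_distance(b, a))

    def test_uniform_spacing_scaling(self):
        rng = np.random.default_rng(3)
        vox_a, vox_b = random_mask(rng), random_mask(rng)
        g1 = ImageGrid((8, 8, 8), (1, 1, 1))
        g2 = ImageGrid((8, 8, 8), (3, 3, 3))
        a1, b1 = StructureMask(g1, vox_a), StructureMask(g1, vox_b)
        a2, b2 = StructureMask(g2, vox_a), StructureMask(g2, vox_b)
        assert dice(a1, b1) == dice(a2, b2)
        assert hausdorff(a2, b2) == pytest.approx(3 * hausdorff(a1, b1))
        assert mean_surface_distance(a2, b2) == pytest.approx(3 * mean_surface_distance(a1, b1))
        assert centre_of_mass_difference(a2, b2) == pytest.approx(
            3 * centre_of_mass_difference(a1, b1)
        )


class TestVolume:
    def test_thousand_unit_voxels_is_one_cc(self):
        m = cube((12, 12, 12), (1, 1, 1), (11, 11, 11))
        assert volume_cc(m) == pytest.approx(1.0)

    def test_quarter_cm_voxel_volume(self):
        # one voxel on a 0.25 cm grid represents 0.0156 cc
        m = mask_from_indices([(0, 0, 0)], spacing=(2.5, 2.5, 2.5))
        assert volume_cc(m) == pytest.approx(0.015625)

    def test_empty_mask_zero(self, small_grid):
        assert volume_cc(StructureMask(small_grid, np.zeros((8, 8, 8), bool))) == 0.0

    def test_volume_difference_signed(self):
        test = cube((10, 10, 10), (0, 0, 0), (5, 10, 10))  # 500 voxels = 0.5 cc
        ref = cube((10, 10, 10), (0, 0, 0), (10, 10, 10))  # 1000 voxels = 1.0 cc
        vd, rel = volume_difference(test, ref)
        assert vd == pytest.approx(-0.5)
        assert rel == pytest.approx(-50.0)
        vd_sw, _ = volume_difference(ref, test)
        assert vd_sw == pytest.approx(0.5)  # antisymmetry

    def test_empty_reference_relative_nan(self, small_grid):
        test = cube((8, 8, 8), (0, 0, 0), (2, 2, 2))
        empty = StructureMask(small_grid, np.zeros((8, 8, 8), bool))
        vd, rel = volume_difference(test, empty)
        assert vd == pytest.approx(volume_cc(test))
        assert math.isnan(rel)


class TestCentreOfMass:
    def test_identical_masks(self):
        m = cube((8, 8, 8), (2, 2, 2), (5, 5, 5))
        assert centre_of_mass_difference(m, m.copy()) == 0.0

    def test_whole_voxel_z_shift(self):
        grid = ImageGrid((8, 8, 10), (1, 1, 2))
        vox = np.zeros((8, 8, 10), bool)
        vox[2:5, 2:5, 1:3] = True
        shifted = np.roll(vox, 3, axis=2)
        a = StructureMask(grid, vox)
        b = StructureMask(grid, shifted)
        assert centre_of_mass_difference(a, b) == pytest.approx(6.0)
        assert dice(b, b.copy()) == 1.0

    def test_single_voxels(self):
        a = mask_from_indices([(0, 0, 0)])
        b = mask_from_indices([(3, 4, 0)])
        assert centre_of_mass_difference(a, b) == pytest.approx(5.0)


class TestCaudalCutoff:
    def make_sc(self, lo, hi):
        return cube((6, 6, 24), (2, 2, lo), (4, 4, hi), name="spinal_cord")

    def test_truncates_to_latest_caudal_end(self):
        masks = [self.make_sc(5, 21), self.make_sc(7, 21), self.make_sc(6, 21)]
        out = apply_caudal_cutoff(masks)
        for m in out:
            occupied = np.nonzero(m.voxels.any(axis=(0, 1)))[0]
            assert occupied[0] == 7
            assert occupied[-1] == 20  # cranial extent untouched

    def test_identical_ends_noop(self):
        masks = [self.make_sc(5, 20), self.make_sc(5, 18)]
        out = apply_caudal_cutoff(masks)
        for before, after in zip(masks, out):
            np.testing.assert_array_equal(before.voxels, after.voxels)

    def test_idempotent(self):
        masks = [self.make_sc(5, 21), self.make_sc(9, 21)]
        once = apply_caudal_cutoff(masks)
        twice = apply_caudal_cutoff(once)
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_empty_mask_errors(self):
        empty = StructureMask(ImageGrid((6, 6, 24), (1, 1, 1)), np.zeros((6, 6, 24), bool))
        with pytest.raises(EmptyMaskError):
            apply_caudal_cutoff([self.make_sc(5, 20), empty])


class TestEvaluatePair:
    def test_self_comparison_is_identity_report(self):
        m = cube((8, 8, 8), (2, 2, 2), (6, 6, 6))
        rep = evaluate_pair(m, m.copy())
        assert rep.dsc == 1.0
        assert rep.msd_mm == rep.hd_mm == rep.cmd_mm == 0.0
        assert rep.vd_cc == rep.vd_rel_pct == 0.0

    def test_composes_per_metric_values(self):
        a = cube((8, 8, 8), (1, 1, 1), (3, 3, 3))
        b = cube((8, 8, 8), (1, 1, 2), (3, 3, 4))
        rep = evaluate_pair(a, b)
        assert rep.dsc == 0.5
        assert rep.hd_mm == pytest.approx(hausdorff(a, b))
        assert rep.msd_mm == pytest.approx(mean_surface_distance(a, b))
        assert rep.vd_cc == pytest.approx(volume_difference(a, b)[0])
        assert rep.cmd_mm == pytest.approx(centre_of_mass_difference(a, b))

    def test_empty_reference_degrades_to_missing(self, small_grid):
        test = cube((8, 8, 8), (0, 0, 0), (2, 2, 2))
        empty = StructureMask(small_grid, np.zeros((8, 8, 8), bool))
        rep = evaluate_pair(test, empty)
        assert math.isnan(rep.msd_mm) and math.isnan(rep.hd_mm) and math.isnan(rep.cmd_mm)
        assert rep.dsc == 0.0
        assert rep.vd_cc == pytest.approx(volume_cc(test))

    def test_vd_negates_under_swap(self):
        a = cube((8, 8, 8), (1, 1, 1), (4, 4, 4))
        b = cube((8, 8, 8), (2, 2, 2), (6, 6, 6))
        assert evaluate_pair(a, b).vd_cc == pytest.approx(-evaluate_pair(b, a).vd_cc)
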