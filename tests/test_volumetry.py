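"""The four volume estimators against analytic and brute-force oracles."""

import numpy as np
import pytest
from conftest import digital_ball, voxelized_ellipsoid
from tests_helpers import frustum_sum_oracle

from hemovol.volumetry import (
    abc_over_2,
    pca_axes_2d,
    pca_axes_3d,
    planimetry_volume,
    truncated_pyramid_volume,
)
from hemovol.voxelgrid import VoxelGrid


def _grid_from_slices(slices, s=1.0, dx=1.0):
    occ = np.stack(slices).astype(bool)
    return VoxelGrid(occ, s, dx)


class TestPlanimetry:
    def test_single_voxel_one_cc(self, single_voxel_grid):
        assert planimetry_volume(single_voxel_grid).volume_cm3 == pytest.approx(1.0)

    def test_thousand_unit_voxels(self):
        occ = np.ones((10, 10, 10), dtype=bool)
        v = planimetry_volume(VoxelGrid(occ, 1.0, 1.0)).volume_cm3
        assert v == pytest.approx(1.0)

    def test_exact_formula_on_random_grids(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            occ = rng.random((3, 9, 9)) < rng.uniform(0.1, 0.9)
            if not occ.any():
                continue
            s, dx = rng.uniform(0.2, 3.0, size=2)
            v = planimetry_volume(VoxelGrid(occ, s, dx)).volume_cm3
            assert v == pytest.approx(occ.sum() * s * s * dx / 1000.0, rel=1e-12)

    def test_additive_over_disjoint_sets(self):
        rng = np.random.default_rng(6)
        a = rng.random((4, 8, 8)) < 0.3
        b = (rng.random((4, 8, 8)) < 0.3) & ~a
        va = planimetry_volume(VoxelGrid(a, 0.5, 1.5)).volume_cm3
        vb = planimetry_volume(VoxelGrid(b, 0.5, 1.5)).volume_cm3
        vu = planimetry_volume(VoxelGrid(a | b, 0.5, 1.5)).volume_cm3
        assert vu == pytest.approx(va + vb, rel=1e-12)

    def test_voxelized_ellipsoid_close_to_analytic(self):
        grid = voxelized_ellipsoid(24, 19, 14.5, h=0.5)
        v = planimetry_volume(grid).volume_cm3
        analytic = 4 / 3 * np.pi * 24 * 19 * 14.5 / 1000.0
        assert v == pytest.approx(analytic, rel=0.01)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            planimetry_volume(VoxelGrid(np.zeros((1, 2, 2), dtype=bool), 1, 1))


def _square_slice(side_px, canvas=40):
    sl = np.zeros((canvas, canvas), dtype=bool)
    lo = (canvas - side_px) // 2
    sl[lo : lo + side_px, lo : lo + side_px] = True
    return sl


class TestTruncatedPyramid:
    def test_single_slice_caps_only(self):
        # area 300 mm^2 (3x100 px at s=... use 10x30 px of s=1), dX=10
        sl = np.zeros((20, 40), dtype=bool)
        sl[5:15, 5:35] = True  # 300 px of 1 mm^2
        grid = _grid_from_slices([sl], s=1.0, dx=10.0)
        v = truncated_pyramid_volume(grid).volume_cm3
        assert v == pytest.approx(2 * (300 * 10) / 3 / 1000.0)

    def test_two_equal_slices(self):
        sl = np.zeros((20, 40), dtype=bool)
        sl[5:15, 5:35] = True
        grid = _grid_from_slices([sl, sl], s=1.0, dx=10.0)
        assert truncated_pyramid_volume(grid).volume_cm3 == pytest.approx(5.0)

    def test_square_pyramid_matches_area_sequence_oracle(self):
        slices = [_square_slice(k) for k in range(10, 0, -1)]
        grid = _grid_from_slices(slices, s=1.0, dx=2.0)
        want = frustum_sum_oracle([k * k for k in range(10, 0, -1)], dx=2.0)
        assert truncated_pyramid_volume(grid).volume_cm3 == pytest.approx(
            want / 1000.0, rel=1e-9
        )

    def test_disconnected_regions_capped_separately(self):
        # two single-voxel towers of height 1, far apart
        sl = np.zeros((10, 10), dtype=bool)
        sl[1, 1] = sl[8, 8] = True
        grid = _grid_from_slices([sl], s=2.0, dx=3.0)
        # each region: two caps of (1/3)*4*3
        assert truncated_pyramid_volume(grid).volume_cm3 == pytest.approx(
            2 * 2 * (4 * 3) / 3 / 1000.0
        )

    def test_branching_merges_overlap_union(self):
        """A slice with 2 regions facing 1 region contributes one frustum."""
        two = np.zeros((10, 12), dtype=bool)
        two[4:6, 2:4] = True   # area 4
        two[4:6, 8:10] = True  # area 4
        one = np.zeros((10, 12), dtype=bool)
        one[4:6, 2:10] = True  # area 16, overlaps both
        grid = _grid_from_slices([two, one], s=1.0, dx=1.0)
        want = (
            frustum_sum_oracle([], 1)  # no-op, keeps intent clear
            + (8 + 16 + np.sqrt(8 * 16)) / 3.0  # merged frustum
            + 8 / 3.0  # bottom caps of the two small regions
            + 16 / 3.0  # top cap of the big region
        )
        assert truncated_pyramid_volume(grid).volume_cm3 == pytest.approx(
            want / 1000.0, rel=1e-12
        )

    def test_close_to_planimetry_on_convex_stack(self):
        grid = voxelized_ellipsoid(20, 16, 12, h=0.5)
        v_f = truncated_pyramid_volume(grid).volume_cm3
        v_p = planimetry_volume(grid).volume_cm3
        assert abs(v_f - v_p) / v_p < 0.05


class TestPcaAxes2d:
    def test_axis_aligned_rectangle(self):
        sl = np.zeros((30, 30), dtype=bool)
        sl[5:15, 4:24] = True  # 10 rows x 20 cols
        axes = pca_axes_2d(_grid_from_slices([sl]))
        assert axes.A == pytest.approx(20.0)
        assert axes.B == pytest.approx(10.0)
        assert axes.C == pytest.approx(1.0)  # one slice, dX=1

    def test_rotated_rectangle_extent(self):
        # 20 mm x 10 mm rectangle rotated 45 deg, pixel 0.25 mm
        s = 0.25
        n = 140
        ax = (np.arange(n) - n / 2) * s
        X, Y = np.meshgrid(ax, ax)
        u = (X + Y) / np.sqrt(2)
        v = (X - Y) / np.sqrt(2)
        sl = (np.abs(u) <= 10) & (np.abs(v) <= 5)
        axes = pca_axes_2d(VoxelGrid(sl[None], s, 1.0))
        assert axes.A == pytest.approx(20.0, abs=2 * s)
        assert axes.B == pytest.approx(10.0, abs=2 * s)

    def test_c_counts_nonempty_slices(self):
        sl = np.zeros((8, 8), dtype=bool)
        sl[2:5, 2:6] = True
        grid = _grid_from_slices([sl] * 7, s=1.0, dx=1.5)
        assert pca_axes_2d(grid).C == pytest.approx(10.5)

    def test_single_pixel_slice_degenerate(self, single_voxel_grid):
        axes = pca_axes_2d(single_voxel_grid)
        assert axes.A == pytest.approx(10.0)  # one pixel of s=10
        assert axes.B == pytest.approx(10.0)

    def test_translation_invariance(self):
        sl = np.zeros((40, 40), dtype=bool)
        sl[5:15, 4:24] = True
        a1 = pca_axes_2d(_grid_from_slices([sl]))
        a2 = pca_axes_2d(_grid_from_slices([np.roll(sl, (9, 7), axis=(0, 1))]))
        assert a1.A == pytest.approx(a2.A) and a1.B == pytest.approx(a2.B)


class TestPcaAxes3d:
    def test_axis_aligned_box(self):
        occ = np.zeros((14, 24, 44), dtype=bool)
        occ[2:12, 2:22, 2:42] = True  # 10 x 20 x 40 voxels
        axes = pca_axes_3d(VoxelGrid(occ, 1.0, 1.0))
        assert axes.A == pytest.approx(40.0, abs=1.0)
        assert axes.B == pytest.approx(20.0, abs=1.0)
        assert axes.C == pytest.approx(10.0, abs=1.0)

    def test_digital_sphere_axes(self):
        grid = digital_ball(15)  # diameter 30
        axes = pca_axes_3d(grid)
        for L in (axes.A, axes.B, axes.C):
            assert L == pytest.approx(30.0, abs=1.5)

    def test_rotation_changes_axes_little(self):
        rng = np.random.default_rng(3)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        g0 = voxelized_ellipsoid(18, 12, 8, h=0.4)
        g1 = voxelized_ellipsoid(18, 12, 8, h=0.4, rot=rot)
        a0, a1 = pca_axes_3d(g0), pca_axes_3d(g1)
        for x, y in [(a0.A, a1.A), (a0.B, a1.B), (a0.C, a1.C)]:
            assert x == pytest.approx(y, abs=0.8)  # < 2 voxels of 0.4 mm

    def test_anisotropic_spacing_respected(self):
        occ = np.ones((4, 6, 6), dtype=bool)
        axes = pca_axes_3d(VoxelGrid(occ, 1.0, 3.0))  # z extent 4*3 = 12 mm
        assert axes.A == pytest.approx(12.0)
        assert axes.B == pytest.approx(6.0)

    def test_90_degree_lattice_rotation_invariance(self):
        occ = np.zeros((10, 16, 24), dtype=bool)
        occ[1:9, 2:14, 3:21] = True
        a0 = pca_axes_3d(VoxelGrid(occ, 1.0, 1.0))
        a1 = pca_axes_3d(VoxelGrid(np.rot90(occ, axes=(1, 2)).copy(), 1.0, 1.0))
        assert a0.A == pytest.approx(a1.A, abs=1.0)
        assert a0.B == pytest.approx(a1.B, abs=1.0)
        assert a0.C == pytest.approx(a1.C, abs=1.0)


class TestAbcOver2:
    def test_cube_of_diameters(self):
        from hemovol.volumetry import PrincipalAxes

        axes = PrincipalAxes(20, 20, 20, np.eye(3), np.zeros(3))
        assert abc_over_2(axes).volume_cm3 == pytest.approx(4.0)
        axes = PrincipalAxes(40, 20, 10, np.eye(3), np.zeros(3))
        assert abc_over_2(axes).volume_cm3 == pytest.approx(4.0)

    def test_sphere_ratio_is_3_over_pi(self):
        # ABC/2 on a perfect sphere of diameter d is d^3/2; truth is pi d^3/6
        d = 30.0
        ratio = (d**3 / 2) / (np.pi * d**3 / 6)
        assert ratio == pytest.approx(3 / np.pi)
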