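import numpy as np
import pytest

from vascatlas import (BinaryMask, centerline_radii, expand_radius, make_grid,
                       skeletonize)
from vascatlas.radius_quant import CenterlineSet, radius_map_from_mask

from conftest import digital_cylinder


def brute_force_radius(mask, spacing):
    """Oracle: per in-mask voxel, min mm distance over all background voxels."""
    spacing = np.asarray(spacing, float)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = {}
    for v in fg:
        d = np.sqrt((((bg - v) * spacing) ** 2).sum(axis=1))
        out[tuple(v)] = d.min()
    return out


def brute_force_expand(indices, radii, shape, spacing, max_dist):
    """Oracle: exhaustive nearest-centerline search, lowest-flat-index ties.

    Mathematical ties surface as float distances equal to ~1e-16 relative,
    so tie detection uses a 1e-9 relative tolerance before picking the
    lowest flattened index.
    """
    spacing = np.asarray(spacing, float)
    order = np.argsort(np.ravel_multi_index(indices.T, shape))
    indices, radii = indices[order], radii[order]
    out = np.zeros(shape)
    for v in np.ndindex(shape):
        d2 = ((((indices - np.asarray(v)) * spacing) ** 2).sum(axis=1))
        dmin2 = d2.min()
        j = int(np.argmax(d2 <= dmin2 * (1.0 + 2e-9) + 1e-18))
        if np.sqrt(dmin2) <= max_dist + 1e-12:
            out[v] = radii[j]
    return out


class TestSkeletonize:
    def test_single_voxel_object(self):
        m = np.zeros((8, 8, 8), bool)
        m[4, 4, 4] = True
        c = skeletonize(BinaryMask(m, np.eye(4)))
        assert len(c) == 1
        assert tuple(c.indices[0]) == (4, 4, 4)

    def test_cylinder_skeleton_on_axis(self):
        m = digital_cylinder((24, 24, 24), (12, 12), 3.0)
        c = skeletonize(BinaryMask(m, np.eye(4)))
        assert len(c) > 0
        assert np.all(m[tuple(c.indices.T)])          # skeleton subset of mask
        in_plane = np.abs(c.indices[:, :2] - 12)
        assert np.all(in_plane <= 1)                  # within 1 voxel of axis

    def test_two_tubes_two_components(self):
        from scipy import ndimage as ndi

        m = digital_cylinder((24, 24, 24), (6, 6), 2.0) \
            | digital_cylinder((24, 24, 24), (17, 17), 2.0)
        c = skeletonize(BinaryMask(m, np.eye(4)))
        _, n = ndi.label(c.mask(), structure=np.ones((3, 3, 3)))
        assert n == 2

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            c = skeletonize(BinaryMask(np.zeros((6, 6, 6), bool), np.eye(4)))
        assert len(c) == 0


class TestCenterlineRadii:
    def test_isolated_voxel_radius_one(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        mask = BinaryMask(m, np.eye(4))
        c = centerline_radii(mask, skeletonize(mask))
        assert c.radii_mm[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_cylinder_radii_vs_brute_force(self, r):
        shape = (2 * r + 6,) * 2 + (10,)
        m = digital_cylinder(shape, (r + 3, r + 3), float(r))
        mask = BinaryMask(m, np.eye(4))
        c = centerline_radii(mask, skeletonize(mask))
        oracle = brute_force_radius(m, (1, 1, 1))
        for idx, rad in zip(map(tuple, c.indices), c.radii_mm):
            assert rad == pytest.approx(oracle[idx], abs=1e-9)
        axis = np.abs(c.indices[:, :2] - (r + 3)).max(axis=1) == 0
        if axis.any():
            assert np.all(np.abs(c.radii_mm[axis] - r) <= 0.5 + 1e-9)

    def test_anisotropic_slab(self):
        # slab of half-thickness 2 voxels along z with 1.0 mm z-spacing:
        # the radius must be ~2 * 1.0 mm, not 2 * 0.5 mm
        m = np.zeros((16, 16, 9), bool)
        m[:, :, 2:7] = True
        aff = np.diag([0.5, 0.5, 1.0, 1.0])
        mask = BinaryMask(m, aff)
        c = CenterlineSet(np.array([[8, 8, 4]]), m.shape, aff)
        c = centerline_radii(mask, c)
        oracle = brute_force_radius(m, (0.5, 0.5, 1.0))
        assert c.radii_mm[0] == pytest.approx(oracle[(8, 8, 4)], abs=1e-9)
        assert c.radii_mm[0] == pytest.approx(3.0, abs=1e-9)  # 3 z-steps to bg

    def test_skeleton_outside_mask_rejected(self):
        m = np.zeros((6, 6, 6), bool)
        m[2, 2, 2] = True
        c = CenterlineSet(np.array([[4, 4, 4]]), m.shape, np.eye(4))
        with pytest.raises(ValueError, match="outside mask"):
            centerline_radii(BinaryMask(m, np.eye(4)), c)


class TestExpandRadius:
    def test_single_site_sphere(self):
        shape = (15, 15, 15)
        c = CenterlineSet(np.array([[7, 7, 7]]), shape, np.eye(4),
                          radii_mm=np.array([1.2]))
        rm = expand_radius(c, max_dist_mm=5.0)
        ii, jj, kk = np.meshgrid(*(np.arange(15),) * 3, indexing="ij")
        d = np.sqrt((ii - 7) ** 2 + (jj - 7) ** 2 + (kk - 7) ** 2)
        assert np.all(rm.data[d <= 5.0] == 1.2)
        assert np.all(rm.data[d > 5.0] == 0.0)

    def test_two_parallel_tubes_no_blending(self):
        # radii 1.0 and 3.0 mm, axes 6 mm apart: values stay {0, 1.0, 3.0}
        shape = (20, 20, 12)
        idx = [[7, y, z] for y in range(3, 17) for z in [5]] \
            + [[13, y, z] for y in range(3, 17) for z in [5]]
        idx = np.array([[7, 10, z] for z in range(2, 10)]
                       + [[13, 10, z] for z in range(2, 10)])
        radii = np.array([1.0] * 8 + [3.0] * 8)
        c = CenterlineSet(idx, shape, np.eye(4), radii_mm=radii)
        rm = expand_radius(c, max_dist_mm=5.0)
        assert set(np.unique(rm.data)) == {0.0, 1.0, 3.0}
        oracle = brute_force_expand(idx, radii, shape, (1, 1, 1), 5.0)
        assert np.array_equal(rm.data, oracle)
        # mid-plane voxels split between the tubes by the tie-break
        assert rm.data[9, 10, 5] == 1.0 and rm.data[11, 10, 5] == 3.0

    def test_tapering_tube_preserves_profile(self):
        shape = (12, 12, 24)
        zs = np.arange(3, 21)
        idx = np.array([[6, 6, z] for z in zs])
        radii = np.linspace(3.0, 1.0, len(zs))
        c = CenterlineSet(idx, shape, np.eye(4), radii_mm=radii)
        rm = expand_radius(c, max_dist_mm=5.0)
        oracle = brute_force_expand(idx, radii, shape, (1, 1, 1), 5.0)
        assert np.array_equal(rm.data, oracle)
        prof = rm.data[6, 6, 3:21]
        assert np.all(np.diff(prof) <= 1e-12)     # non-increasing along axis

    def test_exact_match_random_centerlines(self, rng):
        shape = (16, 16, 16)
        spacing = (0.7, 0.7, 1.1)
        aff = np.diag(list(spacing) + [1.0])
        n = 12
        idx = rng.integers(0, 16, size=(n, 3))
        idx = np.unique(idx, axis=0)
        radii = rng.uniform(0.5, 3.0, len(idx))
        c = CenterlineSet(idx, shape, aff, radii_mm=radii)
        # CenterlineSet sorts by flat index; align the oracle's inputs
        rm = expand_radius(c, max_dist_mm=5.0)
        oracle = brute_force_expand(c.indices, c.radii_mm, shape, spacing, 5.0)
        assert np.array_equal(rm.data, oracle)

    def test_no_new_values_created(self, rng):
        shape = (20, 20, 20)
        idx = rng.integers(2, 18, size=(15, 3))
        idx = np.unique(idx, axis=0)
        radii = rng.uniform(0.5, 4.0, len(idx))
        c = CenterlineSet(idx, shape, np.eye(4), radii_mm=radii)
        rm = expand_radius(c, max_dist_mm=5.0)
        vals = set(np.unique(rm.data)) - {0.0}
        assert vals <= set(radii.tolist())

    def test_unset_radii_rejected(self):
        c = CenterlineSet(np.array([[2, 2, 2]]), (6, 6, 6), np.eye(4))
        with pytest.raises(ValueError, match="unset"):
            expand_radius(c)


class TestEndToEnd:
    def test_radius_recovery_rmse(self):
        """RMSE of centerline radius over cylinders r=1..4 voxels <= 0.5."""
        errs = []
        for r in (1, 2, 3, 4):
            shape = (2 * r + 8,) * 2 + (12,)
            m = digital_cylinder(shape, (r + 4, r + 4), float(r))
            mask = BinaryMask(m, np.eye(4))
            c = centerline_radii(mask, skeletonize(mask))
            errs.extend((c.radii_mm - r).tolist())
        assert np.sqrt(np.mean(np.square(errs))) <= 0.5

    def test_support_covers_mask_near_skeleton(self):
        m = digital_cylinder((20, 20, 12), (10, 10), 3.0)
        mask = BinaryMask(m, np.eye(4))
        rm = radius_map_from_mask(mask)
        assert np.all(rm.data[m] > 0)     # tube radius << 5 mm expansion
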