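import numpy as np
import pytest

from vascatlas import (AtlasAccumulator, BinaryMask, VolumeImage, accumulate,
                       apply_exclusion_mask, finalize, make_grid)
from vascatlas.radius_quant import RadiusMap

SHAPE = (12, 12, 12)


def full_mask(grid):
    return BinaryMask(np.ones(SHAPE, bool), grid.affine.copy())


def subject(grid, rng=None, cov=None, seg=None, rad=None, intensity=50.0):
    cov = np.ones(SHAPE, bool) if cov is None else cov
    seg = np.zeros(SHAPE, bool) if seg is None else seg
    rad = np.zeros(SHAPE) if rad is None else rad
    tof = VolumeImage(np.full(SHAPE, intensity), grid.affine.copy(),
                      coverage=cov)
    return tof, BinaryMask(seg, grid.affine.copy()), \
        RadiusMap(rad, grid.affine.copy())


class TestAccumulate:
    def test_all_false_coverage_no_influence(self, small_grid):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        tof, seg, rad = subject(grid, cov=np.zeros(SHAPE, bool))
        accumulate(acc, tof, seg, rad)
        assert acc.n_cov.sum() == 0 and acc.sum_int.sum() == 0

    def test_single_vessel_voxel(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        seg = np.zeros(SHAPE, bool)
        rad = np.zeros(SHAPE)
        seg[3, 3, 3] = True
        rad[3, 3, 3] = 2.0
        accumulate(acc, *subject(grid, seg=seg, rad=rad))
        assert acc.n_rad[3, 3, 3] == 1
        assert acc.sum_rad[3, 3, 3] == 2.0
        assert acc.sum_rad_sq[3, 3, 3] == 4.0

    def test_order_invariance(self, rng):
        grid = make_grid(SHAPE, (1, 1, 1))
        subjects = []
        for _ in range(5):
            seg = rng.random(SHAPE) < 0.2
            rad = np.where(seg, rng.uniform(0.5, 3, SHAPE), 0.0)
            cov = rng.random(SHAPE) < 0.8
            subjects.append(subject(grid, cov=cov, seg=seg, rad=rad,
                                    intensity=float(rng.uniform(10, 90))))
        acc1 = AtlasAccumulator(grid)
        acc2 = AtlasAccumulator(grid)
        for s in subjects:
            accumulate(acc1, *s)
        for s in reversed(subjects):
            accumulate(acc2, *s)
        for f in ("n_cov", "n_seg", "n_rad"):
            assert np.array_equal(getattr(acc1, f), getattr(acc2, f))
        for f in ("sum_int", "sum_rad", "sum_rad_sq"):
            assert np.allclose(getattr(acc1, f), getattr(acc2, f), rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        other = make_grid(SHAPE, (0.5, 0.5, 0.5))
        acc = AtlasAccumulator(grid)
        with pytest.raises(ValueError, match="grid"):
            accumulate(acc, *subject(other))


class TestFinalize:
    def test_identical_subjects_probability_100_std_0(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        seg = np.zeros(SHAPE, bool)
        rad = np.zeros(SHAPE)
        seg[4:6, 4:6, 4:6] = True
        rad[4:6, 4:6, 4:6] = 1.5
        for _ in range(4):
            accumulate(acc, *subject(grid, seg=seg, rad=rad))
        bundle = finalize(acc, full_mask(grid))
        assert np.all(bundle.probability.data[seg] == 100.0)
        assert np.all(bundle.std_radius.data == 0.0)
        assert np.all(bundle.mean_radius.data[seg] == 1.5)

    def test_half_coverage_probability_50(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        seg = np.zeros(SHAPE, bool)
        seg[5, 5, 5] = True
        cov = np.ones(SHAPE, bool)
        nocov = np.zeros(SHAPE, bool)
        accumulate(acc, *subject(grid, cov=cov, seg=seg))       # covered, vessel
        accumulate(acc, *subject(grid, cov=cov))                # covered, none
        accumulate(acc, *subject(grid, cov=nocov))              # uncovered
        accumulate(acc, *subject(grid, cov=nocov))              # uncovered
        bundle = finalize(acc, full_mask(grid))
        assert bundle.probability.data[5, 5, 5] == pytest.approx(50.0)

    def test_radii_2_0_4_mean_3_std_1(self):
        # radii {2, 0, 4} across three covering subjects: the 0 is excluded,
        # mean = 3.0 and population std = 1.0
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        for r in (2.0, 0.0, 4.0):
            rad = np.zeros(SHAPE)
            rad[6, 6, 6] = r
            accumulate(acc, *subject(grid, rad=rad))
        bundle = finalize(acc, full_mask(grid))
        assert bundle.mean_radius.data[6, 6, 6] == pytest.approx(3.0)
        assert bundle.std_radius.data[6, 6, 6] == pytest.approx(1.0)

    def test_streaming_equals_batch(self, rng):
        """Streaming sufficient statistics == stacking subjects in memory."""
        grid = make_grid((48, 48, 48), (1, 1, 1))
        n = 20
        shape = (48, 48, 48)
        acc = AtlasAccumulator(grid)
        tofs, covs, segs, rads = [], [], [], []
        for _ in range(n):
            cov = rng.random(shape) < 0.9
            seg = rng.random(shape) < 0.1
            rad = np.where(rng.random(shape) < 0.15,
                           rng.uniform(0.5, 4.0, shape), 0.0)
            tof = rng.uniform(0, 100, shape)
            tofs.append(tof); covs.append(cov); segs.append(seg); rads.append(rad)
            accumulate(acc,
                       VolumeImage(tof, grid.affine.copy(), coverage=cov),
                       BinaryMask(seg, grid.affine.copy()),
                       RadiusMap(rad, grid.affine.copy()))
        bundle = finalize(acc, BinaryMask(np.ones(shape, bool),
                                          grid.affine.copy()))

        tofs, covs = np.array(tofs), np.array(covs)
        segs, rads = np.array(segs), np.array(rads)
        n_cov = covs.sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tof_avg = np.where(n_cov > 0,
                               (tofs * covs).sum(0) / n_cov, 0.0)
            prob = np.where(n_cov > 0,
                            100.0 * (segs & covs).sum(0) / n_cov, 0.0)
            has = covs & (rads > 0)
            n_rad = has.sum(0)
            mean_r = np.where(n_rad > 0,
                              np.where(has, rads, 0).sum(0)
                              / np.maximum(n_rad, 1), 0.0)
            # batch oracle: literal second pass over squared differences
            sq_diff = np.where(has, (rads - mean_r[None]) ** 2, 0.0).sum(0)
            std_r = np.where(n_rad > 0,
                             np.sqrt(sq_diff / np.maximum(n_rad, 1)), 0.0)
        std_r = np.where(n_rad > 1, std_r, 0.0)

        assert np.array_equal(bundle.n_cov.data, n_cov.astype(float))
        assert np.allclose(bundle.tof_average.data, tof_avg, rtol=1e-6)
        assert np.allclose(bundle.probability.data, prob, rtol=1e-6)
        assert np.allclose(bundle.mean_radius.data, mean_r, rtol=1e-6)
        assert np.allclose(bundle.std_radius.data, std_r, rtol=1e-6,
                           atol=1e-7)

    def test_probability_times_ncov_is_integer(self, rng):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        for _ in range(7):
            accumulate(acc, *subject(
                grid, cov=rng.random(SHAPE) < 0.7,
                seg=rng.random(SHAPE) < 0.3))
        bundle = finalize(acc, full_mask(grid))
        counts = bundle.probability.data * bundle.n_cov.data / 100.0
        assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_masked_outside_brain(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        seg = np.ones(SHAPE, bool)
        rad = np.ones(SHAPE)
        accumulate(acc, *subject(grid, seg=seg, rad=rad))
        brain = np.zeros(SHAPE, bool)
        brain[3:9, 3:9, 3:9] = True
        bundle = finalize(acc, BinaryMask(brain, grid.affine.copy()))
        assert np.all(bundle.probability.data[~brain] == 0)
        assert np.all(bundle.mean_radius.data[~brain] == 0)
        assert np.all(bundle.tof_average.data[~brain] == 0)

    def test_empty_accumulator_warns(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        with pytest.warns(UserWarning, match="empty"):
            bundle = finalize(acc, full_mask(grid))
        assert np.all(bundle.probability.data == 0)


class TestExclusionMask:
    def make_bundle(self):
        grid = make_grid(SHAPE, (1, 1, 1))
        acc = AtlasAccumulator(grid)
        seg = np.zeros(SHAPE, bool)
        seg[2:6, 2:6, 2:6] = True
        seg[8:10, 8:10, 8:10] = True
        accumulate(acc, *subject(grid, seg=seg))
        return finalize(acc, full_mask(grid)), grid

    def test_empty_exclusion_no_change(self):
        bundle, grid = self.make_bundle()
        out = apply_exclusion_mask(
            bundle, BinaryMask(np.zeros(SHAPE, bool), grid.affine.copy()))
        assert np.array_equal(out.probability.data, bundle.probability.data)

    def test_full_exclusion_zeroes_probability(self):
        bundle, grid = self.make_bundle()
        out = apply_exclusion_mask(
            bundle, BinaryMask(np.ones(SHAPE, bool), grid.affine.copy()))
        assert np.all(out.probability.data == 0)

    def test_region_exclusion_conserves_rest(self):
        bundle, grid = self.make_bundle()
        excl = np.zeros(SHAPE, bool)
        excl[8:10, 8:10, 8:10] = True
        before = bundle.probability.data.sum()
        region = bundle.probability.data[excl].sum()
        out = apply_exclusion_mask(bundle,
                                   BinaryMask(excl, grid.affine.copy()))
        assert out.probability.data.sum() == pytest.approx(before - region)


def test_bundle_save_canonical_files(tmp_path):
    grid = make_grid(SHAPE, (1, 1, 1))
    acc = AtlasAccumulator(grid)
    accumulate(acc, *subject(grid))
    bundle = finalize(acc, full_mask(grid))
    paths = bundle.save(tmp_path)
    import os

    for fname in ("tofAverage.nii.gz", "vesselProbabilities.nii.gz",
                  "vesselRadius.nii.gz", "vesselRadiusStd.nii.gz",
                  "nCoverage.nii.gz"):
        assert os.path.exists(tmp_path / fname)
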