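"""Coverage-aware streaming accumulation of registered subjects into atlases.

Four atlas volumes are built on the reference grid from each subject's
registered TOF intensity, binary artery segmentation and expanded radius
map:

* ``tof_average`` — mean TOF intensity over the subjects *covering* each
  voxel (voxels outside a subject's field of view never enter the mean);
* ``probability`` — artery occurrence probability in percent:
  100 x (number of covering subjects with segmentation = 1) / (number of
  covering subjects);
* ``mean_radius`` — mean of the positive radius values over subjects,
  in mm (zeros excluded: the expansion step exists precisely so that
  rarely-visited voxels still collect radius evidence);
* ``std_radius`` — population standard deviation (divide-by-n) of those
  same positive radius values, in mm.

Accumulation is streaming via per-voxel sufficient statistics
(n, sum, sum of squares), equivalent to stacking all subjects in memory;
order of accumulation is irrelevant. A brain mask zeroes all four
volumes outside the brain to remove border artefacts, and an optional
exclusion mask removes known non-arterial structures (e.g. venous sinus)
from the probability atlas.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .imgvol import BinaryMask, VolumeImage, require_same_grid, save_volume
from .radius_quant import RadiusMap

__all__ = ["AtlasAccumulator", "AtlasBundle", "accumulate", "finalize",
           "apply_exclusion_mask"]

CANONICAL_FILES = {
    "tof_average": "tofAverage.nii.gz",
    "probability": "vesselProbabilities.nii.gz",
    "mean_radius": "vesselRadius.nii.gz",
    "std_radius": "vesselRadiusStd.nii.gz",
    "n_cov": "nCoverage.nii.gz",
}


@dataclass
class AtlasAccumulator:
    """Per-voxel sufficient statistics over the accumulated subjects."""

    grid: VolumeImage
    n_cov: np.ndarray = field(init=False)
    sum_int: np.ndarray = field(init=False)
    n_seg: np.ndarray = field(init=False)
    n_rad: np.ndarray = field(init=False)
    sum_rad: np.ndarray = field(init=False)
    sum_rad_sq: np.ndarray = field(init=False)
    n_subjects: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        shape = self.grid.data.shape
        self.n_cov = np.zeros(shape, dtype=np.int64)
        self.sum_int = np.zeros(shape, dtype=np.float64)
        self.n_seg = np.zeros(shape, dtype=np.int64)
        self.n_rad = np.zeros(shape, dtype=np.int64)
        self.sum_rad = np.zeros(shape, dtype=np.float64)
        self.sum_rad_sq = np.zeros(shape, dtype=np.float64)


@dataclass
class AtlasBundle:
    """The four finalized atlas volumes plus coverage count and brain mask."""

    tof_average: VolumeImage
    probability: VolumeImage        # percent, 0-100
    mean_radius: VolumeImage        # mm
    std_radius: VolumeImage         # mm
    n_cov: VolumeImage
    brain_mask: BinaryMask

    def save(self, out_dir: str | os.PathLike) -> dict:
        """Write the canonical atlas files; returns name -> path."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for attr, fname in CANONICAL_FILES.items():
            path = os.path.join(str(out_dir), fname)
            save_volume(getattr(self, attr), path)
            paths[attr] = path
        return paths


def accumulate(acc: AtlasAccumulator, tof: VolumeImage, seg: BinaryMask,
               rad: RadiusMap) -> AtlasAccumulator:
    """Add one registered subject to the accumulator (in place).

    Counters update only where the subject's coverage is true; the radius
    statistics additionally require a positive radius at the voxel.
    """
    require_same_grid(acc.grid, tof, "accumulator grid and TOF")
    require_same_grid(acc.grid, seg, "accumulator grid and segmentation")
    require_same_grid(acc.grid, rad, "accumulator grid and radius map")
    cov = tof.coverage_or_full()
    acc.n_cov += cov
    acc.sum_int += np.where(cov, tof.data, 0.0)
    acc.n_seg += cov & seg.data
    has_rad = cov & (rad.data > 0)
    acc.n_rad += has_rad
    acc.sum_rad += np.where(has_rad, rad.data, 0.0)
    acc.sum_rad_sq += np.where(has_rad, rad.data ** 2, 0.0)
    acc.n_subjects += 1
    return acc


def finalize(acc: AtlasAccumulator, brain_mask: BinaryMask) -> AtlasBundle:
    """Turn accumulated statistics into the four atlas volumes.

    Ratios are taken only where their denominator is positive (elsewhere
    0); the standard deviation uses the population (divide-by-n)
    convention over the same subject set as the mean — subjects with a
    positive radius at the voxel. All volumes are zeroed outside the
    brain mask.
    """
    require_same_grid(acc.grid, brain_mask, "accumulator grid and brain mask")
    if not (acc.n_cov > 0).any():
        warnings.warn("empty accumulator: all-zero atlas bundle", stacklevel=2)
    mask = brain_mask.data

    with np.errstate(divide="ignore", invalid="ignore"):
        tof_avg = np.where(acc.n_cov > 0, acc.sum_int / acc.n_cov, 0.0)
        prob = np.where(acc.n_cov > 0, 100.0 * acc.n_seg / acc.n_cov, 0.0)
        mean_rad = np.where(acc.n_rad > 0, acc.sum_rad / acc.n_rad, 0.0)
        var = np.where(acc.n_rad > 0,
                       acc.sum_rad_sq / acc.n_rad - mean_rad ** 2, 0.0)
    std_rad = np.sqrt(np.maximum(var, 0.0))
    std_rad[acc.n_rad <= 1] = 0.0

    def vol(arr):
        return VolumeImage(np.where(mask, arr, 0.0), acc.grid.affine.copy())

    return AtlasBundle(
        tof_average=vol(tof_avg),
        probability=vol(prob),
        mean_radius=vol(mean_rad),
        std_radius=vol(std_rad),
        n_cov=vol(acc.n_cov.astype(float)),
        brain_mask=BinaryMask(mask.copy(), acc.grid.affine.copy()),
    )


def apply_exclusion_mask(bundle: AtlasBundle, excl: BinaryMask,
                         also_radius: bool = False) -> AtlasBundle:
    """Zero the probability atlas (optionally radii too) inside a region.

    Used to remove structures that are not arteries in part of the cohort
    (the venous sinus being the classic case).
    """
    require_same_grid(bundle.probability, excl, "bundle and exclusion mask")
    keep = ~excl.data

    def masked(v: VolumeImage) -> VolumeImage:
        return VolumeImage(np.where(keep, v.data, 0.0), v.affine.copy())

    return AtlasBundle(
        tof_average=bundle.tof_average,
        probability=masked(bundle.probability),
        mean_radius=masked(bundle.mean_radius) if also_radius
        else bundle.mean_radius,
        std_radius=masked(bundle.std_radius) if also_radius
        else bundle.std_radius,
        n_cov=bundle.n_cov,
        brain_mask=bundle.brain_mask,
    )
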