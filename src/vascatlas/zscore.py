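"""Voxel-wise z-score mapping against the atlas, and ROI radius statistics.

A new subject's expanded radius map is compared voxel-by-voxel with the
normative atlas:

    Z_i = (x_i - mu_i) / sigma_i

where x_i is the subject's radius, and mu_i / sigma_i are the atlas mean
and standard deviation of the radius at voxel i. Positive Z flags a
locally dilated vessel, negative Z a narrowed one. Z is computed only on
the *support*: voxels where the subject has a vessel (x > 0), the atlas
has radius evidence (mu > 0) and the occurrence probability clears a
minimum gate; sigma is floored to avoid division by near-zero standard
deviations at rarely-visited voxels. The formula is pointwise, so the
comparison works in either direction — subject warped into atlas space,
or atlas warped onto the subject.

ROI statistics summarize per-artery mean radii across a cohort (the
numeric substrate of violin-plot validation): per subject x ROI, the
mean of positive radii inside the ROI; a subject without vessel voxels
in an ROI is recorded as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_build import AtlasBundle
from .imgvol import BinaryMask, require_same_grid
from .radius_quant import RadiusMap

__all__ = ["ZScoreMap", "RoiDefinition", "zscore", "roi_statistics",
           "plot_zscore_mip"]

DEFAULT_SIGMA_FLOOR_MM = 0.05
DEFAULT_MIN_PROB_PCT = 1.0


@dataclass
class ZScoreMap:
    """Unitless z values on the support of valid vessel voxels."""

    data: np.ndarray
    support_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data[self.support_mask])):
            raise ValueError("z-scores must be finite on support")

    @property
    def support_values(self) -> np.ndarray:
        return self.data[self.support_mask]


@dataclass
class RoiDefinition:
    """Named artery region of interest on the atlas grid."""

    name: str
    mask: BinaryMask

    def __post_init__(self) -> None:
        if not self.mask.data.any():
            raise ValueError(f"ROI {self.name!r} has an empty mask")


def zscore(subject_rad: RadiusMap, atlas: AtlasBundle,
           sigma_floor_mm: float = DEFAULT_SIGMA_FLOOR_MM,
           min_prob_pct: float = DEFAULT_MIN_PROB_PCT) -> ZScoreMap:
    """Voxel-wise z-score of a subject radius map against the atlas.

    ``Z = (x - mu) / max(sigma, sigma_floor)`` on voxels with ``x > 0``,
    ``mu > 0`` and ``probability >= min_prob_pct``; everything else is
    outside the support (value 0, support False).
    """
    require_same_grid(subject_rad, atlas.mean_radius, "subject and atlas")
    x = subject_rad.data
    mu = atlas.mean_radius.data
    sigma = atlas.std_radius.data
    if sigma_floor_mm <= 0 and not (sigma > 0).any():
        raise ValueError(
            "atlas sigma is zero everywhere and sigma_floor_mm is not "
            "positive; set a positive floor (e.g. 0.05 mm)")
    support = (x > 0) & (mu > 0) & (atlas.probability.data >= min_prob_pct)
    denom = np.maximum(sigma, sigma_floor_mm)
    z = np.zeros_like(x, dtype=float)
    z[support] = (x[support] - mu[support]) / denom[support]
    return ZScoreMap(z, support, subject_rad.affine.copy())


def roi_statistics(subject_rads, rois,
                   subject_ids=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject per-ROI mean radius table plus cohort summaries.

    Parameters
    ----------
    subject_rads : sequence of RadiusMap
        Expanded radius maps, all on the atlas grid.
    rois : sequence of RoiDefinition
    subject_ids : sequence of str, optional

    Returns
    -------
    per_subject : DataFrame
        Columns ``subject``, one column per ROI name with the mean of the
        positive radii inside the ROI (NaN where the subject has no
        vessel voxel there).
    summary : DataFrame
        Per ROI: n, mean, std, quartiles of the per-subject means.
    """
    rois = list(rois)
    subject_rads = list(subject_rads)
    if subject_ids is None:
        subject_ids = [f"subject_{i:03d}" for i in range(len(subject_rads))]
    for rad in subject_rads:
        require_same_grid(rad, rois[0].mask, "radius map and ROI")
    rows = []
    for sid, rad in zip(subject_ids, subject_rads):
        row = {"subject": sid}
        for roi in rois:
            vals = rad.data[roi.mask.data]
            vals = vals[vals > 0]
            row[roi.name] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    summary = (per_subject.drop(columns="subject")
               .describe(percentiles=[0.25, 0.5, 0.75])
               .T.rename_axis("roi").reset_index())
    summary["count"] = summary["count"].astype(int)
    return per_subject, summary


def plot_zscore_mip(zmap: ZScoreMap, axis: int = 2, ax=None):
    """Maximum-intensity projection of |Z| — a quick-look rendering helper."""
    import matplotlib.pyplot as plt

    mip = np.abs(np.where(zmap.support_mask, zmap.data, 0.0)).max(axis=axis)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(mip.T, origin="lower", cmap="hot")
    ax.set_title("max-intensity projection of |Z|")
    plt.colorbar(im, ax=ax, label="|Z|")
    return ax
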