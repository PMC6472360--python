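"""Volumetric data model and NIfTI I/O shared by all pipeline stages.

The package works on 3D scalar grids with a voxel-to-world affine in mm
(RAS orientation). Voxel indexing is 0-based with voxel *centers* at
integer indices; all physical distances are computed in mm using the
per-axis voxel spacing, which is derived from the affine. An optional
per-subject *coverage* mask marks voxels inside the acquired field of
view — voxels outside coverage must never enter any population average.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "load_volume",
    "save_volume",
    "world_to_voxel",
    "voxel_to_world",
    "grids_match",
]


def _validate_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
        raise ValueError("affine last row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("non-invertible affine")
    return affine


@dataclass
class VolumeImage:
    """3D scalar grid + affine (mm, RAS) + optional acquisition coverage.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar image values (float).
    affine : ndarray, shape (4, 4)
        Voxel-to-world matrix in mm; last row (0, 0, 0, 1).
    coverage : ndarray of bool, optional
        True where the voxel lies inside the subject's acquired field of
        view. ``None`` means fully covered.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D image: ndim={self.data.ndim}")
        self.affine = _validate_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=bool)
            if self.coverage.shape != self.data.shape:
                raise ValueError(
                    "coverage shape "
                    f"{self.coverage.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine columns."""
        return np.sqrt((np.asarray(self.affine, float)[:3, :3] ** 2).sum(axis=0))

    def coverage_or_full(self) -> np.ndarray:
        if self.coverage is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.coverage

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same grid/affine/coverage, new voxel values."""
        return VolumeImage(np.asarray(data), self.affine.copy(),
                           None if self.coverage is None else self.coverage.copy())


@dataclass
class BinaryMask:
    """Boolean 3D mask on the same grid conventions as :class:`VolumeImage`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"non-3D mask: ndim={arr.ndim}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be restricted to {0, 1}")
            arr = arr.astype(bool)
        self.data = arr
        self.affine = _validate_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((np.asarray(self.affine, float)[:3, :3] ** 2).sum(axis=0))


def load_volume(path: str | os.PathLike, derive_coverage: bool = False) -> VolumeImage:
    """Load a 3D NIfTI-1 volume (optionally gzipped).

    Parameters
    ----------
    path : path-like
        Existing ``.nii`` / ``.nii.gz`` file.
    derive_coverage : bool
        If True, derive the coverage mask as ``data > 0``. By default no
        coverage is derived — acquisition coverage is an explicit input.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has shape {data.shape}")
    vol = VolumeImage(np.asarray(data, dtype=np.float64), np.asarray(img.affine))
    if derive_coverage:
        vol.coverage = vol.data > 0
    return vol


def save_volume(v: VolumeImage | BinaryMask, path: str | os.PathLike) -> None:
    """Write as float32 NIfTI-1 (gzipped when the name ends ``.nii.gz``)."""
    data = np.asarray(v.data, dtype=np.float32)
    img = nib.Nifti1Image(data, np.asarray(v.affine, dtype=np.float64))
    img.header.set_data_dtype(np.float32)
    directory = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(directory) or not os.access(directory, os.W_OK):
        raise OSError(f"unwritable destination: {path}")
    nib.save(img, str(path))


def voxel_to_world(v: VolumeImage | BinaryMask | np.ndarray, ijk) -> np.ndarray:
    """Map continuous voxel indices to world mm via the affine.

    Accepts a single 3-vector or an (N, 3) array.
    """
    affine = v if isinstance(v, np.ndarray) else v.affine
    pts = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = pts @ affine[:3, :3].T + affine[:3, 3]
    return out[0] if np.asarray(ijk).ndim == 1 else out


def world_to_voxel(v: VolumeImage | BinaryMask | np.ndarray, xyz_mm) -> np.ndarray:
    """Map world mm coordinates to continuous voxel indices (inverse affine)."""
    affine = v if isinstance(v, np.ndarray) else v.affine
    inv = np.linalg.inv(np.asarray(affine, float))
    pts = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(xyz_mm).ndim == 1 else out


def grids_match(a, b, atol: float = 1e-6) -> bool:
    """Same shape and same affine within tolerance."""
    return a.data.shape == b.data.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(a, b, what: str = "inputs") -> None:
    if not grids_match(a, b):
        raise ValueError(f"grid mismatch between {what}: "
                         f"shapes {a.data.shape} vs {b.data.shape}")


def make_grid(shape, spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> VolumeImage:
    """Convenience: an all-zero volume with a diagonal RAS affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(spacing_mm, dtype=float))
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    return VolumeImage(np.zeros(tuple(shape), dtype=np.float64), affine)
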