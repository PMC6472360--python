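"""Transforms, composition and resampling into a common atlas grid.

Transforms map world points (mm) to world points and are stored
*target-to-source*: a chain attached to a subject maps atlas-space
points back into subject space, so pull-resampling onto the atlas grid
is direct. Rigid matrices and dense displacement fields compose freely;
a chain is applied as a single composed mapping, so the image itself is
interpolated exactly once — concatenating the rigid (TOF -> T1) and
non-linear (T1 -> atlas) stages avoids double interpolation errors.

Interpolation discipline: segmentations and radius maps are resampled
with nearest-neighbour only (enforced), so no values absent from the
source are ever created and vessel information is never falsely
smoothed; intensity volumes use linear interpolation.

Registration *estimation* is a pluggable backend (the shipped oracle
backend returns known ground-truth transforms for phantom cohorts; a
thin SimpleITK adapter is provided for real images). Only transform
application and composition are implemented here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imgvol import BinaryMask, VolumeImage, voxel_to_world, world_to_voxel
from .radius_quant import RadiusMap

__all__ = [
    "RigidTransform",
    "DisplacementField",
    "TransformChain",
    "compose",
    "resample",
    "register",
    "REGISTRATION_BACKENDS",
]


@dataclass
class RigidTransform:
    """4x4 world-to-world rigid matrix (rotation + translation, mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid matrix must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must have det +1 (no reflection)")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_euler(cls, angles_deg=(0.0, 0.0, 0.0),
                   translation_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        ax, ay, az = np.deg2rad(angles_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = np.eye(4)
        m[:3, :3] = Rz @ Ry @ Rx
        m[:3, 3] = translation_mm
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def save(self, path: str | os.PathLike) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RigidTransform":
        return cls(np.loadtxt(path))


@dataclass
class DisplacementField:
    """Dense displacement field u(x) in mm on its own named grid.

    A world point x maps to ``x + u(x)``; u is stored as a 3-channel array
    on the field grid and looked up between nodes by trilinear
    interpolation of the vectors (edge values extend beyond the grid).
    """

    vectors: np.ndarray                 # (nx, ny, nz, 3) mm
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx,ny,nz,3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite everywhere")
        self.affine = np.asarray(self.affine, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        vox = world_to_voxel(self.affine, pts)
        coords = np.atleast_2d(vox).T
        u = np.stack(
            [ndi.map_coordinates(self.vectors[..., k], coords, order=1,
                                 mode="nearest") for k in range(3)],
            axis=-1,
        )
        out = pts + u
        return out[0] if np.asarray(points).ndim == 1 else out

    def save(self, path: str | os.PathLike) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.vectors.astype(np.float32),
                                 self.affine), str(path))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DisplacementField":
        import nibabel as nib

        img = nib.load(str(path))
        vec = np.asanyarray(img.dataobj)
        if vec.ndim == 5:               # (x, y, z, 1, 3) NIfTI convention
            vec = vec[:, :, :, 0, :]
        return cls(np.asarray(vec, float), np.asarray(img.affine))


class TransformChain:
    """Ordered target-to-source world mappings, applied as one composition."""

    def __init__(self, transforms=()):
        self.transforms = list(transforms)
        if not all(isinstance(t, (RigidTransform, DisplacementField))
                   for t in self.transforms):
            raise TypeError("chain elements must be RigidTransform or "
                            "DisplacementField")

    def __len__(self) -> int:
        return len(self.transforms)

    def __iter__(self):
        return iter(self.transforms)

    def apply(self, points: np.ndarray) -> np.ndarray:
        out = points
        for t in self.transforms:
            out = t.apply(out)
        return out


def compose(chain: TransformChain):
    """Single world-point mapping equal to sequential application.

    Used by :func:`resample` so the source image is interpolated exactly
    once regardless of chain length.
    """
    if len(chain) == 0:
        raise ValueError("empty transform chain")
    return chain.apply


def _as_chain(chain) -> TransformChain:
    if isinstance(chain, TransformChain):
        return chain
    if isinstance(chain, (RigidTransform, DisplacementField)):
        return TransformChain([chain])
    return TransformChain(list(chain))


def resample(v, chain, target_grid: VolumeImage, mode: str = "linear"):
    """Pull-resample an image onto the target grid through a chain.

    The chain maps target-space world points to source-space world points;
    source data is interpolated once at the mapped points. ``mode`` must be
    ``nearest`` for BinaryMask and RadiusMap inputs (enforced — vessel
    labels and radii must not be smoothed). Out-of-source-extent voxels
    get value 0 and coverage False; coverage is transported conservatively
    with nearest-neighbour lookup.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode: {mode!r}")
    if isinstance(v, (BinaryMask, RadiusMap)) and mode != "nearest":
        raise ValueError(
            f"{type(v).__name__} must be resampled with mode='nearest'")
    chain = _as_chain(chain)
    mapping = compose(chain)

    shape = target_grid.data.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    tgt_vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    src_world = mapping(voxel_to_world(target_grid.affine, tgt_vox))
    src_vox = world_to_voxel(v.affine if not isinstance(v, np.ndarray) else v,
                             src_world)
    coords = np.atleast_2d(src_vox).T

    inside = np.ones(coords.shape[1], dtype=bool)
    for ax, n in enumerate(v.data.shape):
        inside &= (coords[ax] >= -0.5) & (coords[ax] <= n - 0.5)

    order = 0 if mode == "nearest" else 1
    if isinstance(v, BinaryMask):
        vals = ndi.map_coordinates(v.data.astype(np.uint8), coords, order=0,
                                   mode="constant", cval=0)
        vals[~inside] = 0
        return BinaryMask(vals.reshape(shape).astype(bool),
                          target_grid.affine.copy())
    if isinstance(v, RadiusMap):
        vals = ndi.map_coordinates(v.data, coords, order=0,
                                   mode="constant", cval=0.0)
        vals[~inside] = 0.0
        return RadiusMap(vals.reshape(shape), target_grid.affine.copy())

    vals = ndi.map_coordinates(np.asarray(v.data, float), coords, order=order,
                               mode="constant", cval=0.0)
    vals[~inside] = 0.0
    cov_src = v.coverage_or_full().astype(np.uint8)
    cov = ndi.map_coordinates(cov_src, coords, order=0, mode="constant",
                              cval=0)
    cov = (cov > 0) & inside
    return VolumeImage(vals.reshape(shape), target_grid.affine.copy(),
                       cov.reshape(shape))


# ---------------------------------------------------------------------------
# registration backends


def _ground_truth_backend(moving, fixed, mode, truth=None, **_):
    if truth is None:
        raise ValueError("ground_truth backend requires truth=<transform>")
    return truth


def _simpleitk_backend(moving: VolumeImage, fixed: VolumeImage, mode: str,
                       iterations: int = 100, **_):
    """Rigid/affine intensity registration via SimpleITK (axis-aligned affines).

    Returns the fixed-world -> moving-world (target-to-source) transform,
    matching the pull-resampling convention used throughout.
    """
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "registration backend 'simpleitk' needs the SimpleITK package "
            "(pip install SimpleITK), or use backend='ground_truth' with a "
            "known transform") from exc

    def to_sitk(v: VolumeImage):
        img = sitk.GetImageFromArray(np.ascontiguousarray(
            np.asarray(v.data, np.float64).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.affine[:3, 3]))
        return img

    if mode not in ("rigid", "affine"):
        raise ValueError("simpleitk backend supports rigid/affine modes")
    f, m = to_sitk(fixed), to_sitk(moving)
    tx0 = sitk.CenteredTransformInitializer(
        f, m,
        sitk.Euler3DTransform() if mode == "rigid" else sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=iterations)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx0, inPlace=False)
    tx = reg.Execute(f, m)
    # SITK transforms map fixed physical points into moving space: exactly
    # the target-to-source convention. Flatten to a 4x4 matrix.
    tx = sitk.Euler3DTransform(tx.GetNthTransform(0)) \
        if isinstance(tx, sitk.CompositeTransform) else tx
    mat = np.eye(4)
    params = np.asarray(tx.GetMatrix()).reshape(3, 3)
    center = np.asarray(tx.GetCenter())
    trans = np.asarray(tx.GetTranslation())
    mat[:3, :3] = params
    mat[:3, 3] = trans + center - params @ center
    if mode == "rigid":
        # re-orthonormalize against accumulated round-off
        u, _, vt = np.linalg.svd(mat[:3, :3])
        mat[:3, :3] = u @ vt
        return RigidTransform(mat)
    return mat


REGISTRATION_BACKENDS = {
    "ground_truth": _ground_truth_backend,
    "simpleitk": _simpleitk_backend,
}


def register(moving: VolumeImage, fixed: VolumeImage, mode: str = "rigid",
             backend: str = "ground_truth", **kwargs):
    """Estimate a moving -> fixed registration through a named backend.

    The returned transform maps fixed-space (target) world points into
    moving-space (source) world points, ready for :func:`resample`.
    """
    if backend not in REGISTRATION_BACKENDS:
        raise ValueError(
            f"registration backend {backend!r} unavailable; options: "
            f"{sorted(REGISTRATION_BACKENDS)} (the 'simpleitk' backend needs "
            "pip install SimpleITK)")
    return REGISTRATION_BACKENDS[backend](moving, fixed, mode, **kwargs)
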