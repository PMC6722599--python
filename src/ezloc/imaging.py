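"""Volume data model and shared imaging primitives.

All grids are carried as :class:`Volume3D` / :class:`BinaryMask`: a 3-D
scalar array plus a 4x4 voxel-index -> world-mm affine in RAS orientation,
0-based voxel indices.  NIfTI-1 is the on-disk format (Analyze is accepted
read-only through the same nibabel path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, FormatError, GridMismatchError

#: tolerance (mm) on affine entries when deciding two volumes share a grid
GRID_ATOL = 1e-4


@dataclass
class Volume3D:
    """A 3-D scalar image with a voxel-to-world affine (RAS, mm)."""

    data: np.ndarray
    affine: np.ndarray
    frame: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if np.any(self.voxel_sizes <= 0):
            raise FormatError("voxel sizes must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Column norms of the 3x3 affine block (mm per voxel step)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_center(self) -> np.ndarray:
        """World coordinates of the geometric grid center."""
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)

    def same_grid(self, other: "Volume3D | BinaryMask", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BinaryMask:
    """A strictly two-valued 3-D grid on the same carrier as :class:`Volume3D`."""

    data: np.ndarray
    affine: np.ndarray
    frame: str = "RAS"
    _vol: Volume3D = field(init=False, repr=False)

    def __post_init__(self):
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1, True, False])):
            raise FormatError(f"mask is not binary; values {uniq[:10]}")
        self.data = arr.astype(bool)
        self._vol = Volume3D(self.data.astype(np.uint8), self.affine)
        self.affine = self._vol.affine

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    voxel_to_world = Volume3D.voxel_to_world
    world_to_voxel = Volume3D.world_to_voxel
    same_grid = Volume3D.same_grid

    @property
    def voxel_sizes(self) -> np.ndarray:
        return self._vol.voxel_sizes


def read_volume(path, nan_policy: str = "reject") -> Volume3D:
    """Read a NIfTI-1 (or Analyze) volume from ``path``.

    Parameters
    ----------
    path : path-like
    nan_policy : {"reject", "zero"}
        Non-finite voxels either raise (default) or are zero-filled.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"cannot read {path!s} as a volume: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path!s}: expected a 3-D volume, got shape {data.shape}"
        )
    bad = ~np.isfinite(data.astype(float))
    if bad.any():
        if nan_policy == "reject":
            raise FormatError(
                f"{path!s}: {int(bad.sum())} non-finite voxel(s) under policy 'reject'"
            )
        data = np.where(bad, 0, data)
    return Volume3D(data, np.asarray(img.affine))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.affine)


def write_volume(vol: Volume3D | BinaryMask, path) -> None:
    """Write a volume (or mask, as uint8) to NIfTI-1."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.Nifti1Image(data, vol.affine).to_filename(str(path))


def apply_mask(vol: Volume3D, mask: BinaryMask) -> Volume3D:
    """Zero all voxels outside ``mask``; voxels inside are untouched."""
    if not vol.same_grid(mask):
        raise GridMismatchError(
            "volume and mask are on different grids; resample one of them first "
            f"(shapes {vol.shape} vs {mask.shape})"
        )
    out = np.where(mask.data, vol.data, 0)
    return Volume3D(out, vol.affine.copy())


def resample_to(vol: Volume3D, target: Volume3D | BinaryMask, transform=None,
                order: int = 1) -> Volume3D:
    """Resample ``vol`` onto the grid of ``target`` under a rigid transform.

    ``transform`` maps moving-volume world coordinates into target world
    coordinates (identity when omitted).  Interpolation is trilinear
    (``order=1``); voxels mapping outside the source field of view are 0.
    """
    from .registration import RigidTransform  # local import avoids a cycle

    if transform is None:
        tmat = np.eye(4)
    elif isinstance(transform, RigidTransform):
        tmat = transform.matrix()
    else:
        tmat = np.asarray(transform, dtype=float)
        if tmat.shape != (4, 4):
            raise FormatError("transform must be a RigidTransform or 4x4 matrix")
    # target voxel -> target world -> moving world -> moving voxel
    full = np.linalg.inv(vol.affine) @ np.linalg.inv(tmat) @ target.affine
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in target.shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    src = full[:3, :3] @ idx + full[:3, 3:4]
    out = ndimage.map_coordinates(
        vol.data.astype(float), src, order=order, mode="constant", cval=0.0
    )
    return Volume3D(out.reshape(target.shape), np.asarray(target.affine).copy())
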