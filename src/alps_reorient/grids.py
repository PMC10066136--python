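"""Voxel grids and scalar maps.

Conventions used throughout the package: world coordinates are RAS millimetres,
voxel indices are 0-based, and the affine maps the *centre* of voxel (i, j, k)
to world mm. The default phantom affine is diagonal (isotropic voxels) with the
world origin at the geometric centre of the grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=8)
def _voxel_centers_cached(shape: tuple[int, ...], affine_bytes: bytes) -> np.ndarray:
    affine = np.frombuffer(affine_bytes, dtype=float).reshape(4, 4)
    idx = np.indices(shape).reshape(3, -1).T
    out = idx @ affine[:3, :3].T + affine[:3, 3]
    out.setflags(write=False)  # shared across callers
    return out


@dataclass(frozen=True)
class ImageGrid:
    """A voxel lattice embedded in world (mm) space."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def centered(cls, shape: tuple[int, int, int], voxel_size: float) -> "ImageGrid":
        """Isotropic RAS grid with the world origin at the grid centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = float(voxel_size)
        affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * float(voxel_size)
        return cls(shape, affine)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def world_center(self) -> np.ndarray:
        center_vox = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        return self.voxel_to_world(center_vox[None, :])[0]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """(N, 3) world coordinates of every voxel centre, C-order.

        The returned array is cached and read-only; copy before mutating.
        """
        return _voxel_centers_cached(self.shape, np.ascontiguousarray(self.affine).tobytes())

    def supersampled(self, factor: int) -> "ImageGrid":
        """A finer grid covering the same field of view.

        Each voxel is split ``factor`` ways per axis; voxel centres of the fine
        grid tile the original voxels symmetrically.
        """
        factor = int(factor)
        if factor < 1:
            raise ValueError("factor must be >= 1")
        new_shape = tuple(s * factor for s in self.shape)
        scale = np.diag([1.0 / factor] * 3)
        new_rot = self.affine[:3, :3] @ scale
        # shift so the fine lattice stays centred on the coarse voxels
        offset_vox = (1.0 / factor - 1.0) / 2.0
        new_origin = self.affine[:3, 3] + self.affine[:3, :3] @ np.full(3, offset_vox)
        affine = np.eye(4)
        affine[:3, :3] = new_rot
        affine[:3, 3] = new_origin
        return ImageGrid(new_shape, affine)


@dataclass
class ScalarMap:
    """A per-voxel scalar quantity (FA, MD, Dx, ...) on a grid."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""
    validity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap data must be 3-D")
        if self.validity is not None and self.validity.shape != self.data.shape:
            raise ValueError("validity mask shape mismatch")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.data.shape, self.affine)
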