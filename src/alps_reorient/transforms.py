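"""Rigid (6-DOF) world-coordinate transforms.

A :class:`RigidTransform` maps subject (moving) world points to template
(fixed) world points: ``y = R x + t``.  Only rotation + translation are
allowed — scaling or shear in a matrix file is rejected.  Matrices are stored
as plain-text 4x4 homogeneous arrays in world-mm RAS coordinates (a documented
divergence from FSL's scaled-voxel matrix dialect).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_ORTHO_TOL = 1e-6


def euler_matrix(angles_deg, order: str = "xyz") -> np.ndarray:
    """Rotation matrix for extrinsic rotations about the world axes.

    ``order='xyz'`` applies the x rotation first, then y, then z
    (R = Rz @ Ry @ Rx), all active rotations.
    """
    ax = {"x": 0, "y": 1, "z": 2}
    R = np.eye(3)
    for axis_name, angle in zip(order, np.atleast_1d(angles_deg)):
        a = np.deg2rad(float(angle))
        c, s = np.cos(a), np.sin(a)
        i = ax[axis_name]
        j, k = (i + 1) % 3, (i + 2) % 3
        Ri = np.eye(3)
        Ri[j, j] = c
        Ri[k, k] = c
        Ri[j, k] = -s
        Ri[k, j] = s
        R = Ri @ R
    return R


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if np.max(np.abs(R.T @ R - np.eye(3))) > tol:
        raise ValueError("matrix is not orthonormal (scaling or shear present)")
    if np.linalg.det(R) <= 0:
        raise ValueError("rotation must be proper (det +1); reflections rejected")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation acting on world (mm) RAS coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler(
        cls,
        angles_deg,
        translation=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
        order: str = "xyz",
    ) -> "RigidTransform":
        """Rotation about ``center`` (world mm) followed by ``translation``.

        y = R (x - c) + c + t
        """
        R = euler_matrix(angles_deg, order)
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float)
        return cls(R, c + t - R @ c)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("homogeneous matrix must be 4x4")
        if np.max(np.abs(matrix[3] - [0, 0, 0, 1])) > 1e-9:
            raise ValueError("last row of a rigid matrix must be 0 0 0 1")
        return cls(matrix[:3, :3], matrix[:3, 3])

    # -- algebra ----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """compose(t1, t2)(x) == t1(t2(x))."""
    return t1.compose(t2)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def rotation_error_deg(a: RigidTransform, b: RigidTransform) -> float:
    """Angle of the residual rotation between two transforms."""
    return RigidTransform(a.rotation @ b.rotation.T, np.zeros(3)).rotation_angle_deg()


# -- plain-text matrix I/O ------------------------------------------------

def write_matrix(transform: RigidTransform, path) -> None:
    np.savetxt(path, transform.matrix, fmt="%.12g")


def read_matrix(path) -> RigidTransform:
    arr = np.loadtxt(Path(path), dtype=float)
    if arr.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {arr.shape}")
    return RigidTransform.from_matrix(arr)
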