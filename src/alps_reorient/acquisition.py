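"""Diffusion acquisition description: gradient schemes and scan parameters.

The emulated acquisition is a single-shell DTI protocol: 64 motion-probing
gradient (MPG) directions at b = 1000 s/mm^2 plus one b = 0 volume on a
2.5 mm isotropic grid.  The scanner's actual direction table is not public,
so directions are synthesised either by electrostatic-repulsion relaxation
from a seeded random start (default; near-uniform on the half-sphere) or by
a deterministic spherical Fibonacci lattice.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_UNIT_TOL = 1e-8
MIN_DIRECTIONS = 6  # a symmetric 3x3 tensor has six unknowns


@dataclass(frozen=True)
class AcquisitionSpec:
    """Parameters of the emulated DWI acquisition."""

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: float = 2.5  # mm, isotropic
    b_value: float = 1000.0  # s/mm^2
    n_directions: int = 64
    n_b0: int = 1
    s0: float = 1000.0  # baseline (b=0) signal, unitless
    snr: float = 30.0  # S0 / sigma of the Rician noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0 or self.voxel_size <= 0:
            raise ValueError("grid dimensions and voxel size must be positive")
        if self.b_value <= 0 or self.s0 <= 0 or self.snr <= 0 or self.n_b0 < 1:
            raise ValueError("b_value, s0, snr must be positive and n_b0 >= 1")
        if self.n_directions < MIN_DIRECTIONS:
            raise ValueError(
                f"n_directions must be >= {MIN_DIRECTIONS}: the diffusion tensor has six "
                "independent components, fewer directions leave the fit under-determined"
            )


@dataclass(frozen=True)
class GradientTable:
    """Diffusion-encoding directions (unit vectors) and b-values."""

    bvecs: np.ndarray  # (N, 3)
    bvals: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        bvecs = np.asarray(self.bvecs, dtype=float)
        bvals = np.asarray(self.bvals, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3 or bvals.shape != (bvecs.shape[0],):
            raise ValueError("bvecs must be (N, 3) and bvals (N,)")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > _UNIT_TOL):
            raise ValueError("b > 0 gradient directions must be unit vectors")
        if np.any(norms[~dwi] > _UNIT_TOL):
            raise ValueError("b = 0 rows must have zero direction vectors")
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the b > 0 volumes."""
        return self.bvecs[~self.b0_mask]


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the upper half-sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _electrostatic_directions(n: int, seed: int, n_iter: int = 300) -> np.ndarray:
    """Relax seeded random points under antipodally-symmetric repulsion.

    Energy ~ sum over pairs of 1/d(xi, xj)^2 + 1/d(xi, -xj)^2, minimised by
    projected gradient descent on the sphere with a decaying step.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    eye = np.eye(n, dtype=bool)
    for it in range(n_iter):
        step = 0.05 * (1.0 - it / n_iter) + 1e-3
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]
            d2 = np.sum(diff**2, axis=-1)
            d2[eye] = np.inf
            if sign < 0:
                d2[d2 < 1e-12] = np.inf  # antipode of itself
            force += np.sum(diff / (d2**2)[..., None], axis=1)
        # project onto the tangent plane and renormalise
        force -= np.sum(force * x, axis=1, keepdims=True) * x
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        x = x + step * force / norm
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical half-sphere (z >= 0) for reproducible signs
    flip = x[:, 2] < 0
    x[flip] *= -1.0
    return x


def generate_gradient_table(
    n_directions: int = 64,
    n_b0: int = 1,
    b_value: float = 1000.0,
    seed: int = 0,
    method: str = "electrostatic",
) -> GradientTable:
    """Build a single-shell gradient table with the b = 0 rows first."""
    if n_directions < MIN_DIRECTIONS:
        raise ValueError(
            f"n_directions must be >= {MIN_DIRECTIONS} for the tensor fit to be identifiable"
        )
    if method == "electrostatic":
        dirs = _electrostatic_directions(n_directions, seed)
    elif method == "fibonacci":
        dirs = _fibonacci_hemisphere(n_directions)
    else:
        raise ValueError(f"unknown gradient scheme method: {method!r}")
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    return GradientTable(bvecs, bvals)


def minimum_pairwise_angle_deg(directions: np.ndarray) -> float:
    """Smallest acute angle between any two directions (mod antipode)."""
    d = np.asarray(directions, dtype=float)
    dots = np.abs(d @ d.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.rad2deg(np.arccos(np.clip(np.max(dots), -1.0, 1.0))))


# -- FSL-dialect bvals/bvecs files ---------------------------------------

def write_fsl_gradients(gtab: GradientTable, bvals_path, bvecs_path) -> None:
    """Write `bvals` (one row) and `bvecs` (three rows: x, y, z)."""
    np.savetxt(bvals_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, gtab.bvecs.T, fmt="%.10g")


def read_fsl_gradients(bvals_path, bvecs_path) -> GradientTable:
    bvals = np.loadtxt(Path(bvals_path), dtype=float, ndmin=2)
    if bvals.shape[0] != 1:
        raise ValueError(f"bvals file must contain a single row, got {bvals.shape[0]}")
    bvecs = np.loadtxt(Path(bvecs_path), dtype=float, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvecs file must contain three rows (x, y, z), got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.shape[1]:
        raise ValueError("bvals and bvecs disagree on the number of volumes")
    return GradientTable(bvecs.T, bvals[0])
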