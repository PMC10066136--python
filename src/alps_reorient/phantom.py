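"""Synthetic periventricular DWI phantom with known tensor ground truth.

The phantom is a stylised axial block of the lateral-ventricle level where the
DTI-ALPS geometry lives: a central CSF "ventricle", projection-fiber slabs
lateral to it (principal diffusion axis z, inferior-superior), association-fiber
slabs lateral to those (principal axis y, anterior-posterior), and an isotropic
background.  In both fiber regions the x (right-left) diffusivity is elevated
above the cross-fiber eigenvalue — the perivascular signal the ALPS index
measures.  Every tensor is piecewise constant per region, so every downstream
stage has an exact closed-form oracle.

A "head rotation" is simulated by actively rotating the whole tensor field:
the output voxel at world point p carries the tensor R D(R^-1 (p - c) + c - t) R^T,
with nearest-region lookup so the rotated field stays an exact piecewise-
constant ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import AcquisitionSpec, GradientTable
from .grids import ImageGrid
from .transforms import RigidTransform

# region labels
BACKGROUND, CSF, PROJ_L, PROJ_R, ASSOC_L, ASSOC_R = 0, 1, 2, 3, 4, 5
WM_ANTERIOR, WM_POSTERIOR, WM_SUPERIOR, WM_INFERIOR = 6, 7, 8, 9
REGION_NAMES = {
    BACKGROUND: "background",
    CSF: "csf",
    PROJ_L: "proj_L",
    PROJ_R: "proj_R",
    ASSOC_L: "assoc_L",
    ASSOC_R: "assoc_R",
    WM_ANTERIOR: "wm_anterior",
    WM_POSTERIOR: "wm_posterior",
    WM_SUPERIOR: "wm_superior",
    WM_INFERIOR: "wm_inferior",
}
FIBER_LABELS = (PROJ_L, PROJ_R, ASSOC_L, ASSOC_R)


def _diag(dx: float, dy: float, dz: float) -> np.ndarray:
    return np.diag([dx, dy, dz]).astype(float)


@dataclass(frozen=True, eq=False)
class PhantomSpec:
    """Geometry (world mm) and per-region tensors (mm^2/s, anatomical frame).

    The fiber slabs run the full anterior-posterior/inferior-superior extent of
    the periventricular block; widths are chosen so the default ROIs sit at
    least two voxels away from any region boundary (interpolation-safe for
    rotations up to ~20 deg).
    """

    ventricle_halfwidth: float = 7.5  # |x| < this is CSF
    slab_width: float = 15.0  # width (mm) of each fiber slab along x
    y_halfwidth: float = 15.0
    z_halfwidth: float = 10.0
    # Peripheral white-matter marker structures (anterior, posterior,
    # superior, inferior) carry FA structure far from the rotation centre so
    # that small head rotations are visible to FA-based registration, the way
    # real anatomy is.  Their boundaries are slanted (never parallel to the
    # voxel lattice) and their lever arms long, so the rasterised edge
    # position is dithered rather than coherently quantised; they sit
    # >= 10 mm away from the ALPS ROIs and are deliberately asymmetric in y
    # and z, like a head, to avoid spurious registration optima.
    marker_halfwidth_x: float = 34.0
    marker_y_halfwidth: float = 36.0
    marker_z_halfwidth: float = 16.0
    superior_z_range: tuple[float, float] = (11.9, 16.1)
    superior_slant: tuple[float, float] = (0.06, 0.03)  # dz per y, per |x|
    inferior_z_range: tuple[float, float] = (-16.3, -11.8)
    inferior_slant: tuple[float, float] = (-0.05, -0.03)
    anterior_y_range: tuple[float, float] = (20.5, 30.7)
    anterior_slant: tuple[float, float] = (0.08, 0.04)  # dy per z, per |x|
    posterior_y_range: tuple[float, float] = (-31.2, -20.8)
    posterior_slant: tuple[float, float] = (0.06, -0.05)
    # tensor diagonals, anatomical frame (literature-typical values)
    projection_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.55e-3, 0.40e-3, 1.40e-3)
    )
    association_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.55e-3, 1.40e-3, 0.40e-3)
    )
    anterior_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.45e-3, 1.10e-3, 0.45e-3)
    )
    posterior_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.40e-3, 1.30e-3, 0.40e-3)
    )
    superior_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.45e-3, 0.45e-3, 1.10e-3)
    )
    inferior_tensor: np.ndarray = field(
        default_factory=lambda: _diag(0.50e-3, 0.50e-3, 1.00e-3)
    )
    background_diffusivity: float = 0.80e-3
    csf_diffusivity: float = 3.0e-3
    # multiplicative factor on the perivascular (Dxx) component of both fiber
    # regions; models between-subject physiological variation of the index
    perivascular_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.ventricle_halfwidth, self.slab_width, self.y_halfwidth, self.z_halfwidth
        ) <= 0:
            raise ValueError("all region extents must be positive")
        if self.perivascular_scale <= 0:
            raise ValueError("perivascular_scale must be positive")
        for name, D in self.region_tensors.items():
            if np.max(np.abs(D - D.T)) > 1e-18:
                raise ValueError(f"{name} tensor is not symmetric")
            if np.min(np.linalg.eigvalsh(D)) <= 0:
                raise ValueError(f"{name} tensor is not positive definite")

    @property
    def outer_radius(self) -> float:
        """Lateral extent of the outermost (association) slab."""
        return self.ventricle_halfwidth + 2 * self.slab_width

    @property
    def extent(self) -> np.ndarray:
        """Maximum |world| coordinate of any tissue, per axis (mm)."""
        sy, sx = self.superior_slant
        iy, ix = self.inferior_slant
        az, ax_ = self.anterior_slant
        pz, px = self.posterior_slant
        slant_pad_z = max(
            self.superior_z_range[1]
            + abs(sy) * self.marker_y_halfwidth
            + abs(sx) * self.marker_halfwidth_x,
            -self.inferior_z_range[0]
            + abs(iy) * self.marker_y_halfwidth
            + abs(ix) * self.marker_halfwidth_x,
        )
        slant_pad_y = max(
            self.anterior_y_range[1]
            + abs(az) * self.marker_z_halfwidth
            + abs(ax_) * self.marker_halfwidth_x,
            -self.posterior_y_range[0]
            + abs(pz) * self.marker_z_halfwidth
            + abs(px) * self.marker_halfwidth_x,
        )
        return np.array(
            [
                max(self.outer_radius, self.marker_halfwidth_x),
                max(self.y_halfwidth, slant_pad_y),
                max(self.z_halfwidth, slant_pad_z),
            ]
        )

    @property
    def geometry_key(self) -> tuple:
        """The fields that define region shapes (not tensor values)."""
        return (
            self.ventricle_halfwidth,
            self.slab_width,
            self.y_halfwidth,
            self.z_halfwidth,
            self.marker_halfwidth_x,
            self.marker_y_halfwidth,
            self.marker_z_halfwidth,
            self.superior_z_range,
            self.superior_slant,
            self.inferior_z_range,
            self.inferior_slant,
            self.anterior_y_range,
            self.anterior_slant,
            self.posterior_y_range,
            self.posterior_slant,
        )

    @property
    def region_tensors(self) -> dict[int, np.ndarray]:
        proj = self.projection_tensor.copy()
        assoc = self.association_tensor.copy()
        proj[0, 0] *= self.perivascular_scale
        assoc[0, 0] *= self.perivascular_scale
        return {
            BACKGROUND: self.background_diffusivity * np.eye(3),
            CSF: self.csf_diffusivity * np.eye(3),
            PROJ_L: proj,
            PROJ_R: proj,
            ASSOC_L: assoc,
            ASSOC_R: assoc,
            WM_ANTERIOR: self.anterior_tensor.copy(),
            WM_POSTERIOR: self.posterior_tensor.copy(),
            WM_SUPERIOR: self.superior_tensor.copy(),
            WM_INFERIOR: self.inferior_tensor.copy(),
        }


@dataclass(frozen=True)
class RotationSpec:
    """Active head rotation: extrinsic Euler angles about world x, y, z.

    ``euler_angles_deg[0]`` is the chin-up/down (x) rotation, ``[2]`` the
    neck (z) rotation.  The rotation is about ``center`` (defaults to the
    grid centre, which is the world origin for the default phantom).
    """

    euler_angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] | None = None

    def to_transform(self, grid: ImageGrid | None = None) -> RigidTransform:
        center = self.center
        if center is None:
            center = grid.world_center if grid is not None else (0.0, 0.0, 0.0)
        return RigidTransform.from_euler(
            self.euler_angles_deg, translation=self.translation, center=center
        )


@dataclass
class TensorPhantom:
    """Piecewise-constant diffusion tensor field with its region label map.

    ``spec`` (when present) is the continuous region geometry the labels were
    rasterised from; ``pose`` is the rigid transform of the head relative to
    the anatomical (unrotated) frame.
    """

    tensors: np.ndarray  # (X, Y, Z, 3, 3), mm^2/s
    labels: np.ndarray  # (X, Y, Z) int8
    affine: np.ndarray
    region_tensors: dict[int, np.ndarray]
    spec: PhantomSpec | None = None
    pose: RigidTransform | None = None

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.labels.shape, self.affine)


@dataclass
class DwiDataset:
    """4-D diffusion-weighted signal with its gradient table."""

    signal: np.ndarray  # (X, Y, Z, N), unitless, >= 0
    gradient_table: GradientTable
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[-1] != len(self.gradient_table):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but the gradient table "
                f"has {len(self.gradient_table)} rows"
            )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.signal.shape[:3], self.affine)


def _label_points(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Region label of each world point, vectorised."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    ax = np.abs(x)
    inside = (np.abs(y) < spec.y_halfwidth) & (np.abs(z) < spec.z_halfwidth)
    labels = np.zeros(points.shape[0], dtype=np.int8)
    v = spec.ventricle_halfwidth
    labels[inside & (ax < v)] = CSF
    proj = inside & (ax > v) & (ax < v + spec.slab_width)
    assoc = inside & (ax > v + spec.slab_width) & (ax < spec.outer_radius)
    labels[proj & (x < 0)] = PROJ_L
    labels[proj & (x > 0)] = PROJ_R
    labels[assoc & (x < 0)] = ASSOC_L
    labels[assoc & (x > 0)] = ASSOC_R
    # peripheral marker structures with slanted (lattice-oblique) boundaries
    mx = ax < spec.marker_halfwidth_x
    my = np.abs(y) < spec.marker_y_halfwidth
    mz = np.abs(z) < spec.marker_z_halfwidth
    sy, sx = spec.superior_slant
    zs = z - sy * y - sx * ax
    sup = mx & my & (zs > spec.superior_z_range[0]) & (zs < spec.superior_z_range[1])
    labels[sup] = WM_SUPERIOR
    iy, ix = spec.inferior_slant
    zi = z - iy * y - ix * ax
    inf = mx & my & (zi > spec.inferior_z_range[0]) & (zi < spec.inferior_z_range[1])
    labels[inf] = WM_INFERIOR
    az, ax_s = spec.anterior_slant
    ya = y - az * z - ax_s * ax
    ant = mx & mz & (ya > spec.anterior_y_range[0]) & (ya < spec.anterior_y_range[1])
    labels[ant] = WM_ANTERIOR
    pz, px = spec.posterior_slant
    yp = y - pz * z - px * ax
    post = mx & mz & (yp > spec.posterior_y_range[0]) & (yp < spec.posterior_y_range[1])
    labels[post] = WM_POSTERIOR
    return labels


def build_tensor_phantom(
    phantom_spec: PhantomSpec, acquisition_spec: AcquisitionSpec
) -> TensorPhantom:
    """Rasterise the phantom onto the acquisition grid (RAS, centred)."""
    grid = ImageGrid.centered(acquisition_spec.grid_shape, acquisition_spec.voxel_size)
    half_extent = (
        np.abs(grid.voxel_to_world(np.zeros((1, 3)))[0]) + acquisition_spec.voxel_size / 2.0
    )
    required = phantom_spec.extent
    if np.any(required > half_extent + 1e-9):
        raise ValueError(
            f"phantom regions (extent {required} mm) do not fit inside the grid "
            f"(half extent {half_extent} mm)"
        )
    points = grid.voxel_centers_world()
    labels = _label_points(points, phantom_spec).reshape(grid.shape)
    region_tensors = phantom_spec.region_tensors
    lut = np.stack([region_tensors[k] for k in sorted(region_tensors)], axis=0)
    tensors = lut[labels]
    return TensorPhantom(tensors, labels, grid.affine, region_tensors, spec=phantom_spec)


def with_region_tensors(phantom: TensorPhantom, spec: PhantomSpec) -> TensorPhantom:
    """Same rasterised geometry, new per-region tensors (per-subject physiology)."""
    if phantom.spec is not None and spec.geometry_key != phantom.spec.geometry_key:
        raise ValueError("with_region_tensors requires identical region geometry")
    region_tensors = spec.region_tensors
    lut = np.stack([region_tensors[k] for k in sorted(region_tensors)], axis=0)
    return TensorPhantom(
        lut[phantom.labels], phantom.labels, phantom.affine, region_tensors, spec=spec
    )


def rotate_phantom(phantom: TensorPhantom, rotation_spec: RotationSpec) -> TensorPhantom:
    """Rigidly move the head: output voxel p holds R D(R^-1(p-c)+c-t) R^T.

    Region membership at the pre-image point is looked up in the continuous
    region geometry when the phantom carries its spec (nearest-region, never
    interpolated), falling back to the nearest rasterised voxel otherwise;
    either way the rotated field remains an exact piecewise-constant oracle.
    Voxels whose pre-image falls outside the phantom become background.
    """
    grid = phantom.grid
    t = rotation_spec.to_transform(grid)
    if np.allclose(t.matrix, np.eye(4)):
        return TensorPhantom(
            phantom.tensors.copy(),
            phantom.labels.copy(),
            phantom.affine.copy(),
            dict(phantom.region_tensors),
            spec=phantom.spec,
            pose=t,
        )
    points = grid.voxel_centers_world()
    source = t.invert().apply(points)
    if phantom.spec is not None:
        labels = _label_points(source, phantom.spec)
    else:
        src_vox = np.round(grid.world_to_voxel(source)).astype(int)
        inside = np.all((src_vox >= 0) & (src_vox < np.asarray(grid.shape)), axis=1)
        labels = np.zeros(points.shape[0], dtype=np.int8)
        iv = src_vox[inside]
        labels[inside] = phantom.labels[iv[:, 0], iv[:, 1], iv[:, 2]]
    R = t.rotation
    rotated_region = {
        k: R @ D @ R.T for k, D in phantom.region_tensors.items()
    }
    lut = np.stack([rotated_region[k] for k in sorted(rotated_region)], axis=0)
    tensors = lut[labels].reshape(grid.shape + (3, 3))
    return TensorPhantom(
        tensors, labels.reshape(grid.shape), grid.affine, rotated_region, spec=phantom.spec, pose=t
    )


def _check_psd(tensors: np.ndarray, tol: float = 1e-18) -> None:
    """Reject any voxel tensor with a negative eigenvalue.

    For a symmetric 3x3, all eigenvalues are >= 0 iff the elementary
    symmetric polynomials (trace, second invariant, determinant) are >= 0.
    Raises naming an offending voxel.
    """
    d = tensors
    e1 = np.trace(d, axis1=-2, axis2=-1)
    e2 = (e1**2 - np.sum(d * np.swapaxes(d, -1, -2), axis=(-2, -1))) / 2.0
    e3 = np.linalg.det(d)
    scale = np.maximum(np.abs(e1), 1e-30)
    bad = (e1 < -tol) | (e2 < -tol * scale**2) | (e3 < -tol * scale**3)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0][: d.ndim - 2])
        raise ValueError(f"tensor with a negative eigenvalue at voxel {idx}")


def simulate_dwi(
    tensor_source: TensorPhantom, gradient_table: GradientTable, s0: float = 1000.0
) -> DwiDataset:
    """Noiseless single-tensor forward model S = S0 exp(-b g^T D g)."""
    tensors = tensor_source.tensors
    _check_psd(tensors)
    g = gradient_table.bvecs
    b = gradient_table.bvals
    flat = tensors.reshape(-1, 3, 3)
    # quadratic form g^T D g for every voxel x volume
    quad = np.einsum("vab,na,nb->vn", flat, g, g, optimize=True)
    signal = s0 * np.exp(-b[None, :] * quad)
    signal = signal.reshape(tensors.shape[:3] + (len(gradient_table),))
    return DwiDataset(signal, gradient_table, tensor_source.affine.copy())


def add_rician_noise(dwi: DwiDataset, snr: float, seed: int, s0: float | None = None) -> DwiDataset:
    """Rician magnitude noise: S' = sqrt((S + n1)^2 + n2^2), sigma = S0/SNR.

    ``snr=np.inf`` returns an identical (copied) dataset.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return DwiDataset(dwi.signal.copy(), dwi.gradient_table, dwi.affine.copy())
    if s0 is None:
        b0 = dwi.signal[..., dwi.gradient_table.b0_mask]
        s0 = float(np.max(b0)) if b0.size else float(np.max(dwi.signal))
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    # float32 draws: the noise itself needs no double precision
    n1 = sigma * rng.standard_normal(size=dwi.signal.shape, dtype=np.float32)
    n2 = sigma * rng.standard_normal(size=dwi.signal.shape, dtype=np.float32)
    noisy = np.sqrt((dwi.signal + n1) ** 2 + n2**2)
    return DwiDataset(noisy, dwi.gradient_table, dwi.affine.copy())


def subject_phantom_spec(
    base: PhantomSpec, subject_sd: float, rng: np.random.Generator
) -> PhantomSpec:
    """Per-subject physiological variant: scale the perivascular Dxx contrast.

    Models the real between-subject spread of the ALPS index (which in cohorts
    is age-associated); the scale is drawn once per subject.
    """
    if subject_sd < 0:
        raise ValueError("subject_sd must be >= 0")
    scale = float(np.clip(rng.normal(1.0, subject_sd), 0.5, 1.5))
    return replace(base, perivascular_scale=base.perivascular_scale * scale)
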