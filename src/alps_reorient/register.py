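"""Rigid FA-to-template registration and tensor-field reorientation.

The registration re-implements, at phantom scale, the flirt+vecreg recipe:
a six-degree-of-freedom rigid transform (rotation + translation, never
scaling) is estimated by maximising the normalised cross-correlation (NCC)
between the fixed (template) FA map and the resampled moving FA map, using a
coarse exhaustive search over rotations with a centre-of-mass translation
initialisation, followed by derivative-free (Powell) refinement.  NCC is used
instead of flirt's correlation ratio because both images are FA maps of the
same modality; the whole procedure is deterministic.

Reorientation then resamples each of the six tensor-component maps into the
template grid (trilinear) and conjugates every voxel tensor with the rotation
part of the transform, D' = R D R^T — eigenvectors rotate, eigenvalues are
untouched.  This is the vector-data registration step: a rigid R is spatially
constant, so resample-then-rotate is exact up to interpolation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, map_coordinates
from scipy.optimize import minimize

from .grids import ImageGrid, ScalarMap
from .tensor_fit import DiffusionTensorField
from .transforms import RigidTransform, _check_rotation, euler_matrix


@dataclass(frozen=True)
class RegistrationOptions:
    """Search-strategy knobs for :func:`register_rigid`.

    ``rot_range_deg``/``rot_step_deg`` define the exhaustive rotation grid per
    axis; ``coarse_subsample`` evaluates the coarse cost on a strided voxel
    subset; ``refine_subsample`` does the same for the Powell polish (1 =
    full resolution).  ``min_overlap`` is the fraction of fixed voxels whose
    pre-image must land inside the moving image.
    """

    rot_range_deg: float = 30.0
    rot_step_deg: float = 5.0
    coarse_subsample: int = 2
    refine: bool = True
    refine_subsample: int = 1
    xtol: float = 1e-3
    ftol: float = 1e-8
    maxfev: int | None = None
    min_overlap: float = 0.25
    #: evaluate the cost only where the *fixed* image has structure (FA above
    #: this threshold, dilated by ``mask_dilation_vox``); keeps the evaluation
    #: set independent of the candidate transform, which would otherwise bias
    #: the optimum through field-of-view clipping
    mask_threshold: float = 0.05
    mask_dilation_vox: int = 3
    #: Gaussian pre-smoothing (voxels) of both images before the cost is
    #: evaluated; damps the voxelisation ripple of sharp boundaries
    smooth_sigma_vox: float = 1.0


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_cost: float  # negative NCC (lower is better)
    converged: bool
    trace: list[dict] = field(default_factory=list)


def _center_of_mass_world(smap: ScalarMap) -> np.ndarray:
    w = np.abs(smap.data).reshape(-1)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot register a constant (zero) image")
    pts = smap.grid.voxel_centers_world()
    return (pts * w[:, None]).sum(axis=0) / total


class _NccEngine:
    """Evaluates -NCC(fixed, moving o T^-1) over a fixed evaluation mask.

    The mask lives in the fixed frame (structure voxels plus a dilated
    shell), optionally strided, so the set of compared voxels does not change
    with the candidate transform.
    """

    def __init__(
        self, moving: ScalarMap, fixed: ScalarMap, subsample: int, opts: "RegistrationOptions"
    ):
        if np.ptp(fixed.data) == 0 or np.ptp(moving.data) == 0:
            raise ValueError("cannot register constant images")
        sigma = opts.smooth_sigma_vox
        fixed_data = gaussian_filter(fixed.data, sigma) if sigma > 0 else fixed.data
        self.moving = gaussian_filter(moving.data, sigma) if sigma > 0 else moving.data
        mask = fixed_data > opts.mask_threshold
        if not mask.any():
            mask = np.ones_like(mask)
        if opts.mask_dilation_vox > 0:
            mask = binary_dilation(mask, iterations=opts.mask_dilation_vox)
        stride = max(int(subsample), 1)
        keep = np.zeros_like(mask)
        keep[::stride, ::stride, ::stride] = True
        mask &= keep
        self.fixed_vals = fixed_data[mask]
        idx = np.argwhere(mask)
        self.moving_inv_affine = np.linalg.inv(moving.affine)
        self.shape = np.asarray(moving.data.shape, dtype=float)
        self.min_overlap = opts.min_overlap
        self.center = ImageGrid(fixed.data.shape, fixed.affine).world_center
        fixed_world = ImageGrid(fixed.data.shape, fixed.affine).voxel_to_world(idx)
        self._centered_world = fixed_world - self.center  # precomputed for speed

    def cost(self, params: np.ndarray) -> float:
        # inline inverse rigid map: x = R^T (y - c - t) + c, then world->voxel
        R = euler_matrix(params[:3])
        src = (self._centered_world - params[3:6]) @ R + self.center
        A = self.moving_inv_affine
        vox = src @ A[:3, :3].T + A[:3, 3]
        inside = np.all((vox > -0.5) & (vox < self.shape - 0.5), axis=1)
        n = int(inside.sum())
        if n < self.min_overlap * inside.size:
            return 1.0  # worse than any attainable -NCC of interest
        sampled = map_coordinates(self.moving, vox[inside].T, order=1, mode="constant", cval=0.0)
        f = self.fixed_vals[inside]
        fm = f - f.mean()
        sm = sampled - sampled.mean()
        denom = np.sqrt((fm @ fm) * (sm @ sm))
        if denom == 0:
            return 1.0
        return -float((fm @ sm) / denom)


def register_rigid(
    moving_fa: ScalarMap,
    fixed_fa: ScalarMap,
    options: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Estimate the rigid transform mapping moving world -> fixed world."""
    opts = options or RegistrationOptions()
    coarse = _NccEngine(moving_fa, fixed_fa, opts.coarse_subsample, opts)
    com_fixed = _center_of_mass_world(fixed_fa)
    com_moving = _center_of_mass_world(moving_fa)
    c = coarse.center

    n_steps = int(round(opts.rot_range_deg / opts.rot_step_deg))
    angles = np.arange(-n_steps, n_steps + 1) * opts.rot_step_deg
    trace: list[dict] = []
    best = (np.inf, np.zeros(6))
    for ax, ay, az in itertools.product(angles, angles, angles):
        R = RigidTransform.from_euler((ax, ay, az), center=c).rotation
        # translation that carries the moving centre of mass onto the fixed one
        t = com_fixed - (R @ (com_moving - c) + c)
        params = np.array([ax, ay, az, *t])
        cost = coarse.cost(params)
        if cost < best[0]:
            best = (cost, params)
    trace.append({"stage": "coarse", "cost": best[0], "params": best[1].copy()})

    params, cost, converged = best[1], best[0], True
    if opts.refine:
        fine = (
            coarse
            if opts.refine_subsample == opts.coarse_subsample
            else _NccEngine(moving_fa, fixed_fa, opts.refine_subsample, opts)
        )
        start_cost = fine.cost(params)
        res = minimize(
            fine.cost,
            params,
            method="Powell",
            options={
                "xtol": opts.xtol,
                "ftol": opts.ftol,
                **({"maxfev": opts.maxfev} if opts.maxfev else {}),
            },
        )
        converged = bool(res.success)
        # cost comparisons are only meaningful within one engine
        if float(res.fun) <= start_cost:
            params, cost = res.x, float(res.fun)
        else:
            cost = start_cost
        trace.append({"stage": "refine", "cost": cost, "params": params.copy()})

    transform = RigidTransform.from_euler(params[:3], translation=params[3:6], center=c)
    return RegistrationResult(transform, float(cost), converged, trace)


def _resample_to_grid(
    data: np.ndarray,
    source_affine: np.ndarray,
    transform: RigidTransform,
    target_grid: ImageGrid,
    order: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``data`` (moving) through ``transform`` onto ``target_grid``.

    Returns (resampled, validity); voxels whose pre-image falls outside the
    source field of view are zero-filled and invalid.
    """
    pts = target_grid.voxel_centers_world()
    src = transform.invert().apply(pts)
    inv = np.linalg.inv(source_affine)
    vox = src @ inv[:3, :3].T + inv[:3, 3]
    shape = np.asarray(data.shape[:3])
    valid = np.all((vox > -0.5) & (vox < shape - 0.5), axis=1)
    if data.ndim == 3:
        out = map_coordinates(data, vox.T, order=order, mode="nearest")
        out[~valid] = 0.0
        return out.reshape(target_grid.shape), valid.reshape(target_grid.shape)
    # channel-last stacks (e.g. the six tensor components)
    outs = [
        map_coordinates(data[..., ch], vox.T, order=order, mode="nearest")
        for ch in range(data.shape[-1])
    ]
    out = np.stack(outs, axis=-1)
    out[~valid] = 0.0
    return (
        out.reshape(target_grid.shape + (data.shape[-1],)),
        valid.reshape(target_grid.shape),
    )


def apply_transform_scalar(
    smap: ScalarMap,
    transform: RigidTransform,
    target_grid: ImageGrid,
    interpolation: str = "linear",
) -> ScalarMap:
    """Resample a scalar map into the target grid (trilinear by default)."""
    order = {"linear": 1, "nearest": 0}[interpolation]
    data, valid = _resample_to_grid(smap.data, smap.affine, transform, target_grid, order)
    return ScalarMap(data, target_grid.affine.copy(), name=smap.name, validity=valid)


def reorient_tensor_field(
    tensor_field: DiffusionTensorField,
    transform: RigidTransform,
    target_grid: ImageGrid | None = None,
) -> DiffusionTensorField:
    """Resample the six component maps, then conjugate: D' = R D R^T."""
    R = _check_rotation(transform.rotation)
    if target_grid is None:
        target_grid = tensor_field.grid
    t = tensor_field.tensors
    comps = np.stack(
        [t[..., 0, 0], t[..., 1, 1], t[..., 2, 2], t[..., 0, 1], t[..., 0, 2], t[..., 1, 2]],
        axis=-1,
    )
    res, valid = _resample_to_grid(comps, tensor_field.affine, transform, target_grid)
    D = np.empty(target_grid.shape + (3, 3))
    D[..., 0, 0], D[..., 1, 1], D[..., 2, 2] = res[..., 0], res[..., 1], res[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = res[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = res[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = res[..., 5]
    D = np.einsum("ab,...bc,dc->...ad", R, D, R, optimize=True)
    s0, _ = _resample_to_grid(tensor_field.s0, tensor_field.affine, transform, target_grid)
    m1 = D[..., 0, 0]
    m2 = D[..., 0, 0] * D[..., 1, 1] - D[..., 0, 1] ** 2
    spd = (m1 > 0) & (m2 > 0) & (np.linalg.det(D) > 0) & valid
    out = DiffusionTensorField(D, s0, target_grid.affine.copy(), spd)
    out.validity = valid  # type: ignore[attr-defined]
    return out


def reoriented_axis_maps(
    reoriented_field: DiffusionTensorField,
) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """ro-Dx, ro-Dy, ro-Dz: the diagonal of D' in the template frame."""
    t = reoriented_field.tensors
    validity = getattr(reoriented_field, "validity", None)
    maps = []
    for i, name in enumerate(("ro-Dx", "ro-Dy", "ro-Dz")):
        maps.append(
            ScalarMap(
                t[..., i, i].copy(),
                reoriented_field.affine.copy(),
                name=name,
                validity=None if validity is None else validity.copy(),
            )
        )
    return tuple(maps)
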