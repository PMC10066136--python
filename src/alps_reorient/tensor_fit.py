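"""Per-voxel diffusion tensor estimation and derived scalar maps.

The fit is the classical log-linear model: for volume n with b-value b_n and
unit direction g_n,

    ln S_n = ln S0 - b_n g_n^T D g_n,

which is linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) with design row

    (1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz).

Ordinary least squares (``lls``) is the default and is exact on noiseless
data; ``wls`` re-weights by the squared predicted signal in a second pass,
which downweights the strongly-attenuated (noisiest log) measurements.
Negative-eigenvalue voxels after a noisy fit are retained as fitted but
flagged in ``spd_mask``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid, ScalarMap
from .phantom import DwiDataset

_SIGNAL_CLAMP_FRACTION = 1e-6  # of the reference S0, applied before log


@dataclass
class DiffusionTensorField:
    """Fitted symmetric tensor per voxel, with the fitted S0 map."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3) mm^2/s
    s0: np.ndarray  # (X, Y, Z)
    affine: np.ndarray
    spd_mask: np.ndarray  # True where all eigenvalues > 0

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.tensors.shape[:3], self.affine)


@dataclass
class TensorEigensystem:
    """Per-voxel eigenvalues (descending) and matching eigenvectors."""

    eigenvalues: np.ndarray  # (X, Y, Z, 3), lambda1 >= lambda2 >= lambda3
    eigenvectors: np.ndarray  # (X, Y, Z, 3, 3); [..., :, i] is the i-th eigenvector
    affine: np.ndarray


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ],
        axis=1,
    )


def _beta_to_tensors(beta: np.ndarray) -> np.ndarray:
    """(7, N) coefficients -> (N, 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:7]
    out = np.empty((beta.shape[1], 3, 3))
    out[:, 0, 0] = dxx
    out[:, 1, 1] = dyy
    out[:, 2, 2] = dzz
    out[:, 0, 1] = out[:, 1, 0] = dxy
    out[:, 0, 2] = out[:, 2, 0] = dxz
    out[:, 1, 2] = out[:, 2, 1] = dyz
    return out


def _spd_mask(tensors: np.ndarray) -> np.ndarray:
    m1 = tensors[..., 0, 0]
    m2 = tensors[..., 0, 0] * tensors[..., 1, 1] - tensors[..., 0, 1] ** 2
    m3 = np.linalg.det(tensors)
    return (m1 > 0) & (m2 > 0) & (m3 > 0)


def fit_tensor(dwi: DwiDataset, method: str = "lls") -> DiffusionTensorField:
    """Fit the diffusion tensor in every voxel.

    Requires at least 7 volumes including one b = 0.  Signals are clamped at a
    small fraction of the reference S0 before the log, so background or
    noise-nulled voxels cannot produce -inf.
    """
    if method not in ("lls", "wls"):
        raise ValueError(f"unknown fit method {method!r}")
    gtab = dwi.gradient_table
    if len(gtab) < 7 or not np.any(gtab.b0_mask):
        raise ValueError("tensor fit needs >= 7 volumes including >= 1 b=0 volume")
    X = design_matrix(gtab.bvals, gtab.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate gradient scheme: design matrix is rank deficient")
    s0_ref = float(np.max(dwi.signal[..., gtab.b0_mask]))
    clamp = max(_SIGNAL_CLAMP_FRACTION * s0_ref, np.finfo(float).tiny)
    shape = dwi.signal.shape[:3]
    y = np.log(np.maximum(dwi.signal.reshape(-1, len(gtab)), clamp)).T  # (nvol, nvox)
    beta = np.linalg.pinv(X) @ y  # OLS, all voxels at once
    if method == "wls":
        beta = _wls_pass(X, y, beta)
    tensors = _beta_to_tensors(beta).reshape(shape + (3, 3))
    s0 = np.exp(beta[0]).reshape(shape)
    return DiffusionTensorField(tensors, s0, dwi.affine.copy(), _spd_mask(tensors))


def _wls_pass(X: np.ndarray, y: np.ndarray, beta0: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """Second pass weighted by the squared predicted signal, chunked by voxel."""
    nvox = y.shape[1]
    beta = np.empty_like(beta0)
    for start in range(0, nvox, chunk):
        sl = slice(start, min(start + chunk, nvox))
        w = np.exp(X @ beta0[:, sl]) ** 2  # (nvol, nchunk)
        Xw = X[None, :, :] * w.T[:, :, None]  # (nchunk, nvol, 7)
        lhs = np.einsum("cnk,nj->ckj", Xw, X)  # X^T W X
        rhs = np.einsum("cnk,nc->ck", Xw, y[:, sl])  # X^T W y
        beta[:, sl] = np.linalg.solve(lhs, rhs[..., None])[..., 0].T
    return beta


def eigensystem(field: DiffusionTensorField) -> TensorEigensystem:
    """Sorted eigendecomposition with a deterministic eigenvector sign fix.

    Eigenvalues descend; each eigenvector's largest-magnitude component is
    made positive.
    """
    vals, vecs = np.linalg.eigh(field.tensors)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    dominant = np.argmax(np.abs(vecs), axis=-2, keepdims=True)
    signs = np.sign(np.take_along_axis(vecs, dominant, axis=-2))
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return TensorEigensystem(vals, vecs, field.affine.copy())


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_from_tensors(tensors: np.ndarray) -> np.ndarray:
    """FA straight from tensor invariants (no eigendecomposition).

    FA = sqrt(3/2 ||D - MD I||_F^2 / ||D||_F^2); identical to the eigenvalue
    formula because the Frobenius norm is rotation invariant.
    """
    tr = np.trace(tensors, axis1=-2, axis2=-1)
    md = tr / 3.0
    frob2 = np.sum(tensors**2, axis=(-2, -1))
    dev2 = frob2 - 3.0 * md**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.maximum(dev2, 0.0) / frob2)
    fa = np.where(frob2 > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(eigsys: TensorEigensystem) -> ScalarMap:
    return ScalarMap(fa_from_eigenvalues(eigsys.eigenvalues), eigsys.affine.copy(), name="FA")


def md_map(eigsys: TensorEigensystem) -> ScalarMap:
    return ScalarMap(eigsys.eigenvalues.mean(axis=-1), eigsys.affine.copy(), name="MD")


def axis_diffusivity_maps(field: DiffusionTensorField) -> tuple[ScalarMap, ScalarMap, ScalarMap]:
    """Dx, Dy, Dz: the tensor diagonal in the image frame (right-left,
    anterior-posterior, inferior-superior diffusivity)."""
    t = field.tensors
    return (
        ScalarMap(t[..., 0, 0].copy(), field.affine.copy(), name="Dx"),
        ScalarMap(t[..., 1, 1].copy(), field.affine.copy(), name="Dy"),
        ScalarMap(t[..., 2, 2].copy(), field.affine.copy(), name="Dz"),
    )


def color_fa_map(eigsys: TensorEigensystem, fa: ScalarMap) -> np.ndarray:
    """(X, Y, Z, 3) RGB = |v1| * FA; red = x, green = y, blue = z."""
    v1 = eigsys.eigenvectors[..., :, 0]
    rgb = np.abs(v1) * fa.data[..., None]
    return np.clip(rgb, 0.0, 1.0)
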