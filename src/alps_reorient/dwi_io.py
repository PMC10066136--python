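"""NIfTI-1 dataset I/O with FSL-dialect `bvals`/`bvecs` sidecars."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import read_fsl_gradients, write_fsl_gradients
from .grids import ScalarMap
from .phantom import DwiDataset


def write_dataset(dwi: DwiDataset, out_dir, basename: str = "dwi") -> dict[str, Path]:
    """Write a 4-D NIfTI plus `bvals`/`bvecs` text sidecars.

    Signal is stored as 32-bit float; the round trip is lossless at that
    precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": out_dir / f"{basename}.nii.gz",
        "bvals": out_dir / f"{basename}.bvals",
        "bvecs": out_dir / f"{basename}.bvecs",
    }
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine)
    nib.save(img, paths["dwi"])
    write_fsl_gradients(dwi.gradient_table, paths["bvals"], paths["bvecs"])
    return paths


def read_dataset(dwi_path, bvals_path=None, bvecs_path=None) -> DwiDataset:
    dwi_path = Path(dwi_path)
    stem = dwi_path.name.removesuffix(".gz").removesuffix(".nii")
    if bvals_path is None:
        bvals_path = dwi_path.parent / f"{stem}.bvals"
    if bvecs_path is None:
        bvecs_path = dwi_path.parent / f"{stem}.bvecs"
    img = nib.load(dwi_path)
    signal = np.asarray(img.get_fdata(), dtype=np.float64)
    if signal.ndim != 4:
        raise ValueError(f"{dwi_path} is not a 4-D image")
    gtab = read_fsl_gradients(bvals_path, bvecs_path)
    if len(gtab) != signal.shape[-1]:
        raise ValueError(
            f"image has {signal.shape[-1]} volumes but gradient files describe {len(gtab)}"
        )
    return DwiDataset(signal, gtab, np.asarray(img.affine, dtype=float))


def write_scalar_map(smap: ScalarMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(smap.data.astype(np.float32), smap.affine), path)
    return path


def read_scalar_map(path, name: str = "") -> ScalarMap:
    img = nib.load(path)
    return ScalarMap(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine), name=name)


def write_label_map(labels: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), path)
    return path
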