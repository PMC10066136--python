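"""Spherical ROI placement and the ALPS / ro-ALPS index.

The DTI-ALPS index is the diffusivity contrast

    ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc),

where each component is the mean of the left and right 5 mm-diameter spherical
ROI means: x-axis diffusivity in the projection- and association-fiber ROIs
over y-axis diffusivity in the projection ROI and z-axis diffusivity in the
association ROI.  The perivascular spaces at the lateral-ventricle level run
right-left (x), perpendicular to both tracts, so diffusivity along x relative
to the tract-perpendicular axes is read as perivascular fluid movement.  The
reoriented variant (ro-ALPS) applies the identical formula to the reoriented
axis-diffusivity maps.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .grids import ImageGrid, ScalarMap
from .phantom import ASSOC_L, ASSOC_R, PROJ_L, PROJ_R

ROI_LABELS = ("proj_L", "proj_R", "assoc_L", "assoc_R")
_ROI_REGION = {"proj_L": PROJ_L, "proj_R": PROJ_R, "assoc_L": ASSOC_L, "assoc_R": ASSOC_R}
DEFAULT_ROI_RADIUS_MM = 2.5  # 5 mm diameter spheres


@dataclass(frozen=True)
class Roi:
    label: str
    center: tuple[float, float, float]  # world mm
    radius: float = DEFAULT_ROI_RADIUS_MM

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass(frozen=True)
class RoiSet:
    """The four ALPS ROIs: projection/association x left/right."""

    rois: tuple[Roi, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")

    def __getitem__(self, label: str) -> Roi:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def __iter__(self):
        return iter(self.rois)


def spherical_roi_mask(
    center,
    radius: float,
    grid: ImageGrid,
    radius_scale: float = 1.0,
) -> np.ndarray:
    """Boolean mask of voxels whose *centre* lies within radius*radius_scale.

    The criterion is centre-within-radius in world mm; a hand-painted brush
    can differ, so ``radius_scale`` emulates tighter or looser brushes.
    """
    if radius * radius_scale <= 0:
        raise ValueError("ROI radius must be positive")
    center = np.asarray(center, dtype=float)
    pts = grid.voxel_centers_world()
    d2 = np.sum((pts - center) ** 2, axis=1)
    mask = (d2 <= (radius * radius_scale) ** 2).reshape(grid.shape)
    if not mask.any():
        raise ValueError(
            f"ROI at {tuple(center)} (radius {radius} mm) contains no voxel centres"
        )
    return mask


def roi_mean(smap: ScalarMap, mask: np.ndarray, validity: np.ndarray | None = None) -> float:
    """Arithmetic mean of the map over valid masked voxels."""
    if validity is None:
        validity = smap.validity
    effective = mask if validity is None else (mask & validity)
    if not effective.any():
        raise ValueError("ROI has no valid voxels (fell outside the resampled field of view)")
    return float(smap.data[effective].mean())


@dataclass(frozen=True)
class AlpsInputs:
    """The four bilateral component means (mm^2/s)."""

    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dz_assoc: float

    def __post_init__(self) -> None:
        vals = (self.dx_proj, self.dx_assoc, self.dy_proj, self.dz_assoc)
        if not all(np.isfinite(vals)):
            raise ValueError("ALPS inputs must be finite")


@dataclass(frozen=True)
class AlpsResult:
    index: float
    inputs: AlpsInputs
    voxel_counts: dict[str, int]
    variant: str  # "original" | "reoriented"


def compute_alps(
    inputs: AlpsInputs,
    voxel_counts: dict[str, int] | None = None,
    variant: str = "original",
) -> AlpsResult:
    """ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)."""
    denominator = (inputs.dy_proj + inputs.dz_assoc) / 2.0
    if denominator <= 0:
        raise ValueError("ALPS denominator mean(Dy_proj, Dz_assoc) must be positive")
    numerator = (inputs.dx_proj + inputs.dx_assoc) / 2.0
    return AlpsResult(numerator / denominator, inputs, voxel_counts or {}, variant)


def place_default_rois(
    labels: np.ndarray,
    affine: np.ndarray,
    radius: float = DEFAULT_ROI_RADIUS_MM,
) -> RoiSet:
    """ROI centres at the world-mm centroids of the four fiber regions."""
    grid = ImageGrid(labels.shape, affine)
    pts = grid.voxel_centers_world()
    flat = labels.reshape(-1)
    rois = []
    for label in ROI_LABELS:
        sel = flat == _ROI_REGION[label]
        if not sel.any():
            raise ValueError(f"label map has no voxels for region {label!r}")
        center = pts[sel].mean(axis=0)
        rois.append(Roi(label, tuple(center), radius))
    return RoiSet(tuple(rois))


def jitter_roi_set(roi_set: RoiSet, sd_mm: float, seed) -> RoiSet:
    """Displace each centre by i.i.d. zero-mean Gaussian noise per axis.

    Emulates a rater re-identifying the sites; sd 0 returns identical centres.
    """
    if sd_mm < 0:
        raise ValueError("jitter sd must be >= 0")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sd_mm, size=(len(roi_set.rois), 3)) if sd_mm > 0 else np.zeros(
        (len(roi_set.rois), 3)
    )
    return RoiSet(
        tuple(
            replace(roi, center=tuple(np.asarray(roi.center) + off))
            for roi, off in zip(roi_set.rois, offsets)
        )
    )


def alps_from_maps(
    dx: ScalarMap,
    dy: ScalarMap,
    dz: ScalarMap,
    roi_set: RoiSet,
    variant: str = "original",
    radius_scale: float = 1.0,
    hemisphere: str = "both",
) -> AlpsResult:
    """Sample the four ROIs on axis-diffusivity maps and form the index.

    Left and right ROI means are averaged first (the bilateral mean), then the
    four components enter the formula; ``hemisphere`` restricts to a single
    side for sensitivity checks.
    """
    if hemisphere not in ("both", "L", "R"):
        raise ValueError("hemisphere must be 'both', 'L' or 'R'")
    grid = dx.grid
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    component_map = {"proj": (dx, dy), "assoc": (dx, dz)}
    sides = ("L", "R") if hemisphere == "both" else (hemisphere,)
    for tract in ("proj", "assoc"):
        x_vals, other_vals = [], []
        x_map, other_map = component_map[tract]
        for side in sides:
            roi = roi_set[f"{tract}_{side}"]
            mask = spherical_roi_mask(roi.center, roi.radius, grid, radius_scale)
            counts[roi.label] = int(mask.sum())
            x_vals.append(roi_mean(x_map, mask))
            other_vals.append(roi_mean(other_map, mask))
        means[f"dx_{tract}"] = float(np.mean(x_vals))
        means["dy_proj" if tract == "proj" else "dz_assoc"] = float(np.mean(other_vals))
    inputs = AlpsInputs(
        means["dx_proj"], means["dx_assoc"], means["dy_proj"], means["dz_assoc"]
    )
    return compute_alps(inputs, counts, variant)


# -- RoiSet text I/O (label, x, y, z, radius per line) --------------------

def write_roi_set(roi_set: RoiSet, path) -> None:
    lines = ["# label x_mm y_mm z_mm radius_mm"]
    for roi in roi_set:
        x, y, z = roi.center
        lines.append(f"{roi.label} {x:.6g} {y:.6g} {z:.6g} {roi.radius:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_roi_set(path) -> RoiSet:
    rois = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed ROI line: {line!r}")
        label, x, y, z, radius = parts[0], *map(float, parts[1:])
        rois.append(Roi(label, (x, y, z), radius))
    return RoiSet(tuple(rois))
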