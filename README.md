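# alps-reorient

Rotation-robust computation of the DTI-ALPS perivascular index on synthetic
diffusion-MRI phantoms.

## The problem

Diffusion tensor image analysis along the perivascular space (DTI-ALPS) reads
glymphatic-style interstitial fluid movement out of an ordinary DTI scan.  At
the level of the lateral-ventricle body, the medullary veins — and the
perivascular spaces around them — run right-left (x), perpendicular to both
the projection fibers (inferior-superior, z) and the association fibers
(anterior-posterior, y) that flank them.  The index is the diffusivity
contrast

```
ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)
```

where each `D•` is the mean of a bilateral pair of 5 mm spherical ROI means on
the axis-diffusivity maps (the diagonal of the fitted diffusion tensor in the
image frame).  Because the formula is written in *image* axes, it silently
assumes the head was scanned in a neutral position: a chin-up (x-axis) or
neck (z-axis) rotation rotates the tensor frame, mixes Dy/Dz with the other
diagonal entries, and changes the index with no change in physiology.

This package re-implements, from first principles, the reorientation remedy:
register each subject's FA map to a template with a six-degree-of-freedom
rigid transform (rotation + translation, never scaling), carry the *tensor*
field into the template frame by conjugating every voxel tensor with the
rotation (`D' = R D R^T`, the vector-data registration step), and compute the
same ratio — the reoriented index, ro-ALPS — from the reoriented diffusivity
maps `ro-Dx, ro-Dy, ro-Dz`.

Because real cohort data are not needed to validate the *mechanism*, the
package ships a synthetic periventricular DWI phantom with exact tensor
ground truth: piecewise-constant fiber slabs with the ALPS geometry, a CSF
ventricle, peripheral white-matter structure for registration, controllable
head rotation about any axis, the standard single-tensor forward model
`S = S0 exp(-b g^T D g)` over a 64-direction b=1000 s/mm² scheme, and Rician
noise.  Every stage of the pipeline is therefore testable against closed-form
arithmetic.

## Worked example

```python
import numpy as np
import alps_reorient as ar

template = ar.build_template()            # unrotated phantom, 64x64x32 @ 2.5 mm
subject = ar.run_single_subject(
    ar.RotationSpec((15.0, 0.0, 0.0)),    # 15 deg chin-up rotation
    template=template, snr=np.inf,        # noiseless
)
print(f"original ALPS   {subject.original.index:.4f}")
print(f"reoriented ALPS {subject.reoriented.index:.4f}")
print(f"registration residual {subject.registration_error_deg:.2f} deg")
```

prints

```
original ALPS   1.1778
reoriented ALPS 1.3750
registration residual 0.09 deg
```

The unrotated phantom's index is exactly `(0.55+0.55)/(0.40+0.40) = 1.375` by
construction.  A 15° chin-up rotation mixes the tensor's y and z axes, so the
original pipeline measures `Dy' = cos²15°·0.40 + sin²15°·1.40 ≈ 0.467 ×10⁻³
mm²/s` in the projection ROIs and the index drops to `0.55/0.467 ≈ 1.178` —
a ~14% artifact from head pose alone.  The reoriented pipeline estimates the
rigid pose from the FA maps (here to within a tenth of a degree), rotates the
tensor field back, and recovers 1.375.

The same machinery drives shell commands (`alps-reorient simulate / fit /
reorient / alps / stats / sweep / cohort / retest`) and the narrative
scripts in `examples/`.

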