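# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not show.

## The phantom

The phantom is a stylised axial block of the lateral-ventricle level, built
in world RAS millimetres on a centred isotropic grid (default 64×64×32 at
2.5 mm — the emulated acquisition matrix and voxel size; experiments use a
32×32×16 crop of the same geometry to bound runtime).  Regions, all
piecewise-constant in tensor value:

| region | extent (mm) | tensor diagonal (×10⁻³ mm²/s) |
|---|---|---|
| ventricle (CSF) | \|x\|<7.5, \|y\|<15, \|z\|<10 | 3.0 isotropic |
| projection fibers (L/R) | 7.5<\|x\|<22.5 | (0.55, 0.40, 1.40) |
| association fibers (L/R) | 22.5<\|x\|<37.5 | (0.55, 1.40, 0.40) |
| background | elsewhere | 0.80 isotropic |

plus four peripheral white-matter marker structures (anterior, posterior,
superior, inferior slabs with distinct anisotropic tensors).  Tensor values
are literature-typical for 3 T white matter and CSF, not fitted to any
dataset; the perivascular signature is that Dxx (0.55) exceeds the
cross-fiber eigenvalue (0.40) in both fiber regions, which fixes the
unrotated index at exactly (0.55+0.55)/(0.40+0.40) = 1.375.  No conclusion
in the test suite depends on the specific diffusivities, only on the
contrasts and invariances they induce.

Two geometry decisions matter numerically:

- **ROI safety margins.**  Fiber slabs are 15 mm wide and ROI centres sit at
  the region centroids, ≥ 6 mm from every boundary.  Trilinear resampling
  during reorientation reaches at most one voxel diagonal (≈ 4.3 mm), so
  reoriented ROI voxels can never blend CSF for rotations ≤ 20°, and the
  closed-form index values hold to interpolation precision.
- **Marker structures for registration.**  An FA image of a homogeneous box
  carries almost no information about small rotations: on a coarse lattice a
  5° rotation of tissue within ~18 mm of the axis does not move a single
  voxel-centre label, and thin lattice-aligned slabs produce rasterised
  "terraces" whose apparent tilt is quantised by about (voxel/lever-arm)
  radians.  Real FA maps have structure everywhere, which is what makes
  FA-template registration work.  The markers emulate that: long lever arms
  (up to ±36 mm), several independent boundaries, slants that are never
  parallel to the lattice, and deliberate anterior/posterior and
  superior/inferior asymmetry to kill spurious optima.  They sit ≥ 10 mm from
  the ALPS ROIs and never enter the index.

Head rotation is *active*: the rotated phantom's voxel at world point p
carries the tensor R·D(R⁻¹(p−c)+c−t)·Rᵀ.  Region membership at the pre-image
point is evaluated in the continuous region geometry (nearest region, no
interpolation), so the rotated field remains an exact piecewise-constant
oracle; evaluating the continuous geometry rather than re-sampling the
rasterised label map avoids a double quantisation that would otherwise bias
the rendered pose by up to a degree.

## Acquisition and noise

The emulated protocol is 64 motion-probing-gradient directions at
b = 1000 s/mm² plus one b = 0 volume, S0 = 1000.  The scanner's direction
table is not public; directions come from electrostatic-repulsion relaxation
of a seeded random start on the sphere (antipodally symmetric energy,
projected gradient descent, 300 iterations), with a deterministic spherical
Fibonacci lattice as an alternative.  Noise is Rician,
S' = √((S+n₁)² + n₂²) with σ = S0/SNR and SNR 30 by default — typical for
3 T white matter; the reference acquisition's noise level is not
characterised, so SNR is an explicit simulation parameter.

## Tensor fit

Classical log-linear least squares (the `dtifit` model): ln S regressed on
(1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz).  Signals are
clamped at 10⁻⁶·S0 before the log.  OLS is the default because it is exact
on noiseless data (the fit-exactness test requires max |D̂−D| < 10⁻¹⁰ mm²/s);
a weighted variant (weights = squared predicted signal, one re-weighting
pass) is available and beats OLS in mean-squared error at SNR 30.  Voxels
with negative eigenvalues after a noisy fit are kept as fitted but flagged;
ROI means use values as fitted.  FA is computed from tensor invariants
(Frobenius norms), which is algebraically identical to the eigenvalue
formula and avoids an eigendecomposition in the registration path.

## Registration and reorientation

Six-parameter rigid registration maximises normalised cross-correlation
(NCC) between the template FA and the resampled subject FA.  NCC replaces
the correlation ratio a general-purpose tool would use because both images
are the same modality; the divergence is validated by the recovery tests
(noiseless error < 0.5°, SNR-30 error < 1.0° over ±5–20° rotations about x
and z).  Numerical details that proved load-bearing:

- The cost is evaluated on a *fixed* mask (template FA > 0.05, dilated
  3 voxels, optionally strided).  Letting the evaluation set follow the
  transform's field of view biases the optimum by ~1° through corner
  clipping.
- Both images are pre-smoothed (Gaussian, σ = 1 voxel) to damp the
  rasterisation ripple of sharp region boundaries.
- Search is a coarse exhaustive grid over rotations (default ±30° in 5°
  steps, each candidate paired with the centre-of-mass translation) followed
  by Powell refinement.  Everything is deterministic.  Experiment-scale runs
  use a documented faster profile (±24° in 6° steps, subsampled cost,
  capped Powell evaluations); its residual error (median ≈ 1°, rarely up to
  ~5°) enters the index only quadratically (sin²ε), i.e. < 0.01 index units.

Reorientation resamples the six tensor-component maps into the template grid
(trilinear; rigid transforms never average across the rotation, so linear
interpolation of components is appropriate and no log-Euclidean machinery is
needed) and conjugates each voxel tensor with the transform's rotation,
D' = R D Rᵀ — eigenvalues, FA and MD are preserved to machine precision.
The template in the synthetic pipeline is the unrotated phantom's noiseless
FA map, standing in for a population FA template; any template NIfTI can be
substituted for real data.  The reorientation target grid defaults to the
template grid; the rater study writes reoriented maps on a 2× supersampled
(1.25 mm) grid, mirroring the coarse-native/fine-template resolution
asymmetry of FA-template pipelines in practice (2.5 mm acquisitions
registered to a 1 mm template).

## ROIs and the index

ROIs are 5 mm-diameter spheres; a voxel belongs to an ROI iff its centre
lies within the radius (a `radius_scale` knob emulates tighter hand-painted
brushes — reported voxel counts of manual ROIs are not reproducible from any
single lattice criterion, and nothing downstream depends on exact counts).
Automatic placement puts centres at region centroids; manual world-mm
coordinates are accepted for real data.  Left and right ROI means are
averaged first, then the four bilateral components enter the ratio.  The
denominator must be positive; a single-hemisphere mode exists for
sensitivity checks.

## Reliability statistics

ICC comes from the two-way ANOVA mean squares; the default form is two-way
random effects, absolute agreement, single measurement (ICC(2,1)) — the
standard choice for inter-rater reliability — with one-way and consistency
variants selectable, and the model is always named in results.  Weighted κ
uses linear disagreement weights by default (quadratic selectable).  The
F test is the plain two-sided variance-ratio test applied to the paired
index samples as if they were independent — the procedure this package
re-creates, reported as such.  Bland-Altman limits are bias ± 1.96·SD of differences.  All
p-values are two-sided at α = 0.05.  Each statistic is verified in the test
suite against an independent route (brute-force ANOVA sums, pingouin,
scikit-learn, scipy).

## Simulated studies

The cohort generator draws, per subject: a head pose (40% neutral with ≤ 2°
jitter; 30% chin-up x-rotation and 30% neck z-rotation, angle uniform in
5–20°, translations ≤ 3 mm — the 10° "moderate" threshold and all degree
values are declared operationalisations of a visual grading, not estimates
of it); a physiological perivascular scale (multiplicative on fiber-region
Dxx, sd 0.04, giving a true-index spread of ≈ 0.055 — a conservative
fraction of published cohort spreads; without true between-subject variance
reliability coefficients would be meaningless); and a noise realisation at
SNR 30.  The rater study re-places all four ROIs with i.i.d. 1.5 mm Gaussian
centre jitter per rater and repeat, independently on the original and
reoriented maps, with 16 subjects per rotation group (rotated groups draw
10–15°).  The test-retest study keeps each subject's physiology and draws a
fresh pose and noise per session (n = 23).  Experiments run on the 32×32×16
grid with the full 65-volume scheme; per-subject seeds derive
deterministically from the master seed.

## What the phantom does and does not show

Passing tests demonstrate the *mechanism*: rotation of the tensor frame
biases the original index exactly as the closed-form arithmetic predicts,
x-rotation is worse than z-rotation for this geometry, rigid FA registration
recovers the pose, and reorientation restores the index and the reliability
orderings (reoriented ICC > original ICC in every rotation group; smaller
cohort variance; tighter test-retest agreement).  The phantom does not
emulate real anatomy's curvature or partial-volume mixtures, physiological
noise, eddy/susceptibility distortion, imperfect manual ROI placement beyond
Gaussian jitter, or any disease effect — so the simulated ICC/F magnitudes
characterise the pipeline under these idealised conditions, not values to
expect on clinical data.

## Known limitations

- Registration accuracy is validated for rotations ≤ 30° about x and z with
  small translations; larger or strongly coupled poses are outside the
  search range by default.
- The rotated-phantom renderer is exact but aliased (piecewise-constant by
  construction); registration residuals of a few tenths of a degree reflect
  that rendering, not the optimiser.
- The forward model is single-tensor and single-shell; no multi-shell or
  non-Gaussian extensions.
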