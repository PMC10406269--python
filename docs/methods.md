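# Methods

This note records the models, assumptions, parameter choices and known
limitations behind `cedflow`. The package quantifies the distribution of an
infusate delivered by convection-enhanced delivery (CED) into a brainstem
tumor, from paired pre/post-infusion MRI: the change in segmented lesion
volume between sessions is the imaging estimate of the infusate volume of
distribution (Vd), to be compared against the infused volume (Vi) recorded
by the pump.

## Conventions

- World frame is RAS in millimetres. Grids are defined at voxel centres:
  the NIfTI affine maps 0-based index `(i, j, k)` to the centre of that
  voxel.
- Rigid transforms are parameterized by Euler angles in degrees, applied in
  x, y, z order (`R = Rz @ Ry @ Rx`), plus a translation in mm. A
  "resampling transform" maps target-grid world coordinates into the source
  image's world frame; composition therefore chains target-to-source maps.
- ADC is carried in units of 1e-6 mm²/s: normal white matter near 700–900,
  pontine tumor near 1000–1900, CSF near 3000.

## ADC computation

Two-point DWI model: `ADC = (1e6 / b) * ln(S_b0 / S_b)` with b = 1000 s/mm².
Voxels where either signal is non-positive are set to 0 and flagged invalid
in the volume's validity mask; negative ADC values (the b-weighted signal
exceeding the b0 signal, a noise artefact) are clipped to 0. The validity
mask propagates through resampling and into all downstream statistics.

## Segmentation

A semi-automated active-contour-style procedure:

1. **Speed image.** A dual-threshold admissibility field in [0, 1]: 1
   strictly inside the intensity band, 0 at and beyond both thresholds,
   with a linear ramp of width 5% of the threshold gap inside each edge.
2. **Seeded growth.** Spherical seed bubbles are grown by repeated
   6-connected dilation restricted to admissible voxels (speed > 0.5), with
   a morphological closing pass (cadence set by the smoothing weight:
   < 0.25 never, 0.25–0.75 every second step, > 0.75 every step) and the
   result restricted to the connected component(s) containing the seeds.
   Closing never removes an admitted voxel, so the evolution is monotone;
   on a noise-free scene it converges to exactly the admissible connected
   component, making volumes exact up to voxelization. Convergence is a
   fixpoint by default (`convergence_fraction = 0`): an early-stop fraction
   would systematically stop the front a step short and bias volumes low.
3. **Automatic thresholds (midpoint rule).** The interactive workflow sets
   the lower threshold near the NAWM level and the upper near the CSF
   level, then adjusts until the contour sits on the lesion edge. The
   automated surrogate samples the lesion level in a small ball around the
   seed point and sets `lower = (NAWM + lesion) / 2` and
   `upper = (lesion + CSF) / 2`, with CSF estimated as the 99.8th intensity
   percentile of the image. A threshold midway between two tissue levels
   crosses a partial-volume-blurred edge at its half-height, so the
   segmented boundary lands on the true interface and volumes are unbiased
   to first order in the blur width. A threshold placed *at* the NAWM
   level instead would claim roughly half the blurred shell around the
   lesion and overestimate volumes by tens of percent.

A segmentation that touches the image border is flagged (not failed) as a
possible leak through the band.

## Registration and subtraction

Alignment of the post-infusion ADC map onto the pre-infusion ADC grid
composes three rigid (6-DOF) stages — ADC(post)→T1W(post) and
T1W(pre)→ADC(pre) within sessions (Mattes mutual information, 32 bins,
cross-modality), T1W(post)→T1W(pre) between sessions (mean squares,
same-modality) — into one transform applied with a single trilinear
interpolation. Rigid only: between-session change in the brainstem is the
signal of interest, and any scaling freedom would absorb part of it. T1W
anchors the inter-session stage because the infusate leaves T1W signal
essentially unchanged.

The optimizer is multi-resolution (shrink factors 4/2/1) regular-step
gradient descent with metric sampling on a regular 25% grid with a fixed
sampling seed, so registration is deterministic for fixed inputs.

The subtraction map is the voxelwise post-minus-pre ADC difference on the
pre grid. Voxels whose difference exceeds a noise floor `tau` form the
bright region — the presumed infusate distribution. `tau` defaults to 3x
the SD of the difference inside the NAWM reference region, where no
infusate-driven change is expected. The reported Vd applies a
partial-volume refinement: voxels above half the plateau difference (the
median difference over the supra-threshold region), which places the
boundary at the half-height of the blurred difference profile. Analysis is
restricted to parenchyma — a DWI-b0 signal floor removes the air
background and the ADC upper threshold removes CSF — because the ADC
difference is noise-dominated in both.

## Quantification

Per case and session: T2W segmentation volume, its T2seg/NAWM signal ratio
(lesion mean divided by the NAWM reference mean, normalizing across scans
and scanners), ADC segmentation volume, and mean segmentation ADC. The
changes `dV_T2` and `dV_ADC` (post minus pre) estimate Vd; coverage is
`100 * dV_T2 / V_T2_pre`.

Cohort statistics: column means and sample (n−1) SDs, two-sided paired
t-tests on the four pre/post pairs, and Pearson correlations of each change
against Vi. p-values are computed through the regularized incomplete beta
function, `P(|T| > t) = I_{ν/(ν+t²)}(ν/2, 1/2)`; the test suite verifies
both tests against an independent implementation and against
extended-precision direct evaluation to 1e-10.

A 12-patient reference table ships with the package; its internal
arithmetic (dV and coverage consistency) is validated on load. Note that
the correlation of `dV_ADC` vs Vi recomputed from the rounded per-case rows
is ≈ 0.68 and its p-value ≈ 0.016 — the table's declared headline value of
0.76 is not reproducible from the rounded rows and is deliberately not a
target anywhere in this package.

## Synthetic data (phantom)

Cases are built from analytic ellipsoids so every stage can be verified
against exact truth:

- a triaxial "brain" ellipsoid (semiaxes 42/36/27 mm) with a 2.5 mm CSF
  rim and a pair of off-centre CSF "ventricles" — the triaxiality plus the
  asymmetric ventricles make all six rigid degrees of freedom identifiable
  for registration;
- a tumor ellipsoid (default semiaxes 20/17/14 mm, ≈ 20 ml) of elevated
  T2W signal and diffusivity inside normal-appearing white matter;
- post infusion, the tumor is soaked and a rim of infusate extends beyond
  the margin. The rim is grown voxel-by-voxel in order of distance from
  the infusate centre to **exactly** the voxel count of Vi, so the
  ground-truth volume change equals Vi by construction — the 1:1
  relationship the analysis is designed to recover;
- the post session is rendered analytically at rigidly transformed world
  coordinates, so at zero noise it equals the transformed scene exactly
  with no interpolation residue;
- DWI is synthesised at b = 0 and 1000 from per-tissue diffusivities, so
  ADC computation recovers the scene levels;
- partial-volume blur: Gaussian, sigma 0.425 voxels (FWHM 1 voxel);
- Rician noise: each voxel `x` becomes `sqrt((x + n1)² + n2²)` with
  independent zero-mean Gaussians of SD sigma (default 5, i.e. SNR 20 at
  the NAWM T2W level) — Gaussian in the complex channels, Rayleigh in
  air.

Default tissue levels put the pre/post T2 lesion/NAWM ratios at 2.6/6.3 and
lesion diffusivity at 1100/1750, the dynamic range seen for pontine tumors
before and after infusion. T1W carries no infusate ("soaked") level, so it
is infusion-invariant and honestly anchors the inter-session registration.

**Realism limits.** The phantom is piecewise-constant with ellipsoidal
geometry: no texture, no anatomical heterogeneity, no infusion-driven mass
effect or tissue deformation (the inter-session change is purely rigid plus
the soaked region), no susceptibility or eddy-current distortion in DWI,
and noise is spatially white. Recovery numbers on the phantom are
therefore upper bounds on clinical performance; the phantom's purpose is to
verify the pipeline's correctness against known truth, not to simulate a
scanner.

## Numerical choices

- Resampling uses `scipy.ndimage.map_coordinates` (trilinear or nearest);
  out-of-domain voxels are filled with 0 and excluded from the validity
  mask. ADC maps are clipped at 0 after interpolation.
- Volumes are `voxel count x |det(3x3 affine block)| / 1000` ml — exact
  for the voxelized masks, no mesh estimates.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; per-image noise seeds are derived from the case seed, and cohort
  generation derives per-case seeds from the cohort seed. Reruns with the
  same configuration are byte-identical, which the manifest checksums
  record.

## Limitations

- Rigid-only alignment cannot represent infusion-driven swelling; on
  clinical data a residual non-rigid mismatch would blur the subtraction
  map near the lesion boundary.
- The threshold-based segmentation assumes the lesion is brighter than
  NAWM and darker than CSF on the segmented image; lesions isointense to
  either fail the automatic threshold rule (raised explicitly).
- The subtraction-based Vd is sensitive to the parenchyma restriction;
  without it, air-background ADC noise dominates the positive region.
- The half-plateau refinement assumes a roughly uniform difference inside
  the soaked region; strongly graded infusate concentration would bias it.
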