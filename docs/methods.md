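# Methods

## Problem and model

Bright blood-flow artifacts in T1-weighted head MRI — hyperintense
tubular structures where flow suppression failed — conflict with a
template in which blood is dark. They corrupt brain extraction and bias
both linear and nonlinear registration to the template. The package
implements a conservative heuristic that (i) locates likely artifact
voxels, (ii) replaces them with the subject's mean CSF intensity
through a soft blend ("deblooding"), and (iii) quantifies what the
artifacts did to registration by comparing transform chains driven by
the original versus the deblooded scan.

Detection combines four kinds of evidence:

1. **Blood probability map (BPM).** Co-registered MR-angiography-like
   volumes are averaged in template space and normalised by the global
   maximum. Thresholded at **0.1** and intersected with the template
   brain mask it yields the *bloodless mask* used to keep registration
   from fitting artifacts; thresholded at **0.2** it marks major
   vessels. Boundary convention: a voxel stays "bloodless" when its
   probability is strictly below threshold; vessel membership is
   inclusive (`>=`). The thresholds are inclusive-on-the-vessel-side by
   design: a boundary voxel is treated as vessel, which is the
   conservative choice for registration masking.
2. **Tissue classes and white-matter grouping.** A 3-class Gaussian
   mixture (quantile-initialised, hence deterministic for a given seed)
   labels CSF < GM < WM by increasing component mean. Blood is brighter
   than WM, so artifact voxels land in the top (WM) component. True WM
   forms one large connected component; WM-labelled voxels *outside*
   that main group (26-connectivity, ties broken to the group holding
   the smallest linear voxel index) are artifact candidates.
3. **Gradient difference.** Gaussian-smoothed gradient magnitude (FWHM
   1 mm) of the subject minus that of the template resampled into
   subject space, blurred at FWHM 2 mm. Shared anatomy cancels; edges
   unique to the subject — vessels — survive. "High" is the 90th
   percentile of the within-brain distribution (75th during
   expansion), so the gate adapts to contrast.
4. **Vascular continuity.** Blood forms connected tubes, not isolated
   voxels: the seed set (all gates at full strength) is grown by
   iterative 6-connected dilation, admitting neighbours that pass
   relaxed gradient (75th percentile) and probability (0.05) gates, to
   a fixed point or at most 10 passes.

After a refinement re-registration with the brain-minus-blood mask,
vessels absorbed into the main WM group are recovered where the BPM is
at least 0.2, the gradient gate passes, **and** the voxel is
hyperintense relative to main-group WM (robust z >= 6 against the
median/MAD of main-group intensities). The brightness gate encodes the
rule that a voxel without sufficient intensity is never blood; without
it, the 2-mm blur of the gradient evidence and the width of the BPM
leak onto ordinary WM bordering a vessel — measured on phantoms, that
produced false positives inside the true WM body, which the gate
eliminates while vessels (z around 20) pass untouched. A final
expansion pass may then grow into the main group under the same
brightness + probability gates. `recovery_brightness_z = 6` was set
from the contrast physics: artifacts are tens of percent brighter than
WM while WM fluctuations are a few percent, and with ~3e5 main-group
voxels a 3-sigma gate admits hundreds of chance outliers whereas
6 sigma admits none while sitting far below the artifact contrast.

Deblooding: weights `w = blur(dilate(blood_mask))` (6-connected dilate
x2, Gaussian blur FWHM 1.5 mm; clipped to [0, 1]); output
`t1·(1−w) + csf·w` with `csf` the mean intensity over CSF-labelled
voxels. The dilate/blur pair trades off full replacement (weight near
1 on every detected voxel; a warning fires when a mask too thin for
the blur drops below the 0.99 floor) against preserving the anatomy
around the vessel: a wider dilation recolours a multi-millimetre
collar of genuine tissue to uniform CSF — a mild version of the
do-no-harm failure the conservativeness rule exists to prevent — and
measurably degrades downstream registration of the deblooded scan.
The pipeline also passes the brain mask as a weight support, so CSF is
only ever blended into blood or brain tissue, never into the
background air next to a periphery artifact. Voxels with `w = 0` are
returned bit-exact.

Mask hygiene: the extracted brain mask may contain artifact bumps on
its periphery. After detection, periphery-connected blood components
are trimmed from the mask — but only their genuinely protruding part
(voxels outside the morphological closure, radius 4 voxels, of the
non-blood core); the within-envelope half of a surface vessel is brain
territory and stays.

## Registration

Affine (6/9/12 parameters; default 9 = translation + rotation +
log-scale) maximises a 64-bin joint-histogram mutual information with
a fully deterministic multi-resolution compass search (shrinks 4/2/1,
Gaussian anti-aliasing at 0.5·shrink voxels, per-level step halving).
A Pearson cross-correlation objective is available as `metric="cc"`;
it is the objective family of the classic hierarchical linear tools
and, unlike MI, is genuinely degraded by bright blood overlying dark
template tissue (MI gives the artifact its own joint-histogram cell
and barely moves). The *evaluation* linear chain therefore uses
correlation by default (`evaluation_linear_metric`), while the
pipeline's internal, bloodless-masked registrations keep MI.

Nonlinear refinement is a demons-style iteration: force
`(f − m∘φ)·∇f / (‖∇f‖² + (f − m∘φ)²/s̄²)`, capped at 2 mm per step,
fluid smoothing sigma 1.0 voxel on the update and elastic smoothing on
the accumulated field, over a shrink pyramid (default 8/4/2/1 at
40/30/20/10 iterations). Forces are restricted to the dilated fixed
mask — structure far outside it (field-of-view edges of a resampled
scan) must not drive the warp. The displacement field lives in world
millimetres on the fixed grid. The field is accepted only if (a) its
*signed* analytic Jacobian determinant is positive everywhere
(progressive smoothing, then failure) and (b) the masked similarity
did not get worse: by default mutual information (so the MI-monotone
property holds for every completed registration); for the
impact-mapping registration between two nearly identical volumes the
gate is masked SSD, because any warp's interpolation blur slightly
lowers a global-histogram MI even when alignment genuinely improves.

Transforms: a world-to-world affine (moving -> fixed) optionally
followed by a deformation in fixed space; resampling pulls back through
`p_moving = A⁻¹(x + u(x))`. The Jacobian/displacement analysis applies
to the deformation part only — the affine would add a spatially
constant term and the maps are meant to show local effects.

## Evaluation protocol

Per subject, two chains: register the original (bloody, bias-corrected)
scan to the template, and the deblooded scan to the template — linear,
then linear + nonlinear. Each transform is applied to the *deblooded*
scan (so only the transforms are compared) and to the chain's own brain
mask (the raw extraction for the bloody chain, the trimmed mask for the
deblooded one). Metrics: Dice of the warped mask against the template
mask; MI (nats, 64 bins, unnormalised) of the warped volume against the
template inside its mask. Cohort aggregation: per-metric mean and
sample variance for each arm plus a two-tailed paired t-test
(`t = mean(d)/(sd(d)/√n)`, sample sd, df = n−1; all-zero differences
give (0, 1), zero variance with nonzero mean the limiting (±inf, 0)).
The summary table has exactly four metric rows (linear/nonlinear x
Dice/MI). Impact maps: the bloody-chain result is nonlinearly
registered to the deblooded-chain result; per-subject |Jacobian| and
displacement-magnitude maps are reduced by voxelwise maximum across
the cohort, with overlay masks at |det| > 2 and displacement > 5 mm
(interpreted as millimetres; the determinant is unitless).

Because the MI estimator behind any particular published analysis is
never fully specified, absolute MI values are comparable only within
this package; between-arm *ordering* is the meaningful output.

## Synthetic phantoms

The generator emulates the data regime the method targets, with ground
truth for every quantity the tests need:

- **Template** (default 96³ voxels at 1 mm): nested ellipsoids —
  CSF shell, GM ribbon, WM core with a mild angular perturbation
  ("gyrification", amplitude 0.05) — plus CSF clefts standing in for
  the longitudinal and Sylvian fissures, carved only outside the deep
  core so WM remains a single connected component. Intensities CSF 30,
  GM 65, WM 100 (arbitrary units).
- **Vessels**: five polyline arcs — through the longitudinal fissure,
  both Sylvian clefts, along the inferior surface, and a
  sagittal-sinus-like arc on the posterior-superior surface. Tube
  radius 1.5 mm for the parenchymal arcs and 2.3x that for the two
  surface arcs, whose curves sit at 0.995 of the envelope so the tubes
  protrude — dural-sinus-scale periphery artifacts are what contaminate
  extracted brain masks and drive the mask-overlap part of the
  analysis. Tube voxels are set to intensity 140 (bright, above WM).
- **Subjects**: the template pulled through a known affine (defaults:
  a few mm/deg/percent; cohorts draw uniformly within ±4 mm, ±3°,
  ±2% scale) and a smooth random warp (5³ control grid, maximum
  displacement 3 mm, rejected if the signed Jacobian is not positive),
  multiplied by a bias field (product of per-axis degree-2
  polynomials, total deviation ±10%), vessels rasterised along the
  forward-mapped curves, and additive Gaussian noise sigma 2 (Rician
  optional). Clean and bloody volumes share bias and noise, so they
  differ exactly on the vessel support.
- **MRA cohort**: jittered copies of the vessel tree (global offset
  sigma 1 mm per curve, tube radius 2 mm for parenchymal / scaled for
  surface arcs), bright tubes on dark background, lightly blurred.

What the phantoms do **not** model: real cortical folding, partial
volume beyond interpolation, susceptibility or motion artifacts,
scanner-specific intensity distributions, or vasculature beyond five
vessels. Passing tests therefore demonstrate the mechanics and the
conservativeness contract of the method under controlled conditions,
not clinical-grade segmentation accuracy.

## Numerical choices

- FWHM-to-sigma: `sigma = FWHM / (2·sqrt(2·ln 2))`, applied per axis in
  mm and converted to voxels.
- Voxel indices 0-based; world coordinates RAS; displacements always
  world mm.
- Both-empty Dice defined as 1.0 (identical masks overlap perfectly).
- Finite differences use central differences in mm with one-sided
  stencils at boundaries (this is what `numpy.gradient` provides).
- Bias correction: alternating deterministic 3-means assignment and a
  robust (median-centred, MAD-trimmed) least-squares fit of the
  class-residual against a tensor-product Legendre basis (degree <= 2
  per axis), 6 iterations, in the log domain; masked mean preserved.
  A plain polynomial fit of log-intensity absorbs anatomy (the WM core
  looks like a bowl-shaped field) and was rejected for violating the
  do-no-harm requirement on bias-free input.
- Brain extraction threshold: 0.2 of the robust (p2-p98) intensity
  range; an Otsu split on head images with a dominant background drops
  the dim CSF shell.
- Determinism: every stochastic step (classification init, phantom
  generation, cohort subject draws) is seeded; registrations are
  deterministic by construction (compass search, fixed schedules).
  Cohorts derive per-subject seeds as `seed + index`.

## Problem sizes and schedules

Cohort-scale runs use `fast_config()`: slightly reduced affine
halvings/sweeps, demons pyramid 8/4/2 (no full-resolution level) and
elastic sigma 3.0 voxels instead of 1.5. The stronger regularisation
for the evaluation chain mirrors the behaviour of heavily regularised
production tools: an aggressive low-regularisation warp can "hide" mask
junk by compressing periphery artifacts into the envelope, rewarding
exactly the distortions the analysis is meant to expose. The default
config keeps the finer schedule (pyramid to full resolution, elastic
1.5), which recovers a known 3 mm warp to ~0.75 mm mean error on
noise-free phantoms.

The shipped analyses use a 10-phantom cohort at 96³ for the
registration-impact replication and 20 phantoms for the
conservativeness/sensitivity check; measured end-to-end on one CPU
these take a few minutes each.

## Known limitations

- The in-repo registration engines are compact stand-ins: accurate on
  phantoms, but not substitutes for production tools on clinical data
  (no BSpline/SyN parameterisation, single-channel similarity only).
- The conservativeness guarantee is demonstrated on phantoms; on real
  data it depends on the BPM's quality and the classifier's behaviour
  with pathology.
- `expansion_relax_*`, `recovery_brightness_z` and the replacement
  dilate/blur defaults quantify qualitative notions ("relatively
  high", "bright", "dilate then blur"); they are config-exposed and
  not claimed to be anyone's published values.
- Impact maps reflect *between-chain* differences; with a global linear
  component in that difference, high-displacement voxels are spread
  over the brain rather than confined to vessel neighbourhoods.
- Of the four cohort metrics, the nonlinear mask Dice carries no
  usable signal at phantom scale: after the nonlinear stage both
  chains' mask boundaries sit near their overlap ceiling, and an
  artifact-laden scan can even *profit* in pure mask overlap when the
  warp compresses its periphery artifacts into the envelope. Measured
  across cohort seeds the between-arm difference is zero-centred
  (|mean| below 0.001, p > 0.3) and its sign flips with the seed and
  with minor method details; it is also not monotone in the
  regularisation strength. The corresponding directional-significance
  test is expected to fail and is retained as an honest negative. The
  linear Dice and MI rows and the nonlinear MI row are the robust
  findings.
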