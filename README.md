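# bloodless

Detection and removal of blood-flow artifacts in T1-weighted brain MRI,
and quantification of their impact on registration to a template.

When flow suppression fails or is absent, moving blood leaves bright
tubular artifacts in T1-weighted scans — along the interhemispheric and
Sylvian fissures, around the brain base, in the dural sinuses. A
template built from properly suppressed data has *dark* blood in those
places, so the artifacts corrupt brain extraction and pull both linear
and nonlinear registration away from the correct alignment. This
package is for neuroimaging researchers who need to (a) find those
artifact voxels without ever sacrificing real tissue, (b) replace them
with CSF-like intensity ("deblooding", mimicking successful blood
suppression), and (c) measure what the artifacts were doing to their
registrations.

## Method in brief

A **blood probability map** `P` is built by averaging co-registered
MR-angiography volumes in template space and normalising by the global
maximum. Artifact detection then combines four heuristics:

1. voxels with high `P` are likely blood (`P >= 0.1` gates candidacy,
   `P >= 0.2` marks major vessels);
2. bright voxels outside the main connected body of white matter are
   suspect — a 3-class Gaussian-mixture segmentation (CSF < GM < WM)
   puts hyperintense blood in its top component, and true WM forms one
   big 26-connected group;
3. voxels strong in the blurred **gradient-difference map**
   `G_2mm * (‖∇(G_1mm * subject)‖ − ‖∇(G_1mm * template)‖)`
   carry edges the template does not have — vessels;
4. blood is vascular, not isolated: seeds grow by iterative dilation
   while the (relaxed) evidence gates keep holding.

Detected voxels are blended to the subject's mean CSF intensity:

    deblooded = t1 · (1 − w) + csf · w,   w = blur(dilate(blood_mask))

The impact analysis registers each subject twice (original vs deblooded
scan driving the registration), always applies the resulting transforms
to the *deblooded* scan, and compares: Dice overlap of the transformed
brain mask with the template mask, mutual information with the
template, paired t-tests across the cohort, and cohort-maximum
|Jacobian determinant| and displacement maps of the warp between the
two chains.

Everything runs on synthetic phantoms with known ground truth (tissue
compartments, vessel tubes, affine + smooth nonlinear misalignments,
bias fields, noise) generated by the package itself; no external data
is required. See `docs/methods.md` for the full model, parameter
defaults and limitations.

## Worked example

```sh
python examples/02_detect_and_deblood.py
```

prints, for a seeded phantom with ~4700 artifact voxels:

```
detected blood voxels: 4134 (truth: 4666, sensitivity 0.89)
false positives outside truth vessels: 0
estimated CSF mean: 32.3
mean intensity over vessels after deblooding: 32.3 (was 139.8)
```

Read: the pipeline found 89% of the true vessel voxels and invented
none, and the bright artifacts (about 140, well above white matter at
100) were pulled down to the estimated CSF level (about 32; the blur
margin of the replacement also covers the few undetected voxels).
`examples/01_make_phantom.py` shows the generator,
`examples/03_registration_impact.py` the cohort analysis with its four
metric rows and deformation maps.

A thin CLI mirrors the library (`bloodless phantom|probmap|preprocess|
register|transform|run|run-cohort ...`); the Python API is the primary
interface.

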