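"""Detect blood-flow artifacts in one scan and replace them with CSF.

Runs the full single-subject flow (registration to the template with a
bloodless mask, bias correction, tissue classification, the artifact
heuristics, blended CSF replacement) and compares the detected mask to
the phantom's ground truth.
"""

import warnings

import numpy as np

from bloodless.config import fast_config
from bloodless.phantom import (PhantomSpec, generate_mra_cohort,
                               generate_subject, generate_template)
from bloodless.pipeline import make_template_bundle, run_subject

warnings.filterwarnings("ignore")

spec = PhantomSpec(rng_seed=3)
template = generate_template(spec)
bundle = make_template_bundle(
    template.t1, template.brain_mask, generate_mra_cohort(spec, 10, seed=1003)
)
subject = generate_subject(spec, template)

result = run_subject(subject.t1_bloody, bundle, fast_config(),
                     with_evaluation=False)

truth = subject.truth_blood_mask.astype_bool()
detected = result.blood_mask.astype_bool()
sensitivity = (detected & truth).sum() / truth.sum()
print(f"detected blood voxels: {int(detected.sum())} "
      f"(truth: {int(truth.sum())}, sensitivity {sensitivity:.2f})")
print(f"false positives outside truth vessels: {int((detected & ~truth).sum())}")
print(f"estimated CSF mean: {result.csf_mean:.1f}")
tube_after = result.deblooded.data[truth].mean()
print(f"mean intensity over vessels after deblooding: {tube_after:.1f} "
      f"(was {result.corrected.data[truth].mean():.1f})")
# A good run detects nearly all vessel voxels, adds none elsewhere, and
# pulls the bright artifact intensity down to the CSF level.
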