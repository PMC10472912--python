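"""Quantify how blood-flow artifacts bend registration to a template.

Processes a small phantom cohort twice — registering the original
(bloody) and the deblooded scan of each subject to the template — and
compares the two transform chains: Dice overlap of the transformed
brain masks with the template mask, mutual information of the
transformed (always deblooded) volume with the template, paired t-tests
across subjects, and cohort-maximum |Jacobian| / displacement maps of
the warp between the two results.

A cohort of 4 keeps this example quick (~2 min); the acceptance script
runs the full 10-subject analysis.
"""

import warnings

import numpy as np

from bloodless.config import fast_config
from bloodless.phantom import (PhantomSpec, generate_mra_cohort,
                               generate_subject, generate_template,
                               random_subject_spec)
from bloodless.pipeline import make_template_bundle, run_cohort

warnings.filterwarnings("ignore")

base = PhantomSpec()
template = generate_template(base)
bundle = make_template_bundle(
    template.t1, template.brain_mask, generate_mra_cohort(base, 10, seed=1234)
)
rng = np.random.default_rng(11)
subjects = []
for i in range(4):
    spec = random_subject_spec(base, rng)
    subjects.append((f"sub-{i}", generate_subject(spec, template).t1_bloody))

cohort = run_cohort(subjects, bundle, fast_config())
s = cohort.summary
for metric, label in [("dice_lin", "linear mask Dice"),
                      ("mi_lin", "linear similarity (MI)"),
                      ("dice_nl", "nonlinear mask Dice"),
                      ("mi_nl", "nonlinear similarity (MI)")]:
    print(f"{label:26s} bloody {s.mean_bloody[metric]:.4f}  "
          f"deblooded {s.mean_deblooded[metric]:.4f}  "
          f"p={s.p_value[metric]:.3g}")
brain = bundle.brain_mask.astype_bool()
print(f"max |Jacobian det| across cohort (brain): "
      f"{cohort.det_map.data[brain].max():.3f}")
print(f"max displacement across cohort (brain): "
      f"{cohort.disp_map.data[brain].max():.2f} mm")
# Higher deblooded means say the artifacts were degrading alignment; the
# deformation maps show where the bloody-driven registrations had to be
# bent to agree with the deblooded-driven ones.
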