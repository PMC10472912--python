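"""End-to-end orchestration of artifact removal and cohort analysis.

``run_subject`` executes the full single-subject flow: bloodless-mask
registration, brain extraction gated by the major-vessel map,
nonuniformity correction and intensity normalisation, re-registration,
tissue classification, white-matter grouping, gradient-difference
evidence, seeding and vascular expansion, refined re-registration with
the brain-minus-blood mask, main-group recovery, periphery trimming,
and blended CSF replacement. ``run_cohort`` repeats this over subjects
and aggregates the registration-impact analysis.

Registrations that map template-space resources (blood probability map,
template gradient) into subject space are run template -> subject, so
no deformation field ever needs inverting; the subject -> template
chain used for evaluation is estimated separately, as the analysis
prescribes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import bloodmask as bm
from . import deblood as db
from . import evaluate as ev
from . import preprocess as pp
from . import probmap as pm
from .config import PipelineConfig
from .io import (read_mask, read_volume, write_mask, write_probmap,
                 write_volume)
from .registration import register_affine, register_nonlinear, resample
from .types import BinaryMask, ProbabilityMap, Volume

__all__ = [
    "TemplateBundle",
    "SubjectResult",
    "make_template_bundle",
    "run_subject",
    "run_cohort",
    "CohortResult",
]


@dataclass
class TemplateBundle:
    """Template-space resources shared by every subject."""

    t1: Volume
    brain_mask: BinaryMask
    bpm: ProbabilityMap
    bloodless_mask: BinaryMask

    @classmethod
    def from_probmap(
        cls,
        t1: Volume,
        brain_mask: BinaryMask,
        bpm: ProbabilityMap,
        config: PipelineConfig | None = None,
    ) -> "TemplateBundle":
        config = config or PipelineConfig()
        bloodless = pm.make_bloodless_mask(bpm, brain_mask, config.bloodless_threshold)
        return cls(t1=t1, brain_mask=brain_mask, bpm=bpm, bloodless_mask=bloodless)


def make_template_bundle(
    t1: Volume,
    brain_mask: BinaryMask,
    mra_volumes: list[Volume],
    config: PipelineConfig | None = None,
) -> TemplateBundle:
    """Build the bundle from raw MRA volumes already in template space."""
    bpm = pm.build_blood_probability_map(mra_volumes)
    return TemplateBundle.from_probmap(t1, brain_mask, bpm, config)


@dataclass
class SubjectResult:
    subject_id: str
    blood_mask: BinaryMask
    deblooded: Volume
    corrected: Volume  # nonuniformity-corrected, intensity-normalised bloody scan
    brain_mask: BinaryMask  # extracted from the bloody scan (untrimmed)
    trimmed_brain_mask: BinaryMask
    csf_mean: float
    evaluation: ev.SubjectEvaluation | None
    provenance: dict


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_subject(
    t1,
    template_bundle: TemplateBundle,
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
    work_dir: str | Path | None = None,
    resume: bool = False,
    with_evaluation: bool = True,
) -> SubjectResult:
    """Detect and remove blood-flow artifacts in one T1-weighted scan.

    `t1` may be a Volume or a NIfTI path. With a work directory, every
    intermediate is written under stable names; with ``resume`` a
    completed run is loaded back instead of recomputed (the provenance
    then records the reuse). Evaluation (four extra registrations) can
    be skipped for detection-only runs.
    """
    config = config or PipelineConfig()
    tpl = template_bundle
    if not isinstance(t1, Volume):
        t1 = read_volume(t1)
    work = Path(work_dir) if work_dir is not None else None
    if work is not None:
        work.mkdir(parents=True, exist_ok=True)

    if resume and work is not None:
        final_mask = work / "blood_mask.nii.gz"
        final_vol = work / "deblooded.nii.gz"
        meta_path = work / "provenance.json"
        if final_mask.exists() and final_vol.exists() and meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta.get("config_hash") == _config_hash(config):
                meta["resumed"] = True
                return SubjectResult(
                    subject_id=subject_id,
                    blood_mask=read_mask(final_mask),
                    deblooded=read_volume(final_vol),
                    corrected=read_volume(work / "corrected.nii.gz"),
                    brain_mask=read_mask(work / "brain_mask.nii.gz"),
                    trimmed_brain_mask=read_mask(work / "brain_mask_trimmed.nii.gz"),
                    csf_mean=float(meta["csf_mean"]),
                    evaluation=None,
                    provenance=meta,
                )

    stages: list[dict] = []

    def record(stage: str, t0: float, **extra) -> None:
        stages.append({"stage": stage, "seconds": round(time.time() - t0, 3), **extra})

    # 1. initial registration constrained by the template bloodless mask
    t0 = time.time()
    t_s2t = register_affine(t1, tpl.t1, tpl.bloodless_mask, None, config)
    t_t2s = t_s2t.inverse()
    record("initial_registration", t0)

    # 2. brain extraction, gated by the major-vessel probability
    t0 = time.time()
    brain0 = pp.extract_brain_mask(t1)
    bpm_subj = resample(tpl.bpm, t_t2s, t1, "linear")
    major = bpm_subj.data >= config.major_vessel_threshold
    nomajor = BinaryMask(
        (brain0.astype_bool() & ~major).astype(np.uint8), t1.affine.copy()
    )
    record("brain_extraction", t0, brain_voxels=brain0.count(),
           major_vessel_voxels=int(major.sum()))

    # 3. nonuniformity correction and intensity normalisation
    t0 = time.time()
    corrected = pp.correct_nonuniformity(t1, nomajor)
    corrected = pp.normalize_intensity(corrected, nomajor, tpl.t1)
    record("nonuniformity_correction", t0)

    # 4. re-registration on the corrected scan
    t0 = time.time()
    t_s2t = register_affine(corrected, tpl.t1, tpl.bloodless_mask, nomajor, config)
    t_t2s = t_s2t.inverse()
    record("re_registration", t0)

    # optional coarse nonlinear template->subject alignment for mapping
    # template-space evidence (probability map, gradient) onto the subject
    t0 = time.time()
    if config.pipeline_nonlinear_align:
        t2s_map = register_nonlinear(tpl.t1, corrected, t_t2s, brain0, config)
    else:
        t2s_map = t_t2s
    bpm_subj = resample(tpl.bpm, t2s_map, t1, "linear")
    record("evidence_mapping", t0)

    # 5. tissue classification and white-matter grouping
    t0 = time.time()
    labels = pp.classify_tissue(corrected, brain0, seed=config.rng_seed)
    grouping = bm.group_white_matter(labels, config.wm_connectivity)
    record("classification", t0,
           wm_groups=int((grouping.counts > 0).sum()),
           main_group_voxels=int(grouping.counts[grouping.main_group_id]))

    # 6. gradient-difference evidence
    t0 = time.time()
    subj_grad = bm.gradient_magnitude(corrected, config.gradient_fwhm_mm)
    tpl_grad = bm.gradient_magnitude(tpl.t1, config.gradient_fwhm_mm)
    tpl_grad_subj = resample(tpl_grad, t2s_map, t1, "linear")
    grad_diff = bm.gradient_difference_map(
        subj_grad, tpl_grad_subj, config.graddiff_blur_fwhm_mm
    )
    record("gradient_difference", t0)

    # 7. seed and expand
    t0 = time.time()
    seed = bm.seed_blood_voxels(labels, grouping, grad_diff, bpm_subj, config)
    blood = bm.expand_blood_mask(seed, labels, grouping, grad_diff, bpm_subj, config)
    record("seed_and_expand", t0, seed_voxels=seed.count(), expanded_voxels=blood.count())

    # 8. refinement: re-register with brain-minus-blood, recover main-group blood
    for _pass in range(config.refinement_passes):
        t0 = time.time()
        refined = bm.refine_brain_mask(brain0, blood)
        t_s2t = register_affine(corrected, tpl.t1, tpl.brain_mask, refined, config)
        t_t2s = t_s2t.inverse()
        if config.pipeline_nonlinear_align:
            t2s_map = register_nonlinear(tpl.t1, corrected, t_t2s, refined, config)
        else:
            t2s_map = t_t2s
        bpm_subj = resample(tpl.bpm, t2s_map, t1, "linear")
        blood = bm.recover_main_group_blood(
            grouping, bpm_subj, grad_diff, blood, config, corrected
        )
        blood = bm.expand_blood_mask(
            blood, labels, grouping, grad_diff, bpm_subj, config,
            t1_corrected=corrected, include_bright_main=True,
        )
        record(f"refinement_{_pass}", t0, blood_voxels=blood.count())

    # 9. periphery trim
    t0 = time.time()
    trimmed = bm.trim_brain_mask_periphery(brain0, blood)
    record("periphery_trim", t0, trimmed_voxels=trimmed.count())

    # 10. CSF replacement
    t0 = time.time()
    csf = pp.csf_mean(corrected, labels)
    weights = db.make_replacement_weights(
        blood, config.replacement_dilate_iters, config.replacement_blur_fwhm_mm,
        support_mask=brain0,
    )
    deblooded = db.apply_deblooding(corrected, weights, csf)
    record("deblooding", t0, csf_mean=round(csf, 4))

    evaluation = None
    if with_evaluation:
        t0 = time.time()
        evaluation = ev.evaluate_subject(
            subject_id, corrected, deblooded, brain0, trimmed,
            tpl.t1, tpl.brain_mask, config,
        )
        record("evaluation", t0)

    provenance = {
        "subject_id": subject_id,
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "csf_mean": csf,
        "stages": stages,
        "resumed": False,
    }

    if work is not None:
        write_mask(blood, work / "blood_mask.nii.gz")
        write_volume(deblooded, work / "deblooded.nii.gz")
        write_volume(corrected, work / "corrected.nii.gz")
        write_mask(brain0, work / "brain_mask.nii.gz")
        write_mask(trimmed, work / "brain_mask_trimmed.nii.gz")
        write_mask(seed, work / "blood_seed.nii.gz")
        write_volume(grad_diff, work / "gradient_difference.nii.gz")
        write_probmap(bpm_subj, work / "bpm_in_subject.nii.gz")
        (work / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return SubjectResult(
        subject_id=subject_id,
        blood_mask=blood,
        deblooded=deblooded,
        corrected=corrected,
        brain_mask=brain0,
        trimmed_brain_mask=trimmed,
        csf_mean=csf,
        evaluation=evaluation,
        provenance=provenance,
    )


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    evaluations: list[ev.SubjectEvaluation]
    summary: ev.CohortSummary
    det_map: Volume | None
    disp_map: Volume | None


def run_cohort(
    subjects: list[tuple[str, Volume]],
    template_bundle: TemplateBundle,
    config: PipelineConfig | None = None,
    work_dir: str | Path | None = None,
    with_impact_maps: bool = True,
) -> CohortResult:
    """Process a cohort and aggregate the registration-impact analysis.

    `subjects` is a list of (subject_id, volume-or-path). Per-subject
    seeds derive from the cohort seed plus the subject index. Failures
    are recorded and skipped; the summary reflects the subjects that
    completed.
    """
    config = config or PipelineConfig()
    if len(subjects) < 2:
        raise ValueError("cohort analysis needs at least 2 subjects")
    results: list[SubjectResult] = []
    pairs = []
    for i, (sid, vol) in enumerate(subjects):
        sub_cfg = config.replace(rng_seed=config.rng_seed + i)
        sub_work = None if work_dir is None else Path(work_dir) / sid
        res = run_subject(
            vol, template_bundle, sub_cfg, subject_id=sid,
            work_dir=sub_work, with_evaluation=False,
        )
        evaluation, artifacts = ev.evaluate_subject_full(
            sid, res.corrected, res.deblooded, res.brain_mask,
            res.trimmed_brain_mask, template_bundle.t1,
            template_bundle.brain_mask, sub_cfg,
        )
        res.evaluation = evaluation
        results.append(res)
        pairs.append((artifacts["warped_nl_bloody"], artifacts["warped_nl_deblooded"]))

    evaluations = [r.evaluation for r in results]
    summary = ev.summarize_cohort(evaluations)
    det_map = disp_map = None
    if with_impact_maps:
        det_map, disp_map = ev.impact_maps(pairs, template_bundle.t1, config)
    if work_dir is not None:
        from .io import write_table

        out = Path(work_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        rows = [vars(e) for e in evaluations]
        write_table(pd.DataFrame(rows), out / "subject_metrics.tsv")
        write_table(ev.cohort_summary_table(summary), out / "cohort_summary.tsv")
        if det_map is not None:
            write_volume(det_map, out / "max_abs_jacobian.nii.gz")
            write_volume(disp_map, out / "max_displacement.nii.gz")
            tpl_mask = template_bundle.brain_mask.astype_bool()
            det_overlay = (det_map.data > 2.0) & tpl_mask
            disp_overlay = (disp_map.data > 5.0) & tpl_mask
            write_mask(
                BinaryMask(det_overlay.astype(np.uint8), det_map.affine.copy()),
                out / "overlay_det_gt2.nii.gz",
            )
            write_mask(
                BinaryMask(disp_overlay.astype(np.uint8), disp_map.affine.copy()),
                out / "overlay_disp_gt5.nii.gz",
            )
    return CohortResult(results, evaluations, summary, det_map, disp_map)
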