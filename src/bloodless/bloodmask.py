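"""The blood-flow-artifact heuristics.

Artifact voxels are identified by combining four pieces of evidence:

(i)   a high value in the blood probability map (vessels live in
      predictable places);
(ii)  bright intensity outside the main body of white matter — the
      classifier puts hyperintense blood in its top (WM) component, but
      true WM forms one large connected group, so bright voxels in
      *other* WM-labelled groups are suspect;
(iii) strong values in the blurred gradient-difference map (edges
      present in the subject but absent from the template);
(iv)  vascular continuity — blood appears in connected tubular
      structures, so the seed set is grown by iterative dilation,
      admitting neighbours that still satisfy (slightly relaxed)
      versions of the evidence gates.

The design goal is conservativeness: a voxel of true main-body white
matter must never be relabelled as blood, because replacing real WM
with CSF intensity is far more damaging than leaving a little residual
artifact behind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import FWHM_TO_SIGMA, PipelineConfig
from .types import (WM, BinaryMask, ProbabilityMap, TissueLabels, Volume,
                    require_same_grid)

__all__ = [
    "WMGrouping",
    "gradient_magnitude",
    "gradient_difference_map",
    "group_white_matter",
    "seed_blood_voxels",
    "expand_blood_mask",
    "recover_main_group_blood",
    "refine_brain_mask",
    "trim_brain_mask_periphery",
]


@dataclass
class WMGrouping:
    """Connected components of WM-labelled voxels.

    ``label_grid`` is 0 outside WM; groups are numbered from 1. The main
    group is the largest; ties break to the group containing the
    smallest linear voxel index.
    """

    label_grid: np.ndarray
    main_group_id: int
    counts: np.ndarray  # counts[g] = voxel count of group g (index 0 unused)

    def main_mask(self) -> np.ndarray:
        return self.label_grid == self.main_group_id

    def off_main_wm(self) -> np.ndarray:
        return (self.label_grid > 0) & (self.label_grid != self.main_group_id)


def _sigma_vox(fwhm_mm: float, voxel_sizes: np.ndarray) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_sizes)


def gradient_magnitude(v: Volume, fwhm_mm: float = 1.0) -> Volume:
    """Gaussian-smoothed gradient magnitude, intensity units per mm.

    The volume is smoothed with a Gaussian of the given FWHM (per-axis
    sigma converted from mm to voxels), then central differences with
    mm spacing give the spatial gradient.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm must be positive")
    smoothed = ndimage.gaussian_filter(v.data, _sigma_vox(fwhm_mm, v.voxel_sizes))
    grads = np.gradient(smoothed, *v.voxel_sizes)
    mag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
    return Volume(mag, v.affine.copy())


def gradient_difference_map(
    subj_grad: Volume,
    template_grad_in_subject: Volume,
    blur_fwhm_mm: float = 2.0,
) -> Volume:
    """Blurred (subject - template) gradient difference.

    Edges shared with the template cancel; edges unique to the subject
    — blood vessels above all — survive and are strengthened by the
    blur. Values may be negative where template edges dominate.
    """
    require_same_grid(subj_grad, template_grad_in_subject, "gradient maps")
    diff = subj_grad.data - template_grad_in_subject.data
    out = ndimage.gaussian_filter(diff, _sigma_vox(blur_fwhm_mm, subj_grad.voxel_sizes))
    return Volume(out, subj_grad.affine.copy())


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def group_white_matter(labels: TissueLabels, connectivity: int = 26) -> WMGrouping:
    """Connected-component grouping of WM-labelled voxels."""
    wm = labels.mask_of(WM)
    if not wm.any():
        raise ValueError("no white-matter voxels to group")
    grid, n = ndimage.label(wm, structure=_structure(connectivity))
    counts = np.bincount(grid.ravel())
    counts[0] = 0
    top = counts.max()
    candidates = np.flatnonzero(counts == top)
    if candidates.size == 1:
        main = int(candidates[0])
    else:
        # tie-break: group containing the smallest linear voxel index
        flat = grid.ravel()
        positions = np.flatnonzero(np.isin(flat, candidates))
        main = int(flat[positions[0]])
    return WMGrouping(label_grid=grid, main_group_id=main, counts=counts)


def _graddiff_threshold(
    grad_diff: Volume, brain: np.ndarray, percentile: float
) -> float:
    if not brain.any():
        raise ValueError("empty brain mask")
    return float(np.percentile(grad_diff.data[brain], percentile))


def seed_blood_voxels(
    labels: TissueLabels,
    grouping: WMGrouping,
    grad_diff: Volume,
    bpm_subject: ProbabilityMap,
    config: PipelineConfig | None = None,
) -> BinaryMask:
    """Initial blood voxels: all four evidence gates at full strength.

    A voxel is seeded when it is WM-labelled, outside the main WM group,
    has a gradient-difference value at or above the configured
    percentile of the within-brain distribution, and a blood probability
    at or above the configured threshold.
    """
    config = config or PipelineConfig()
    require_same_grid(labels, grad_diff, "labels and gradient difference")
    require_same_grid(labels, bpm_subject, "labels and blood probability map")
    brain = labels.data > 0
    thr = _graddiff_threshold(grad_diff, brain, config.expansion_graddiff_percentile)
    seed = (
        grouping.off_main_wm()
        & (grad_diff.data >= thr)
        & (bpm_subject.data >= config.expansion_prob_threshold)
    )
    return BinaryMask(seed.astype(np.uint8), labels.affine.copy())


def expand_blood_mask(
    seed: BinaryMask,
    labels: TissueLabels,
    grouping: WMGrouping,
    grad_diff: Volume,
    bpm_subject: ProbabilityMap,
    config: PipelineConfig | None = None,
    t1_corrected: Volume | None = None,
    include_bright_main: bool = False,
) -> BinaryMask:
    """Grow the seed along the vascular structure by iterative dilation.

    Each pass dilates the current mask (6-connected) and accepts new
    voxels that satisfy the seed conditions with relaxed gradient and
    probability gates; iteration stops at a fixed point or after
    ``expansion_max_iters`` passes. The output always contains the seed.

    By default growth never touches the main WM group. With
    ``include_bright_main`` (used after main-group recovery, and
    requiring the corrected volume) a neighbour inside the main group
    is also accepted when it is hyperintense relative to the main-group
    intensity distribution and has relaxed blood-probability support —
    vessels partially absorbed into the WM body are completed without
    ever admitting normally-bright white matter.
    """
    config = config or PipelineConfig()
    require_same_grid(seed, labels, "seed and labels")
    current = seed.astype_bool()
    if not current.any():
        return BinaryMask(current.astype(np.uint8), seed.affine.copy())
    brain = labels.data > 0
    thr = _graddiff_threshold(
        grad_diff, brain, config.expansion_relax_graddiff_percentile
    )
    eligible = (
        grouping.off_main_wm()
        & (grad_diff.data >= thr)
        & (bpm_subject.data >= config.expansion_relax_prob_threshold)
    )
    if include_bright_main:
        if t1_corrected is None:
            raise ValueError("include_bright_main requires the corrected volume")
        main_vals = t1_corrected.data[grouping.main_mask()]
        center = np.median(main_vals)
        spread = 1.4826 * np.median(np.abs(main_vals - center))
        bright = t1_corrected.data >= center + config.recovery_brightness_z * max(
            spread, 1e-6
        )
        eligible |= (
            grouping.main_mask()
            & bright
            & (bpm_subject.data >= config.expansion_relax_prob_threshold)
        )
    structure = _structure(6)
    for _ in range(config.expansion_max_iters):
        candidates = ndimage.binary_dilation(current, structure=structure) & ~current
        accepted = candidates & eligible
        if not accepted.any():
            break
        current = current | accepted
    return BinaryMask(current.astype(np.uint8), seed.affine.copy())


def recover_main_group_blood(
    grouping: WMGrouping,
    bpm_subject: ProbabilityMap,
    grad_diff: Volume,
    current_blood: BinaryMask,
    config: PipelineConfig | None = None,
    t1_corrected: Volume | None = None,
) -> BinaryMask:
    """Catch artifacts absorbed into the main WM group.

    After the refined registration has improved the blood-probability
    alignment, main-group voxels sitting where the map is at or above
    the major-vessel threshold (and with supporting gradient evidence)
    are added to the blood mask. When the corrected volume is supplied,
    candidates must additionally be hyperintense relative to the WM
    component (a robust z-score against main-group intensities) —
    voxels without sufficient intensity are never blood, and this keeps
    ordinary WM bordering a vessel out of the mask even where the
    blurred gradient and probability evidence leak onto it. The result
    is a superset of the input.
    """
    config = config or PipelineConfig()
    require_same_grid(current_blood, bpm_subject, "blood mask and probability map")
    require_same_grid(current_blood, grad_diff, "blood mask and gradient difference")
    within_brain = grouping.label_grid > 0
    thr = _graddiff_threshold(
        grad_diff,
        within_brain if within_brain.any() else np.ones_like(within_brain),
        config.expansion_graddiff_percentile,
    )
    added = (
        grouping.main_mask()
        & (bpm_subject.data >= config.major_vessel_threshold)
        & (grad_diff.data >= thr)
    )
    if t1_corrected is not None and added.any():
        require_same_grid(current_blood, t1_corrected, "blood mask and volume")
        main_vals = t1_corrected.data[grouping.main_mask()]
        center = np.median(main_vals)
        spread = 1.4826 * np.median(np.abs(main_vals - center))
        bright = t1_corrected.data >= center + config.recovery_brightness_z * max(
            spread, 1e-6
        )
        added &= bright
    out = current_blood.astype_bool() | added
    return BinaryMask(out.astype(np.uint8), current_blood.affine.copy())


def refine_brain_mask(brain_mask: BinaryMask, blood_mask: BinaryMask) -> BinaryMask:
    """Brain mask minus identified blood voxels."""
    require_same_grid(brain_mask, blood_mask, "brain and blood masks")
    out = brain_mask.astype_bool() & ~blood_mask.astype_bool()
    if not out.any():
        raise ValueError("refined brain mask is empty (blood mask covers brain)")
    return BinaryMask(out.astype(np.uint8), brain_mask.affine.copy())


def trim_brain_mask_periphery(
    brain_mask: BinaryMask, blood_mask: BinaryMask
) -> BinaryMask:
    """Drop protruding periphery blood from the brain mask.

    Blood components (26-connected) touching the brain-mask boundary are
    artifacts sitting on the surface. Only their truly protruding part
    is removed: voxels of such components that fall inside the closed
    hull of the non-blood brain core are genuine brain-envelope
    territory and stay in the mask. The largest remaining component is
    kept so the mask stays connected.
    """
    require_same_grid(brain_mask, blood_mask, "brain and blood masks")
    brain = brain_mask.astype_bool()
    blood = blood_mask.astype_bool()
    if not blood.any():
        return brain_mask.copy()
    boundary = brain & ~ndimage.binary_erosion(brain)
    grid, n = ndimage.label(blood, structure=_structure(26))
    out = brain.copy()
    touching = np.unique(grid[boundary & (grid > 0)])
    if touching.size:
        periphery = np.isin(grid, touching)
        core = brain & ~blood
        lab, nc = ndimage.label(core, structure=_structure(26))
        if nc > 1:
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            core = lab == counts.argmax()
        core = ndimage.binary_fill_holes(core)
        core = ndimage.binary_closing(core, structure=_ball3(), iterations=1)
        core = ndimage.binary_fill_holes(core)
        out &= ~(periphery & ~core)
    lab, n2 = ndimage.label(out, structure=_structure(26))
    if n2 > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        out = lab == counts.argmax()
    return BinaryMask(out.astype(np.uint8), brain_mask.affine.copy())


def _ball3() -> np.ndarray:
    g = np.indices((9, 9, 9)) - 4
    return (g**2).sum(axis=0) <= 16
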