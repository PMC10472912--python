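"""Blood probability map construction and thresholding.

The map is the voxelwise mean of co-registered MRA-like volumes,
normalised by its global maximum so values lie in [0,1]. Thresholding
at 0.1 (combined with the template brain mask) gives the "bloodless"
registration mask; thresholding at 0.2 picks out the major vessels.
Boundary voxels count as vessel (strict `<` keeps a voxel bloodless),
the conservative choice for registration masking.
"""

from __future__ import annotations

import numpy as np

from .types import BinaryMask, ProbabilityMap, Volume, require_same_grid

__all__ = [
    "build_blood_probability_map",
    "make_bloodless_mask",
    "binarize_probmap",
]


def build_blood_probability_map(mra_in_template: list[Volume]) -> ProbabilityMap:
    """Average template-space MRA volumes and normalise by the global max.

    An all-zero input set yields an all-zero map (no division by zero).
    """
    if len(mra_in_template) < 1:
        raise ValueError("need at least one MRA volume")
    first = mra_in_template[0]
    acc = np.zeros_like(first.data)
    for v in mra_in_template:
        require_same_grid(first, v, "MRA volumes")
        if v.data.min() < 0:
            raise ValueError(
                f"MRA volumes must be non-negative (min={v.data.min():.4g})"
            )
        acc += v.data
    acc /= len(mra_in_template)
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    return ProbabilityMap(np.clip(acc, 0.0, 1.0), first.affine.copy())


def make_bloodless_mask(
    bpm: ProbabilityMap, brain_mask: BinaryMask, threshold: float = 0.1
) -> BinaryMask:
    """Brain mask minus likely-vessel voxels: keep where bpm < threshold."""
    require_same_grid(bpm, brain_mask, "probability map and brain mask")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    out = brain_mask.astype_bool() & (bpm.data < threshold)
    return BinaryMask(out.astype(np.uint8), brain_mask.affine.copy())


def binarize_probmap(bpm: ProbabilityMap, threshold: float = 0.2) -> BinaryMask:
    """Vessel membership mask: 1 where bpm >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    return BinaryMask((bpm.data >= threshold).astype(np.uint8), bpm.affine.copy())
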