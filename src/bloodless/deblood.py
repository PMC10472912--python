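"""CSF replacement ("deblooding").

Detected blood voxels are replaced by the subject's mean CSF intensity
through a soft weight map — the dilated, Gaussian-blurred blood mask —
so the inserted CSF blends smoothly into its surroundings:

    out = t1 * (1 - w) + csf * w

Voxels with w == 0 are untouched bit-exact; every output value lies
between the original intensity and the CSF mean.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .config import FWHM_TO_SIGMA
from .types import BinaryMask, ProbabilityMap, Volume, require_same_grid

__all__ = ["make_replacement_weights", "apply_deblooding"]


def make_replacement_weights(
    blood_mask: BinaryMask,
    dilate_iters: int = 1,
    blur_fwhm_mm: float = 2.0,
    support_mask: BinaryMask | None = None,
) -> ProbabilityMap:
    """Soft replacement weights: blur(dilate(blood mask)), clipped to [0,1].

    Dilation (6-connected) before blurring guarantees the original
    blood voxels stay saturated (w close to 1) after the blur; if the
    dilation radius is too small for the blur width a warning is
    emitted.

    With a support mask (typically the brain mask) the weights are
    zeroed outside ``support OR blood``: the dilated blur may blend CSF
    into the tissue around a vessel, but never paint CSF into the
    background air next to a periphery artifact.
    """
    data = blood_mask.astype_bool()
    if data.any() and dilate_iters > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        data = ndimage.binary_dilation(data, structure=structure, iterations=dilate_iters)
    w = data.astype(float)
    if blur_fwhm_mm > 0 and data.any():
        sigma = blur_fwhm_mm * FWHM_TO_SIGMA / blood_mask.voxel_sizes
        w = ndimage.gaussian_filter(w, sigma)
    w = np.clip(w, 0.0, 1.0)
    if support_mask is not None:
        require_same_grid(blood_mask, support_mask, "blood and support masks")
        allowed = support_mask.astype_bool() | blood_mask.astype_bool()
        w = np.where(allowed, w, 0.0)
    core = blood_mask.astype_bool()
    if core.any() and w[core].min() < 0.99:
        warnings.warn(
            "replacement weights fall below 0.99 on blood voxels; "
            "increase dilate_iters relative to the blur FWHM",
            stacklevel=2,
        )
    return ProbabilityMap(w, blood_mask.affine.copy())


def apply_deblooding(t1: Volume, w: ProbabilityMap, csf: float) -> Volume:
    """Blend the CSF mean into the volume under the weight map."""
    require_same_grid(t1, w, "volume and weights")
    if not np.isfinite(csf):
        raise ValueError("csf mean must be finite")
    out = t1.data.copy()
    sel = w.data > 0
    out[sel] = t1.data[sel] * (1.0 - w.data[sel]) + csf * w.data[sel]
    return Volume(out, t1.affine.copy())
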