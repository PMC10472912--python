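"""Preprocessing stand-ins: brain extraction, bias correction,
intensity normalisation, tissue classification.

These replace the heavyweight external tools a production pipeline
would call (BET-style extraction, N3-style nonuniformity correction,
a dedicated tissue classifier) with compact equivalents that honour the
same contracts: a single connected brain mask, a smooth multiplicative
field divided out with the masked mean preserved, a deterministic
3-class segmentation ordered CSF < GM < WM.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from .types import (BACKGROUND, CSF, GM, WM, BinaryMask, TissueLabels,
                    Volume, require_same_grid)

__all__ = [
    "extract_brain_mask",
    "correct_nonuniformity",
    "normalize_intensity",
    "classify_tissue",
    "csf_mean",
]


def extract_brain_mask(t1: Volume) -> BinaryMask:
    """Foreground threshold + largest component + closing + hole fill.

    The threshold is a BET-style fraction (0.2) of the robust intensity
    range (2nd-98th percentile), which keeps the dim CSF shell that a
    plain Otsu split tends to drop; the largest 26-connected component
    is then kept, morphologically closed (2-voxel ball) and hole-filled,
    yielding one connected head-interior mask.
    """
    data = t1.data
    if np.ptp(data) == 0:
        raise ValueError("empty foreground: image is constant")
    p2, p98 = np.percentile(data, (2.0, 98.0))
    thr = p2 + 0.2 * (p98 - p2)
    fg = data > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    lab, n = ndimage.label(fg, structure=structure)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    fg = lab == counts.argmax()
    ball = _ball(2)
    fg = ndimage.binary_closing(fg, structure=ball, iterations=1)
    fg = ndimage.binary_fill_holes(fg)
    lab, n = ndimage.label(fg, structure=structure)
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        fg = lab == counts.argmax()
    return BinaryMask(fg.astype(np.uint8), t1.affine.copy())


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    grid = np.indices((2 * r + 1,) * 3) - r
    return (grid**2).sum(axis=0) <= r**2


def _legendre_basis(coords: np.ndarray) -> np.ndarray:
    """Tensor-product Legendre basis, degree <= 2 per axis (27 columns)."""
    polys = []
    for ax in range(3):
        t = coords[:, ax]
        polys.append([np.ones_like(t), t, 1.5 * t**2 - 0.5])
    cols = []
    for i in range(3):
        for j in range(3):
            for k in range(3):
                cols.append(polys[0][i] * polys[1][j] * polys[2][k])
    return np.stack(cols, axis=1)


def _kmeans3(values: np.ndarray, iters: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 3-means on 1D data, quantile-initialised."""
    centers = np.percentile(values, (15.0, 50.0, 85.0)).astype(float)
    for _ in range(iters):
        assign = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
        new = centers.copy()
        for c in range(3):
            sel = assign == c
            if sel.any():
                new[c] = values[sel].mean()
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
    return centers, assign


def correct_nonuniformity(t1: Volume, mask: BinaryMask) -> Volume:
    """Estimate and remove a smooth multiplicative intensity field.

    Works in the log domain: alternately assigns masked voxels to three
    intensity classes (deterministic k-means) and fits the class-mean
    residual with a low-order (tensor-product degree-2) polynomial —
    the residual is the bias plus noise, so anatomy does not leak into
    the field on bias-free input. The masked mean is preserved.
    """
    require_same_grid(t1, mask, "volume and mask")
    msel = mask.astype_bool()
    if not msel.any():
        raise ValueError("mask is empty")
    vals = t1.data[msel]
    floor = max(np.percentile(vals[vals > 0], 1) * 0.05, 1e-6) if (vals > 0).any() else 1e-6
    log_i = np.log(np.maximum(vals, floor))

    idx = np.argwhere(msel).astype(float)
    span = np.array(t1.data.shape, dtype=float) - 1.0
    coords = 2.0 * idx / span - 1.0
    basis = _legendre_basis(coords)

    b = np.zeros_like(log_i)
    coef = np.zeros(basis.shape[1])
    for _ in range(6):
        corrected = log_i - b
        centers, assign = _kmeans3(corrected)
        # robust per-class centres: medians are immune to bright outliers
        robust = centers.copy()
        for c in range(3):
            sel = assign == c
            if sel.any():
                robust[c] = np.median(corrected[sel])
        resid = corrected - robust[assign]  # residual bias increment + noise
        # trim outliers (vessels, partial volume) so they cannot bend the fit
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = np.abs(resid - med) <= max(3.0 * 1.4826 * mad, 0.02)
        coef, _, rank, _ = np.linalg.lstsq(basis[keep], resid[keep], rcond=None)
        if rank < basis.shape[1]:
            raise ValueError(
                f"degenerate bias fit: design rank {rank} < {basis.shape[1]}"
            )
        b = b + basis @ coef

    out = t1.data.copy()
    field = np.exp(b)
    out[msel] = vals / field
    scale = vals.mean() / out[msel].mean()
    out[msel] *= scale
    return Volume(out, t1.affine.copy())


def normalize_intensity(t1: Volume, mask: BinaryMask, reference: Volume) -> Volume:
    """Linear rescale matching masked 10th/90th percentiles to the
    reference's (computed over reference voxels above zero)."""
    require_same_grid(t1, mask, "volume and mask")
    msel = mask.astype_bool()
    if not msel.any():
        raise ValueError("mask is empty")
    lo, hi = np.percentile(t1.data[msel], (10.0, 90.0))
    if hi <= lo:
        raise ValueError("zero intensity spread within mask")
    ref_vals = reference.data[reference.data > 0]
    if ref_vals.size == 0:
        ref_vals = reference.data.ravel()
    rlo, rhi = np.percentile(ref_vals, (10.0, 90.0))
    scale = (rhi - rlo) / (hi - lo)
    return Volume((t1.data - lo) * scale + rlo, t1.affine.copy())


def classify_tissue(t1_corrected: Volume, mask: BinaryMask, seed: int = 0) -> TissueLabels:
    """Three-class Gaussian-mixture segmentation within the brain mask.

    Components are initialised at masked intensity quantiles (so the
    fit is deterministic for a given seed) and relabelled by increasing
    mean: CSF < GM < WM. Voxels brighter than white matter (including
    blood-flow artifacts) fall into the top component and are labelled
    WM — downstream heuristics rely on this.
    """
    require_same_grid(t1_corrected, mask, "volume and mask")
    msel = mask.astype_bool()
    if not msel.any():
        raise ValueError("mask is empty")
    vals = t1_corrected.data[msel].reshape(-1, 1)
    if np.unique(vals).size < 3:
        raise ValueError("fewer than 3 distinct intensity levels in mask")
    means_init = np.percentile(vals, (10.0, 50.0, 85.0)).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="diag",
        means_init=means_init,
        weights_init=np.full(3, 1 / 3),
        precisions_init=1.0 / np.full((3, 1), max(np.var(vals) / 9.0, 1e-6)),
        reg_covar=1e-3,
        max_iter=100,
        random_state=int(seed),
    )
    gmm.fit(vals)
    comp = gmm.predict(vals)
    order = np.argsort(gmm.means_.ravel())
    relabel = np.empty(3, dtype=np.uint8)
    relabel[order] = (CSF, GM, WM)
    labels = np.full(t1_corrected.data.shape, BACKGROUND, dtype=np.uint8)
    labels[msel] = relabel[comp]
    return TissueLabels(labels, t1_corrected.affine.copy())


def csf_mean(t1: Volume, labels: TissueLabels) -> float:
    """Mean intensity over CSF-labelled voxels."""
    require_same_grid(t1, labels, "volume and labels")
    sel = labels.mask_of(CSF)
    if not sel.any():
        raise ValueError("no CSF-labelled voxels")
    return float(t1.data[sel].mean())
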