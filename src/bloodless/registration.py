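"""Mask-constrained intensity registration and deformation analysis.

Affine registration maximises a joint-histogram mutual-information (MI)
estimate with a deterministic multi-resolution compass (pattern) search
over 6/9/12 parameters. Nonlinear registration is a demons-style
iteration with Gaussian fluid/elastic regularisation, initialised by an
affine and returning a dense displacement field on the fixed grid; the
field is accepted only if it does not reduce MI and its analytic
Jacobian determinant stays positive.

Conventions: an AffineTransform maps moving-space world mm to
fixed-space world mm. A CompositeTransform applies the affine first,
then the deformation in fixed space; resampling pulls back through
``p_moving = A^-1 (x + u(x))`` for every fixed-grid point x.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .types import (AffineTransform, BinaryMask, CompositeTransform,
                    DeformationField, GridMismatchError, ProbabilityMap,
                    TissueLabels, Volume)

__all__ = [
    "RegistrationError",
    "register_affine",
    "register_nonlinear",
    "resample",
    "compose",
    "jacobian_determinant_map",
    "displacement_magnitude_map",
    "mutual_information_arrays",
    "signed_jacobian_determinant",
    "affine_from_params",
]


class RegistrationError(RuntimeError):
    """Registration failed to produce an acceptable transform."""


# ---------------------------------------------------------------------------
# mutual information


def mutual_information_arrays(
    a: np.ndarray,
    b: np.ndarray,
    bins: int = 64,
    a_range: tuple[float, float] | None = None,
    b_range: tuple[float, float] | None = None,
) -> float:
    """MI (nats) between two flat samples via an equal-width joint histogram.

    Zero-probability cells contribute nothing. Ranges default to the
    samples' own min/max; fixed ranges keep values comparable across
    optimizer iterations.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("samples must be paired")
    if a.size == 0:
        return 0.0
    alo, ahi = a_range if a_range is not None else (a.min(), a.max())
    blo, bhi = b_range if b_range is not None else (b.min(), b.max())
    if ahi <= alo or bhi <= blo:
        raise ValueError("need at least 2 distinct values in each sample")
    ia = np.clip(((a - alo) / (ahi - alo) * bins).astype(np.int64), 0, bins - 1)
    ib = np.clip(((b - blo) / (bhi - blo) * bins).astype(np.int64), 0, bins - 1)
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


# ---------------------------------------------------------------------------
# resampling


def _moving_voxel_coords(transform, reference, moving_affine):
    """Pull fixed-grid voxel centres back to moving voxel coordinates."""
    if isinstance(transform, AffineTransform):
        affine_part, deformation = transform, None
    elif isinstance(transform, CompositeTransform):
        affine_part, deformation = transform.affine_part, transform.deformation
    else:
        raise TypeError(f"unsupported transform type {type(transform).__name__}")

    shape = reference.data.shape
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    world = reference.affine[:3, :3] @ idx + reference.affine[:3, 3:4]
    if deformation is not None:
        if deformation.shape != shape or not np.allclose(
            deformation.affine, reference.affine, atol=1e-5
        ):
            raise GridMismatchError(
                "deformation field must live on the reference grid"
            )
        world = world + deformation.displacements.reshape(-1, 3).T
    inv_a = np.linalg.inv(affine_part.matrix)
    mov_world = inv_a[:3, :3] @ world + inv_a[:3, 3:4]
    inv_m = np.linalg.inv(moving_affine)
    mov_vox = inv_m[:3, :3] @ mov_world + inv_m[:3, 3:4]
    return mov_vox, shape


def resample(v, transform, reference: Volume, interp: str = "linear"):
    """Resample a grid object onto the reference grid through a transform.

    `transform` maps moving to fixed; resampling evaluates the moving
    image at the pulled-back location of each reference voxel.
    Out-of-field voxels become 0. Masks and label grids require
    ``interp='nearest'``.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    discrete = isinstance(v, (BinaryMask, TissueLabels))
    if discrete and interp == "linear":
        raise ValueError(
            f"linear interpolation is invalid for {type(v).__name__}; use 'nearest'"
        )
    coords, shape = _moving_voxel_coords(transform, reference, v.affine)
    order = 0 if interp == "nearest" else 1
    out = ndimage.map_coordinates(
        v.data.astype(float), coords, order=order, mode="constant", cval=0.0
    ).reshape(shape)
    if isinstance(v, BinaryMask):
        return BinaryMask(out.astype(np.uint8), reference.affine.copy())
    if isinstance(v, TissueLabels):
        return TissueLabels(out.astype(np.uint8), reference.affine.copy())
    if isinstance(v, ProbabilityMap):
        return ProbabilityMap(np.clip(out, 0.0, 1.0), reference.affine.copy())
    return Volume(out, reference.affine.copy())


def compose(a: AffineTransform, b) -> CompositeTransform:
    """Compose: apply `a` first, then `b`.

    `b` may be an AffineTransform or a CompositeTransform; `a` must be
    affine (two deformation fields cannot be composed here).
    """
    if isinstance(a, CompositeTransform):
        raise TypeError("first operand must be a plain AffineTransform")
    if isinstance(b, AffineTransform):
        return CompositeTransform(AffineTransform(b.matrix @ a.matrix), None)
    if isinstance(b, CompositeTransform):
        return CompositeTransform(
            AffineTransform(b.affine_part.matrix @ a.matrix), b.deformation
        )
    raise TypeError(f"cannot compose with {type(b).__name__}")


# ---------------------------------------------------------------------------
# deformation analysis


def _field_of(t) -> DeformationField | None:
    if isinstance(t, DeformationField):
        return t
    if isinstance(t, CompositeTransform):
        return t.deformation
    raise TypeError(f"expected DeformationField or CompositeTransform, got {type(t)}")


def signed_jacobian_determinant(u: np.ndarray, spacing) -> np.ndarray:
    """Signed det of I + grad(u); negative values mean folding."""
    jac = np.empty(u.shape[:3] + (3, 3))
    for c in range(3):
        grads = np.gradient(u[..., c], *spacing)
        for d in range(3):
            jac[..., c, d] = grads[d]
    jac[..., 0, 0] += 1.0
    jac[..., 1, 1] += 1.0
    jac[..., 2, 2] += 1.0
    return (
        jac[..., 0, 0] * (jac[..., 1, 1] * jac[..., 2, 2] - jac[..., 1, 2] * jac[..., 2, 1])
        - jac[..., 0, 1] * (jac[..., 1, 0] * jac[..., 2, 2] - jac[..., 1, 2] * jac[..., 2, 0])
        + jac[..., 0, 2] * (jac[..., 1, 0] * jac[..., 2, 1] - jac[..., 1, 1] * jac[..., 2, 0])
    )


def jacobian_determinant_map(t, reference: Volume) -> Volume:
    """Voxelwise |det| of phi(x) = x + u(x) for the deformation part.

    Central differences in mm (one-sided at the boundary); the affine
    component is deliberately excluded so the map shows local effects
    only. A composite without a deformation yields 1 everywhere.
    Assumes an axis-aligned reference affine for the finite differences.
    """
    field = _field_of(t)
    if field is None:
        return Volume(np.ones(reference.data.shape), reference.affine.copy())
    if field.shape != reference.data.shape:
        raise GridMismatchError("field and reference grids differ")
    det = signed_jacobian_determinant(field.displacements, reference.voxel_sizes)
    return Volume(np.abs(det), reference.affine.copy())


def displacement_magnitude_map(t, reference: Volume) -> Volume:
    """Per-voxel Euclidean norm (mm) of the deformation's displacements."""
    field = _field_of(t)
    if field is None:
        return Volume(np.zeros(reference.data.shape), reference.affine.copy())
    if field.shape != reference.data.shape:
        raise GridMismatchError("field and reference grids differ")
    return Volume(field.magnitude(), reference.affine.copy())


# ---------------------------------------------------------------------------
# affine registration


def affine_from_params(params: np.ndarray, center: np.ndarray) -> AffineTransform:
    """Build a moving->fixed affine from parameters about a centre (mm).

    Layout: [tx,ty,tz, rx,ry,rz (deg), log sx, log sy, log sz,
    (optional) hxy, hxz, hyz]. Rotations compose as Rz @ Ry @ Rx.
    """
    params = np.asarray(params, dtype=float)
    t = params[0:3]
    rx, ry, rz = np.deg2rad(params[3:6])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M3 = Rz @ Ry @ Rx
    if params.size >= 9:
        M3 = M3 @ np.diag(np.exp(params[6:9]))
    if params.size == 12:
        H = np.eye(3)
        H[0, 1], H[0, 2], H[1, 2] = params[9:12]
        M3 = M3 @ H
    m = np.eye(4)
    m[:3, :3] = M3
    m[:3, 3] = t + center - M3 @ center
    return AffineTransform(m)


def _weighted_centroid(vol: Volume, mask: BinaryMask | None) -> np.ndarray:
    if mask is not None:
        w = mask.data.astype(float)
    else:
        w = vol.data - vol.data.min()
    tot = w.sum()
    if tot <= 0:
        raise RegistrationError("cannot locate centroid: empty weights")
    idx = np.indices(vol.data.shape, dtype=float).reshape(3, -1)
    c_vox = (idx * w.ravel()).sum(axis=1) / tot
    return vol.affine[:3, :3] @ c_vox + vol.affine[:3, 3]


def _level_fixed(fixed: Volume, mask: BinaryMask, shrink: int, smooth_vox: float):
    sigma = max(smooth_vox, 0.5 * shrink if shrink > 1 else 0.0)
    data = ndimage.gaussian_filter(fixed.data, sigma) if sigma > 0 else fixed.data
    sl = (slice(None, None, shrink),) * 3
    data = data[sl]
    m = mask.data[sl].astype(bool)
    idx = np.indices(fixed.data.shape, dtype=float)[(slice(None),) + sl]
    pts = idx.reshape(3, -1)[:, m.ravel()]
    world = fixed.affine[:3, :3] @ pts + fixed.affine[:3, 3:4]
    vals = data[m]
    return world, vals


def register_affine(
    moving: Volume,
    fixed: Volume,
    fixed_mask: BinaryMask,
    moving_mask: BinaryMask | None = None,
    config: PipelineConfig | None = None,
    metric: str | None = None,
) -> AffineTransform:
    """Multi-resolution affine registration (moving -> fixed).

    The similarity is mutual information by default, or Pearson
    cross-correlation with ``metric='cc'`` (the objective family of the
    classic hierarchical linear tools; unlike MI it is genuinely hurt
    by bright artifacts overlying dark template tissue). The compass
    search is fully deterministic: per resolution level it sweeps each
    parameter with +/- steps, keeps strict improvements, and halves the
    step when a sweep stalls. Voxels pulled back outside the moving
    volume are excluded from the similarity; if a moving mask is given,
    voxels landing outside it are excluded as well.
    """
    config = config or PipelineConfig()
    metric = metric or config.affine_metric
    if metric not in ("mi", "cc"):
        raise ValueError(f"metric must be 'mi' or 'cc', got {metric!r}")
    if fixed_mask.count() == 0:
        raise RegistrationError("fixed mask is empty")
    bins = config.mi_bins

    c_fix = _weighted_centroid(fixed, fixed_mask)
    c_mov = _weighted_centroid(moving, moving_mask)
    nparams = {6: 6, 9: 9, 12: 12}[config.affine_dof]
    params = np.zeros(nparams)
    params[0:3] = c_fix - c_mov

    inv_mov_affine = np.linalg.inv(moving.affine)
    mov_mask_data = moving_mask.data.astype(float) if moving_mask is not None else None
    shape_m = np.array(moving.data.shape, dtype=float)

    last_score = None
    for level, (shrink, smooth) in enumerate(
        zip(config.affine_shrinks, config.affine_smooth_vox)
    ):
        world, f_vals = _level_fixed(fixed, fixed_mask, shrink, smooth)
        if f_vals.size < 32 or np.ptp(f_vals) == 0:
            continue
        sigma_m = max(smooth, 0.5 * shrink if shrink > 1 else 0.0)
        m_data = (
            ndimage.gaussian_filter(moving.data, sigma_m) if sigma_m > 0 else moving.data
        )
        f_range = (float(f_vals.min()), float(f_vals.max()))
        m_range = (float(m_data.min()), float(m_data.max()))
        if m_range[1] <= m_range[0]:
            raise RegistrationError("moving image has no intensity spread")
        f_dig = np.clip(
            ((f_vals - f_range[0]) / (f_range[1] - f_range[0]) * bins).astype(np.int64),
            0,
            bins - 1,
        )

        def cost(p: np.ndarray) -> float:
            t = affine_from_params(p, c_fix)
            inv_a = np.linalg.inv(t.matrix)
            mov_world = inv_a[:3, :3] @ world + inv_a[:3, 3:4]
            vox = inv_mov_affine[:3, :3] @ mov_world + inv_mov_affine[:3, 3:4]
            inb = np.all((vox >= 0) & (vox <= (shape_m[:, None] - 1)), axis=0)
            if inb.sum() < 32:
                return 1.0  # essentially no overlap
            m_vals = ndimage.map_coordinates(
                m_data, vox[:, inb], order=1, mode="nearest"
            )
            fd = f_dig[inb]
            fv = f_vals[inb]
            if mov_mask_data is not None:
                keep = (
                    ndimage.map_coordinates(
                        mov_mask_data, vox[:, inb], order=0, mode="constant", cval=0.0
                    )
                    > 0.5
                )
                if keep.sum() < 32:
                    return 1.0
                m_vals = m_vals[keep]
                fd = fd[keep]
                fv = fv[keep]
            if metric == "cc":
                ms = m_vals.std()
                fs = fv.std()
                if ms == 0 or fs == 0:
                    return 1.0
                cc = ((m_vals - m_vals.mean()) * (fv - fv.mean())).mean() / (ms * fs)
                return -float(cc)
            md = np.clip(
                ((m_vals - m_range[0]) / (m_range[1] - m_range[0]) * bins).astype(
                    np.int64
                ),
                0,
                bins - 1,
            )
            joint = np.bincount(fd * bins + md, minlength=bins * bins).astype(float)
            joint /= joint.sum()
            joint = joint.reshape(bins, bins)
            pa = joint.sum(axis=1)
            pb = joint.sum(axis=0)
            nz = joint > 0
            outer = pa[:, None] * pb[None, :]
            return -float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))

        level_scale = shrink / config.affine_shrinks[0]
        steps = np.empty(nparams)
        steps[0:3] = config.affine_step_mm * max(level_scale, 0.25)
        steps[3:6] = config.affine_step_deg * max(level_scale, 0.25)
        if nparams >= 9:
            steps[6:9] = config.affine_step_logscale * max(level_scale, 0.25)
        if nparams == 12:
            steps[9:12] = config.affine_step_logscale * max(level_scale, 0.25)

        best = cost(params)
        start_best = best
        for _ in range(config.affine_halvings[level]):
            for _sweep in range(config.affine_max_sweeps):
                improved = False
                for i in range(nparams):
                    for sgn in (1.0, -1.0):
                        trial = params.copy()
                        trial[i] += sgn * steps[i]
                        c = cost(trial)
                        if c < best - 1e-12:
                            best, params = c, trial
                            improved = True
                            break
                if not improved:
                    break
            steps *= 0.5
        if best > start_best + 1e-9:
            raise RegistrationError(
                f"MI decreased over level {level}: {-start_best:.5f} -> {-best:.5f}"
            )
        last_score = -best
    if last_score is None:
        raise RegistrationError("no usable resolution level (mask too small?)")
    return affine_from_params(params, c_fix)


# ---------------------------------------------------------------------------
# nonlinear (demons-style) registration


def _zoom_field(u: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    if u.shape[:3] == tuple(target_shape):
        return u
    factors = [t / s for t, s in zip(target_shape, u.shape[:3])]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = ndimage.zoom(u[..., c], factors, order=1, mode="nearest")
    return out


def register_nonlinear(
    moving: Volume,
    fixed: Volume,
    init: AffineTransform,
    fixed_mask: BinaryMask,
    config: PipelineConfig | None = None,
    gate: str = "mi",
) -> CompositeTransform:
    """Demons-style nonlinear refinement of an affine initialisation.

    The moving image is first brought into fixed space through `init`
    and linearly intensity-matched (trimmed least-squares) so the
    difference-driven demons force is meaningful. Displacements live in
    world mm on the fixed grid. Each update is fluid-smoothed, capped at
    ``nl_max_step_mm``, added, and the total field elastic-smoothed. The
    result is accepted only if the masked gate metric does not worsen
    relative to the affine-only alignment (otherwise a zero field is
    returned) and the analytic Jacobian determinant is positive
    everywhere (otherwise the field is progressively smoothed;
    persistent folding is an error).

    ``gate='mi'`` (default) guarantees MI non-decrease end-to-end.
    ``gate='ssd'`` gates on the masked sum of squared differences
    instead — appropriate when the two images are already nearly
    identical, where the interpolation blur of any warp slightly lowers
    a global histogram MI even though the residual alignment genuinely
    improves.
    """
    config = config or PipelineConfig()
    if gate not in ("mi", "ssd"):
        raise ValueError(f"gate must be 'mi' or 'ssd', got {gate!r}")
    if fixed_mask.count() == 0:
        raise RegistrationError("fixed mask is empty")
    m0 = resample(moving, init, fixed, "linear").data
    f = fixed.data
    mask = fixed_mask.data.astype(bool)

    # intensity match m0 -> f: trimmed least-squares linear regression over
    # the roughly aligned pair, so already-matched intensities map to the
    # identity and no spurious demons force is introduced
    mv = m0[mask]
    fv = f[mask]
    if mv.size < 16 or np.ptp(mv) == 0:
        raise RegistrationError("moving image is constant within the mask")
    keep = np.ones(mv.size, dtype=bool)
    a, b = 1.0, 0.0
    for _ in range(3):
        mk, fk = mv[keep], fv[keep]
        var = mk.var()
        if var <= 0:
            break
        a = ((mk - mk.mean()) * (fk - fk.mean())).mean() / var
        b = fk.mean() - a * mk.mean()
        resid = fv - (a * mv + b)
        s = resid[keep].std()
        if s == 0:
            break
        keep = np.abs(resid) <= 2.0 * s
        if keep.sum() < 16:
            raise RegistrationError("intensity match failed: all voxels trimmed")
    if abs(a) < 1e-12:
        raise RegistrationError("degenerate intensity match (zero slope)")
    m0n = a * m0 + b

    spacing = fixed.voxel_sizes
    u = np.zeros((1, 1, 1, 3))
    for shrink, iters in zip(config.nl_shrinks, config.nl_iters):
        sl = (slice(None, None, shrink),) * 3
        sigma_aa = 0.5 * shrink if shrink > 1 else 0.0
        f_l = ndimage.gaussian_filter(f, sigma_aa)[sl] if sigma_aa else f[sl]
        m_l = ndimage.gaussian_filter(m0n, sigma_aa)[sl] if sigma_aa else m0n[sl]
        # forces act only in and just around the fixed mask, so spurious
        # structure far outside it (e.g. field-of-view edges) cannot
        # drive the deformation
        mask_l = ndimage.binary_dilation(mask[sl], iterations=2).astype(float)
        spacing_l = spacing * shrink
        grad_f = np.gradient(f_l, *spacing_l)
        gnorm2 = grad_f[0] ** 2 + grad_f[1] ** 2 + grad_f[2] ** 2
        mean_sp2 = float(np.mean(spacing_l) ** 2)
        u = _zoom_field(u, f_l.shape)
        idx = np.indices(f_l.shape, dtype=float)
        for _ in range(iters):
            coords = [idx[c] + u[..., c] / spacing_l[c] for c in range(3)]
            warped = ndimage.map_coordinates(m_l, coords, order=1, mode="nearest")
            diff = (f_l - warped) * mask_l
            denom = gnorm2 + diff * diff / mean_sp2
            scale = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
            step = np.stack([scale * g for g in grad_f], axis=-1)
            mag = np.sqrt((step**2).sum(axis=-1))
            cap = config.nl_max_step_mm
            factor = np.where(mag > cap, cap / np.maximum(mag, 1e-12), 1.0)
            step *= factor[..., None]
            if config.nl_sigma_fluid_vox > 0:
                for c in range(3):
                    step[..., c] = ndimage.gaussian_filter(
                        step[..., c], config.nl_sigma_fluid_vox
                    )
            u = u + config.nl_step * step
            if config.nl_sigma_elastic_vox > 0:
                for c in range(3):
                    u[..., c] = ndimage.gaussian_filter(
                        u[..., c], config.nl_sigma_elastic_vox
                    )
    u = _zoom_field(u, f.shape)

    # enforce a positive (signed) Jacobian determinant
    for _attempt in range(6):
        if signed_jacobian_determinant(u, spacing).min() > 0:
            break
        for c in range(3):
            u[..., c] = ndimage.gaussian_filter(u[..., c], 1.0)
    else:
        raise RegistrationError("non-positive Jacobian persists after smoothing")
    field = DeformationField(u, fixed.affine.copy())

    # acceptance gate: never return a field that degrades similarity
    bins = config.mi_bins
    composite = CompositeTransform(init, field)
    warped_full = resample(moving, composite, fixed, "linear").data
    if gate == "mi":
        s0 = mutual_information_arrays(f[mask], m0[mask], bins=bins)
        s1 = mutual_information_arrays(f[mask], warped_full[mask], bins=bins)
        ok = s1 >= s0
    else:
        s0 = float(((f[mask] - m0n[mask]) ** 2).mean())
        s1 = float(((f[mask] - (a * warped_full + b)[mask]) ** 2).mean())
        ok = s1 <= s0
    if not ok:
        field = DeformationField(np.zeros(f.shape + (3,)), fixed.affine.copy())
        composite = CompositeTransform(init, field)
    return composite
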