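"""Synthetic head phantoms with ground-truth vessels and misalignments.

The generator produces a template (nested ellipsoidal head: CSF shell,
grey-matter ribbon, gently gyrified white-matter core, plus CSF clefts
mimicking the longitudinal and Sylvian fissures), subjects derived from
it by a known affine + smooth nonlinear warp, a multiplicative bias
field and additive noise, and bright tubular blood-flow artifacts
rasterised along vessel curves threaded through the clefts and along
the inferior surface — the places such artifacts appear in real
T1-weighted data. An MRA-like cohort of jittered vessel trees supports
building the blood probability map.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .registration import resample
from .types import (CSF, GM, WM, AffineTransform, BinaryMask,
                    CompositeTransform, DeformationField, TissueLabels,
                    Volume)

__all__ = [
    "PhantomSpec",
    "TemplatePhantom",
    "SubjectPhantom",
    "generate_template",
    "generate_subject",
    "generate_mra_cohort",
    "default_vessel_curves",
    "random_subject_spec",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic head and its corruptions.

    Intensities are arbitrary units; the vessel intensity must exceed
    white matter (the artifacts are bright). Misalignment is given as
    explicit translation (mm), rotation (deg) and per-axis scale; the
    nonlinear warp amplitude is the maximum displacement magnitude (mm).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 1.0
    csf_intensity: float = 30.0
    gm_intensity: float = 65.0
    wm_intensity: float = 100.0
    vessel_curves: list | None = None  # list of (N,3) world-mm polylines
    vessel_radius_mm: float = 1.5
    vessel_intensity: float = 140.0
    bias_field_amplitude: float = 0.10
    noise_sigma: float = 2.0
    rician: bool = False
    misalign_translation_mm: tuple[float, float, float] = (2.5, -2.0, 1.5)
    misalign_rotation_deg: tuple[float, float, float] = (2.0, -1.5, 1.0)
    misalign_scale: tuple[float, float, float] = (1.02, 0.99, 1.01)
    warp_amplitude_mm: float = 3.0
    gyrification: float = 0.05
    mra_radius_mm: float = 2.0
    mra_jitter_mm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if min(self.grid_shape) * self.voxel_size_mm < 32:
            raise ValueError(
                "grid too small to contain all compartments "
                f"(need >= 32 mm per axis, got {min(self.grid_shape) * self.voxel_size_mm})"
            )
        if not self.vessel_intensity > self.wm_intensity:
            raise ValueError("vessel_intensity must exceed wm_intensity (bright artifacts)")
        if not (self.csf_intensity < self.gm_intensity < self.wm_intensity):
            raise ValueError("tissue intensities must satisfy CSF < GM < WM")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        a[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return a

    @property
    def brain_radii(self) -> np.ndarray:
        """Semi-axes (mm) of the outer brain (CSF envelope) ellipsoid."""
        extent = np.array(self.grid_shape) * self.voxel_size_mm
        return extent * np.array([0.335, 0.405, 0.32])


@dataclass
class TemplatePhantom:
    t1: Volume
    brain_mask: BinaryMask
    labels: TissueLabels


@dataclass
class SubjectPhantom:
    t1_bloody: Volume
    t1_clean: Volume
    truth_blood_mask: BinaryMask
    brain_mask: BinaryMask
    truth_affine: AffineTransform
    truth_warp: DeformationField
    truth_labels: TissueLabels = dc_field(default=None)  # type: ignore[assignment]

    def truth_transform(self) -> CompositeTransform:
        """Template -> subject mapping exactly as applied."""
        return CompositeTransform(self.truth_affine, self.truth_warp)


# ---------------------------------------------------------------------------
# geometry helpers


def _cleft_masks(spec: PhantomSpec, world: np.ndarray, rho_core: np.ndarray):
    """CSF clefts: an interhemispheric slab and two tilted lateral slabs.

    Clefts are carved only outside the deep core (rho_core > 0.62) so
    the white-matter body always remains a single connected component.
    """
    r = spec.brain_radii
    x, y, z = world
    outer = rho_core > 0.62
    long_fissure = outer & (np.abs(x) <= 1.3) & (z > -0.1 * r[2])
    clefts = long_fissure
    alpha = np.deg2rad(35.0)
    n = np.array([np.cos(alpha), 0.0, np.sin(alpha)])
    for side in (1.0, -1.0):
        p0 = np.array([side * 0.55 * r[0], -0.05 * r[1], -0.05 * r[2]])
        d = (
            (x - p0[0]) * (side * n[0])
            + (y - p0[1]) * n[1]
            + (z - p0[2]) * n[2]
        )
        slab = (
            (np.abs(d) <= 1.3)
            & (y > -0.65 * r[1])
            & (y < 0.55 * r[1])
            & (z > -0.55 * r[2])
            & (z < 0.35 * r[2])
        )
        clefts = clefts | (slab & outer)
    return clefts


def _template_geometry(spec: PhantomSpec):
    rng = np.random.default_rng(spec.rng_seed)
    shape = spec.grid_shape
    affine = spec.affine
    idx = np.indices(shape, dtype=float)
    world = (
        affine[:3, :3] @ idx.reshape(3, -1) + affine[:3, 3:4]
    ).reshape((3,) + shape)
    r = spec.brain_radii
    x, y, z = world

    rho_brain = np.sqrt((x / r[0]) ** 2 + (y / r[1]) ** 2 + (z / r[2]) ** 2)
    r_gm = 0.90 * r
    rho_gm = np.sqrt((x / r_gm[0]) ** 2 + (y / r_gm[1]) ** 2 + (z / r_gm[2]) ** 2)
    r_wm = 0.76 * r
    rho_wm = np.sqrt((x / r_wm[0]) ** 2 + (y / r_wm[1]) ** 2 + (z / r_wm[2]) ** 2)

    # mild angular perturbation of the WM boundary ("gyrification")
    theta = np.arctan2(y, x)
    phi = np.arctan2(np.sqrt(x**2 + y**2), z)
    ph0, ph1 = rng.uniform(0, 2 * np.pi, size=2)
    bumps = 1.0 + spec.gyrification * np.sin(4 * theta + ph0) * np.cos(3 * phi + ph1)
    rho_wm_eff = rho_wm / bumps

    clefts = _cleft_masks(spec, world, rho_wm)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[rho_brain <= 1.0] = CSF
    labels[(rho_gm <= 1.0) & ~clefts] = GM
    labels[(rho_wm_eff <= 1.0) & ~clefts] = WM
    brain = (rho_brain <= 1.0).astype(np.uint8)
    return labels, brain, affine, world


def default_vessel_radii(spec: PhantomSpec) -> list[float]:
    """Per-curve tube radii: parenchymal vessels at the base radius,
    the two surface vessels (inferior, sinus) wider, as dural sinuses
    and basal vessels are in real scans."""
    base = spec.vessel_radius_mm
    return [base, base, base, 2.3 * base, 2.3 * base]


def default_vessel_curves(spec: PhantomSpec) -> list[np.ndarray]:
    """Vessel polylines (template world mm) threaded through the clefts.

    Five arcs: one along the longitudinal fissure, one in each
    Sylvian-like lateral cleft, one hugging the inferior surface and a
    sagittal-sinus-like arc along the posterior-superior surface. The
    two surface curves sit just inside the brain envelope so their
    tubes protrude slightly beyond it — peripheral artifacts are what
    contaminate extracted brain masks in real scans.
    """
    r = spec.brain_radii
    curves = []
    s = np.linspace(-1.2, 1.2, 60)
    curves.append(
        np.stack([np.zeros_like(s), 0.62 * r[1] * np.sin(s), 0.70 * r[2] * np.cos(s)], axis=1)
    )
    alpha = np.deg2rad(35.0)
    e2 = np.array([-np.sin(alpha), 0.0, np.cos(alpha)])
    ss = np.linspace(-1.1, 1.1, 50)
    for side in (1.0, -1.0):
        p0 = np.array([side * 0.55 * r[0], -0.05 * r[1], -0.05 * r[2]])
        e2s = e2 * np.array([side, 1.0, 1.0])
        pts = (
            p0[None, :]
            + np.outer(0.45 * r[1] * np.sin(ss), np.array([0.0, 1.0, 0.0]))
            + np.outer(0.22 * r[2] * np.cos(ss) - 0.10 * r[2], e2s)
        )
        curves.append(pts)
    t = np.linspace(-0.55, 0.55, 50)
    yv = t * r[1]
    xv = np.full_like(yv, 0.15 * r[0])
    inner = np.clip(1.0 - (yv / r[1]) ** 2 - (xv / r[0]) ** 2, 0.0, None)
    zv = -0.995 * r[2] * np.sqrt(inner)
    curves.append(np.stack([xv, yv, zv], axis=1))
    # sagittal-sinus-like arc: posterior-superior midline surface
    ss2 = np.linspace(0.15 * np.pi, 0.6 * np.pi, 50)
    curves.append(
        np.stack(
            [
                np.zeros_like(ss2),
                -0.995 * r[1] * np.sin(ss2),
                0.995 * r[2] * np.cos(ss2),
            ],
            axis=1,
        )
    )
    return curves


def _densify(curve: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly `step` mm spacing."""
    curve = np.asarray(curve, dtype=float)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.interp(t, arclen, curve[:, c])
    return out


def rasterize_tubes(
    curves: list[np.ndarray],
    radius_mm: float | list[float],
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Boolean grid of voxels whose centres lie within the tube radius of
    a curve; `radius_mm` may be one value or one per curve."""
    out = np.zeros(shape, dtype=bool)
    inv = np.linalg.inv(affine)
    voxsz = np.linalg.norm(affine[:3, :3], axis=0)
    radii = ([radius_mm] * len(curves) if np.isscalar(radius_mm) else list(radius_mm))
    if len(radii) != len(curves):
        raise ValueError("need one radius per curve")
    for curve, radius_mm in zip(curves, radii):
        pts = _densify(curve)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        pad = radius_mm / voxsz + 1.0
        lo = np.maximum(np.floor(vox.min(axis=0) - pad).astype(int), 0)
        hi = np.minimum(np.ceil(vox.max(axis=0) + pad).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        sub = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
        sub_world = sub @ affine[:3, :3].T + affine[:3, 3]
        tree = cKDTree(pts)
        dist, _ = tree.query(sub_world, k=1)
        hit = dist <= radius_mm
        if hit.any():
            coords = sub[hit]
            out[coords[:, 0], coords[:, 1], coords[:, 2]] = True
    return out


# ---------------------------------------------------------------------------
# generators


def generate_template(spec: PhantomSpec) -> TemplatePhantom:
    """Build the vessel-free template head with truth labels and mask."""
    labels, brain, affine, _ = _template_geometry(spec)
    lut = np.array(
        [0.0, spec.csf_intensity, spec.gm_intensity, spec.wm_intensity]
    )
    t1 = lut[labels]
    return TemplatePhantom(
        t1=Volume(t1, affine),
        brain_mask=BinaryMask(brain, affine),
        labels=TissueLabels(labels, affine),
    )


def _truth_affine(spec: PhantomSpec) -> AffineTransform:
    rx, ry, rz = np.deg2rad(spec.misalign_rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M3 = Rz @ Ry @ Rx @ np.diag(spec.misalign_scale)
    m = np.eye(4)
    m[:3, :3] = M3
    m[:3, 3] = spec.misalign_translation_mm
    return AffineTransform(m)


def _truth_warp(spec: PhantomSpec, rng: np.random.Generator) -> DeformationField:
    """Smooth low-frequency random displacement field, max |u| = amplitude."""
    shape = spec.grid_shape
    u = np.zeros(shape + (3,))
    if spec.warp_amplitude_mm > 0:
        coarse = rng.standard_normal((5, 5, 5, 3))
        for c in range(3):
            comp = ndimage.zoom(
                coarse[..., c],
                [s / 5 for s in shape],
                order=3,
                mode="nearest",
            )
            u[..., c] = ndimage.gaussian_filter(comp, 2.0)
        mag = np.sqrt((u**2).sum(axis=-1))
        peak = mag.max()
        if peak > 0:
            u *= spec.warp_amplitude_mm / peak
    field = DeformationField(u, spec.affine)
    # reject non-invertible warps (signed determinant: folding is negative)
    from .registration import signed_jacobian_determinant

    det = signed_jacobian_determinant(u, np.full(3, spec.voxel_size_mm))
    if det.min() <= 0:
        raise ValueError(
            "warp_amplitude_mm too large: deformation is non-invertible "
            f"(min det J = {det.min():.3g})"
        )
    return field


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative bias: product of per-axis degree-2 polynomials,
    rescaled so the total deviation from 1 equals the spec amplitude."""
    shape = spec.grid_shape
    if spec.bias_field_amplitude == 0:
        return np.ones(shape)
    axes = []
    for s in shape:
        t = np.linspace(-1.0, 1.0, s)
        c = rng.uniform(-1.0, 1.0, size=3)
        p = c[0] + c[1] * t + c[2] * t**2
        axes.append(p)
    prod = np.ones(shape)
    for ax, p in enumerate(axes):
        sh = [1, 1, 1]
        sh[ax] = len(p)
        prod = prod * (1.0 + 0.5 * p.reshape(sh))
    dev = prod - prod.mean()
    peak = np.abs(dev).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + spec.bias_field_amplitude * dev / peak


def _forward_map_points(
    pts: np.ndarray, affine_t: AffineTransform, warp: DeformationField
) -> np.ndarray:
    """Map template-space points to subject space.

    The resampling convention samples the template at A^-1 (x + u(x));
    the forward image of p solves x + u(x) = A p, found by fixed-point
    iteration (valid for smooth, moderate warps).
    """
    target = affine_t.apply_points(pts)
    x = target.copy()
    inv_aff = np.linalg.inv(warp.affine)
    for _ in range(25):
        vox = x @ inv_aff[:3, :3].T + inv_aff[:3, 3]
        u_at = np.stack(
            [
                ndimage.map_coordinates(
                    warp.displacements[..., c], vox.T, order=1, mode="nearest"
                )
                for c in range(3)
            ],
            axis=1,
        )
        x_new = target - u_at
        if np.max(np.abs(x_new - x)) < 1e-4:
            x = x_new
            break
        x = x_new
    return x


def generate_subject(spec: PhantomSpec, template: TemplatePhantom) -> SubjectPhantom:
    """Derive a misaligned, biased, noisy subject with bright vessel tubes.

    The clean and bloody volumes share bias and noise realisations, so
    they differ exactly on the rasterised vessel support.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    affine_t = _truth_affine(spec)
    warp = _truth_warp(spec, rng)
    truth = CompositeTransform(affine_t, warp)

    ref = Volume(np.zeros(spec.grid_shape), spec.affine)
    base = resample(template.t1, truth, ref, "linear").data
    brain_mask = resample(template.brain_mask, truth, ref, "nearest")
    truth_labels = resample(template.labels, truth, ref, "nearest")

    bias = _bias_field(spec, rng)
    clean = base * bias

    curves = spec.vessel_curves
    if curves is None:
        curves = default_vessel_curves(spec)
        radii = default_vessel_radii(spec)
    else:
        radii = [spec.vessel_radius_mm] * len(curves)
    subj_curves = [
        _forward_map_points(_densify(np.asarray(c)), affine_t, warp) for c in curves
    ]
    tube = rasterize_tubes(subj_curves, radii, spec.grid_shape, spec.affine)
    bloody = clean.copy()
    bloody[tube] = spec.vessel_intensity * bias[tube]

    if spec.noise_sigma > 0:
        if spec.rician:
            n1 = rng.normal(0.0, spec.noise_sigma, size=clean.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=clean.shape)
            clean = np.sqrt((clean + n1) ** 2 + n2**2)
            bloody = np.sqrt((bloody + n1) ** 2 + n2**2)
        else:
            noise = rng.normal(0.0, spec.noise_sigma, size=clean.shape)
            clean = clean + noise
            bloody = bloody + noise

    return SubjectPhantom(
        t1_bloody=Volume(bloody, spec.affine),
        t1_clean=Volume(clean, spec.affine),
        truth_blood_mask=BinaryMask(tube.astype(np.uint8), spec.affine),
        brain_mask=brain_mask,
        truth_affine=affine_t,
        truth_warp=warp,
        truth_labels=truth_labels,
    )


def generate_mra_cohort(
    spec: PhantomSpec, n: int, seed: int | None = None
) -> list[Volume]:
    """MRA-like template-space volumes: bright along jittered vessel trees.

    Each cohort member shifts every vessel curve by an independent
    Gaussian offset (sigma = spec.mra_jitter_mm per axis), emulating
    inter-subject vascular variability; tubes of radius
    spec.mra_radius_mm are rasterised at intensity 100 and lightly
    blurred. Averaging and normalising these yields the blood
    probability map.
    """
    if n < 1:
        raise ValueError(f"need at least one MRA volume, got n={n}")
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    curves = spec.vessel_curves
    if curves is None:
        curves = default_vessel_curves(spec)
        scale = spec.mra_radius_mm / spec.vessel_radius_mm
        radii = [scale * r for r in default_vessel_radii(spec)]
    else:
        radii = [spec.mra_radius_mm] * len(curves)
    out = []
    for _ in range(n):
        jittered = []
        for c in curves:
            offset = rng.normal(0.0, spec.mra_jitter_mm, size=3)
            jittered.append(np.asarray(c, dtype=float) + offset)
        tube = rasterize_tubes(jittered, radii, spec.grid_shape, spec.affine)
        data = np.where(tube, 100.0, 0.0)
        data = ndimage.gaussian_filter(data, 0.6)
        out.append(Volume(data, spec.affine))
    return out


def random_subject_spec(
    base: PhantomSpec,
    rng: np.random.Generator,
    max_translation_mm: float = 4.0,
    max_rotation_deg: float = 3.0,
    max_log_scale: float = 0.02,
) -> PhantomSpec:
    """Per-subject spec with randomised misalignment drawn from `rng`."""
    import dataclasses

    return dataclasses.replace(
        base,
        misalign_translation_mm=tuple(rng.uniform(-max_translation_mm, max_translation_mm, 3)),
        misalign_rotation_deg=tuple(rng.uniform(-max_rotation_deg, max_rotation_deg, 3)),
        misalign_scale=tuple(np.exp(rng.uniform(-max_log_scale, max_log_scale, 3))),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
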