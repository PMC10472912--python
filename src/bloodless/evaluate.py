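"""Registration-impact analysis.

For each subject two registration chains to the template are run — one
driven by the original ("bloody") scan, one by the deblooded scan —
and the quality of each is measured against the template: Dice overlap
of the transformed brain mask with the template mask, and mutual
information between the transformed volume and the template. The
similarity comparand is always the deblooded scan, so the comparison
isolates the transforms themselves. Cohort-level differences are
tested with two-tailed paired t-tests, and the deformation needed to
map the bloody-transform result onto the deblooded-transform result is
summarised by voxelwise-maximum |Jacobian determinant| and
displacement-magnitude maps across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .registration import (RegistrationError, mutual_information_arrays,
                           register_affine, register_nonlinear, resample)
from .types import BinaryMask, Volume, require_same_grid

__all__ = [
    "SubjectEvaluation",
    "CohortSummary",
    "dice",
    "mutual_information",
    "paired_t_test",
    "evaluate_subject",
    "max_map",
    "impact_maps",
    "summarize_cohort",
    "cohort_summary_table",
]

METRICS = ("dice_lin", "mi_lin", "dice_nl", "mi_nl")
METRIC_ROWS = {
    "dice_lin": "Linear mask dice",
    "mi_lin": "Linear similarity (MI)",
    "dice_nl": "Nonlinear mask dice",
    "mi_nl": "Nonlinear similarity (MI)",
}


@dataclass
class SubjectEvaluation:
    subject_id: str
    dice_lin_bloody: float
    dice_lin_deblooded: float
    mi_lin_bloody: float
    mi_lin_deblooded: float
    dice_nl_bloody: float
    dice_nl_deblooded: float
    mi_nl_bloody: float
    mi_nl_deblooded: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("dice"):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name}={v} outside [0,1]")
            elif f.name.startswith("mi"):
                if getattr(self, f.name) < -1e-9:
                    raise ValueError(f"{f.name} negative")


@dataclass
class CohortSummary:
    """Per-metric means/variances plus the paired-test statistics."""

    n: int
    mean_bloody: dict[str, float]
    var_bloody: dict[str, float]
    mean_deblooded: dict[str, float]
    var_deblooded: dict[str, float]
    t_stat: dict[str, float]
    p_value: dict[str, float]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1."""
    require_same_grid(a, b, "masks")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.astype_bool() & b.astype_bool()).sum())
    return 2.0 * inter / (na + nb)


def mutual_information(
    a: Volume,
    b: Volume,
    mask: BinaryMask | None = None,
    bins: int = 64,
) -> float:
    """Histogram MI (nats) between two volumes, optionally masked."""
    require_same_grid(a, b, "volumes")
    if mask is not None:
        require_same_grid(a, mask, "volume and mask")
        sel = mask.astype_bool()
        av, bv = a.data[sel], b.data[sel]
    else:
        av, bv = a.data.ravel(), b.data.ravel()
    if np.unique(av).size < 2 or np.unique(bv).size < 2:
        raise ValueError("need at least 2 distinct values in each volume")
    return mutual_information_arrays(av, bv, bins=bins)


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-tailed paired t-test of y - x.

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)), sample sd
    (n-1 denominator), p from the t distribution with n-1 df. All
    differences zero gives (0, 1); zero variance with nonzero mean is
    the degenerate limit (±inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def max_map(volumes: list[Volume]) -> Volume:
    """Voxelwise maximum across a stack of same-grid volumes."""
    if not volumes:
        raise ValueError("need at least one volume")
    out = volumes[0].data.copy()
    for v in volumes[1:]:
        require_same_grid(volumes[0], v, "volumes")
        np.maximum(out, v.data, out=out)
    return Volume(out, volumes[0].affine.copy())


def evaluate_subject(
    subject_id: str,
    bloody: Volume,
    deblooded: Volume,
    bloody_mask: BinaryMask,
    deblooded_mask: BinaryMask,
    template: Volume,
    template_mask: BinaryMask,
    config: PipelineConfig | None = None,
) -> SubjectEvaluation:
    """Run both registration chains and fill the eight metrics.

    The bloody chain registers the original scan to the template; the
    deblooded chain registers the deblooded scan. Each resulting
    transform (linear, then linear+nonlinear) is applied to the
    deblooded scan and to the chain's own brain mask; Dice is taken
    against the template mask, MI against the template within its mask.
    """
    ev, _ = evaluate_subject_full(
        subject_id, bloody, deblooded, bloody_mask, deblooded_mask,
        template, template_mask, config,
    )
    return ev


def evaluate_subject_full(
    subject_id: str,
    bloody: Volume,
    deblooded: Volume,
    bloody_mask: BinaryMask,
    deblooded_mask: BinaryMask,
    template: Volume,
    template_mask: BinaryMask,
    config: PipelineConfig | None = None,
) -> tuple[SubjectEvaluation, dict]:
    """As evaluate_subject, additionally returning transforms and the
    deblooded scan warped into template space by each chain (the inputs
    impact_maps needs)."""
    config = config or PipelineConfig()
    results: dict[str, float] = {}
    artifacts: dict = {}
    try:
        for tag, driver, mask in (
            ("bloody", bloody, bloody_mask),
            ("deblooded", deblooded, deblooded_mask),
        ):
            t_lin = register_affine(
                driver, template, template_mask, None, config,
                metric=config.evaluation_linear_metric,
            )
            t_nl = register_nonlinear(driver, template, t_lin, template_mask, config)
            artifacts[f"t_lin_{tag}"] = t_lin
            artifacts[f"t_nl_{tag}"] = t_nl
            for stage, transform in (("lin", t_lin), ("nl", t_nl)):
                warped_mask = resample(mask, transform, template, "nearest")
                warped_vol = resample(deblooded, transform, template, "linear")
                artifacts[f"warped_{stage}_{tag}"] = warped_vol
                results[f"dice_{stage}_{tag}"] = dice(warped_mask, template_mask)
                results[f"mi_{stage}_{tag}"] = mutual_information(
                    template, warped_vol, template_mask, bins=config.mi_bins
                )
    except RegistrationError as err:
        raise RegistrationError(f"subject {subject_id}: {err}") from err
    return SubjectEvaluation(subject_id=subject_id, **results), artifacts


def impact_maps(
    cohort_pairs: list[tuple[Volume, Volume]],
    template: Volume,
    config: PipelineConfig | None = None,
) -> tuple[Volume, Volume]:
    """Cohort-maximum deformation maps between the two transform chains.

    Each pair holds the deblooded scan mapped to template space by the
    bloody-driven transform and by the deblooded-driven transform. The
    first is nonlinearly registered to the second; the resulting warp's
    |Jacobian determinant| and displacement magnitude quantify how much
    the artifacts bent the registration. Outputs are voxelwise maxima
    across subjects. Per-subject failures are skipped with a warning;
    all failing is an error.
    """
    from .registration import (displacement_magnitude_map,
                               jacobian_determinant_map)
    from .types import AffineTransform

    config = config or PipelineConfig()
    det_maps: list[Volume] = []
    disp_maps: list[Volume] = []
    for i, (via_bloody, via_deblooded) in enumerate(cohort_pairs):
        try:
            mask_arr = (template.data > template.data.max() * 0.05).astype(np.uint8)
            comp = register_nonlinear(
                via_bloody,
                via_deblooded,
                AffineTransform.identity(),
                BinaryMask(mask_arr, template.affine.copy()),
                config,
                gate="ssd",
            )
        except RegistrationError as err:
            warnings.warn(f"impact map: subject {i} failed: {err}", stacklevel=2)
            continue
        det_maps.append(jacobian_determinant_map(comp, template))
        disp_maps.append(displacement_magnitude_map(comp, template))
    if not det_maps:
        raise RegistrationError("all subjects failed during impact mapping")
    return max_map(det_maps), max_map(disp_maps)


def summarize_cohort(evaluations: list[SubjectEvaluation]) -> CohortSummary:
    """Aggregate subject metrics; paired t-tests need n >= 2."""
    n = len(evaluations)
    if n < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    mean_b, var_b, mean_d, var_d, tstat, pval = {}, {}, {}, {}, {}, {}
    for metric in METRICS:
        xb = np.array([getattr(e, f"{metric}_bloody") for e in evaluations])
        xd = np.array([getattr(e, f"{metric}_deblooded") for e in evaluations])
        mean_b[metric] = float(xb.mean())
        var_b[metric] = float(xb.var(ddof=1))
        mean_d[metric] = float(xd.mean())
        var_d[metric] = float(xd.var(ddof=1))
        t, p = paired_t_test(xb, xd)
        tstat[metric] = t
        pval[metric] = p
    return CohortSummary(n, mean_b, var_b, mean_d, var_d, tstat, pval)


def cohort_summary_table(summary: CohortSummary) -> pd.DataFrame:
    """Four metric rows: mean ± variance for both arms plus significance."""
    rows = []
    for metric in METRICS:
        rows.append(
            {
                "metric": METRIC_ROWS[metric],
                "bloody_mean": summary.mean_bloody[metric],
                "bloody_variance": summary.var_bloody[metric],
                "deblooded_mean": summary.mean_deblooded[metric],
                "deblooded_variance": summary.var_deblooded[metric],
                "significance": summary.p_value[metric],
            }
        )
    return pd.DataFrame(rows)
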