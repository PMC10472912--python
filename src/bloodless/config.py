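"""Pipeline configuration.

The numeric thresholds that define the method (probability-map thresholds
0.1 and 0.2, gradient FWHM 1 mm, gradient-difference blur FWHM 2 mm) have
fixed defaults here; everything else parameterises the surrounding
machinery (registration schedules, expansion caps, replacement blending)
and is exposed so studies can tighten or relax it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "FWHM_TO_SIGMA"]

# sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass
class PipelineConfig:
    # --- blood probability map thresholds ---
    bloodless_threshold: float = 0.1  # keep voxels with blood probability below this
    major_vessel_threshold: float = 0.2  # binarization picking out major vessels

    # --- gradient evidence ---
    gradient_fwhm_mm: float = 1.0
    graddiff_blur_fwhm_mm: float = 2.0

    # --- white-matter grouping / expansion heuristics ---
    wm_connectivity: int = 26
    expansion_max_iters: int = 10
    expansion_graddiff_percentile: float = 90.0  # seed gate, percentile within brain
    expansion_prob_threshold: float = 0.1  # seed gate on blood probability
    expansion_relax_graddiff_percentile: float = 75.0  # relaxed gate during dilation
    expansion_relax_prob_threshold: float = 0.05
    recovery_brightness_z: float = 6.0  # robust z vs main-WM intensities

    # --- CSF replacement ---
    replacement_dilate_iters: int = 2
    replacement_blur_fwhm_mm: float = 1.5

    # --- similarity metric ---
    mi_bins: int = 64

    # --- affine registration schedule ---
    affine_shrinks: tuple[int, ...] = (4, 2, 1)
    affine_smooth_vox: tuple[float, ...] = (2.0, 1.0, 0.0)
    affine_step_mm: float = 2.0
    affine_step_deg: float = 2.0
    affine_step_logscale: float = 0.02
    affine_halvings: tuple[int, ...] = (4, 3, 2)
    affine_max_sweeps: int = 10
    affine_dof: int = 9  # translation + rotation + anisotropic scale
    affine_metric: str = "mi"  # 'mi' or 'cc'
    evaluation_linear_metric: str = "cc"  # objective of the analysis' linear tool

    # --- nonlinear (demons-style) registration schedule ---
    nl_shrinks: tuple[int, ...] = (8, 4, 2, 1)
    nl_iters: tuple[int, ...] = (40, 30, 20, 10)
    nl_sigma_fluid_vox: float = 1.0
    nl_sigma_elastic_vox: float = 1.5
    nl_step: float = 1.0
    nl_max_step_mm: float = 2.0

    # --- pipeline orchestration ---
    pipeline_nonlinear_align: bool = True  # coarse nonlinear template->subject pass
    refinement_passes: int = 1

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bloodless_threshold", "major_vessel_threshold",
                     "expansion_prob_threshold", "expansion_relax_prob_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("gradient_fwhm_mm", "graddiff_blur_fwhm_mm",
                     "replacement_blur_fwhm_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wm_connectivity not in (6, 18, 26):
            raise ValueError("wm_connectivity must be 6, 18 or 26")
        for name in ("expansion_graddiff_percentile",
                     "expansion_relax_graddiff_percentile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0,100], got {v}")
        if self.expansion_max_iters < 0 or self.replacement_dilate_iters < 0:
            raise ValueError("iteration counts must be non-negative")
        for name in ("affine_metric", "evaluation_linear_metric"):
            if getattr(self, name) not in ("mi", "cc"):
                raise ValueError(f"{name} must be 'mi' or 'cc'")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be at least 2")
        for tup in ("affine_shrinks", "affine_smooth_vox", "affine_halvings",
                    "nl_shrinks", "nl_iters"):
            setattr(self, tup, tuple(getattr(self, tup)))
        if len(self.affine_shrinks) != len(self.affine_smooth_vox) or \
                len(self.affine_shrinks) != len(self.affine_halvings):
            raise ValueError("affine schedule tuples must have equal length")
        if len(self.nl_shrinks) != len(self.nl_iters):
            raise ValueError("nonlinear schedule tuples must have equal length")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def fast_config(**kw) -> PipelineConfig:
    """A reduced-iteration schedule for cohort-scale runs on one CPU."""
    base = dict(
        affine_halvings=(4, 3, 2),
        affine_max_sweeps=6,
        nl_shrinks=(8, 4, 2),
        nl_iters=(40, 30, 20),
        nl_sigma_elastic_vox=3.0,
    )
    base.update(kw)
    return PipelineConfig(**base)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON; unknown keys are an error."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if payload is None:
        payload = {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**payload)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    payload = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
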