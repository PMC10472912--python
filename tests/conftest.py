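"""Shared fixtures: small phantoms reused across the suite.

Everything is generated at test time; session scope keeps the expensive
template/subject/bundle construction to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from bloodless.config import PipelineConfig, fast_config
from bloodless.phantom import (PhantomSpec, generate_mra_cohort,
                               generate_subject, generate_template)
from bloodless.pipeline import make_template_bundle


@pytest.fixture(scope="session")
def spec64() -> PhantomSpec:
    return PhantomSpec(grid_shape=(64, 64, 64), rng_seed=0)


@pytest.fixture(scope="session")
def template64(spec64):
    return generate_template(spec64)


@pytest.fixture(scope="session")
def subject64(spec64, template64):
    return generate_subject(spec64, template64)


@pytest.fixture(scope="session")
def mra64(spec64):
    return generate_mra_cohort(spec64, 10, seed=1234)


@pytest.fixture(scope="session")
def bundle64(template64, mra64):
    return make_template_bundle(template64.t1, template64.brain_mask, mra64)


@pytest.fixture(scope="session")
def clean_spec64() -> PhantomSpec:
    """Noise-free, bias-free, unwarped variant for exactness checks."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        rng_seed=0,
        noise_sigma=0.0,
        bias_field_amplitude=0.0,
        warp_amplitude_mm=0.0,
    )


@pytest.fixture(scope="session")
def clean_template64(clean_spec64):
    return generate_template(clean_spec64)


@pytest.fixture(scope="session")
def fast_cfg() -> PipelineConfig:
    return fast_config()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231001)
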