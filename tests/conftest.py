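"""Shared fixtures: phantom scenes and pipeline runs reused across tests.

All randomness is seeded; session-scoped fixtures cache the expensive
phantom pipeline runs.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from handspec.phantom import PhantomSpec, generate_cube, generate_hand_mask
from handspec.pipeline import PipelineConfig, run_pipeline

#: structuring element sized to the phantom population (2 x max finger
#: width + 1), analogous to the 201-px element for full-frame acquisitions
PHANTOM_SE_FULLRES = 27
#: working-resolution factor used for phantom-scale scenes
PHANTOM_DOWNSCALE = 0.5


def phantom_config(spec: PhantomSpec, seed: int | None = None, **overrides) -> PipelineConfig:
    """Pipeline configuration matched to the phantom scene scale."""
    return PipelineConfig(
        phantom=spec,
        seed=spec.seed if seed is None else seed,
        downscale_factor=PHANTOM_DOWNSCALE,
        se_size_fullres=PHANTOM_SE_FULLRES,
        log_level="WARNING",
        **overrides,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(seed=1, noise_sd=0.0, impulse_fraction=0.0)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_spec):
    """(cube, truth) of the default noiseless upright phantom."""
    return generate_cube(noiseless_spec)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Default scene with a short wavelength axis (25 bands) for fast runs."""
    base = PhantomSpec(seed=3)
    return dataclasses.replace(base, wl_stop=base.wl_start + 24 * base.wl_step)


@pytest.fixture(scope="session")
def small_run(small_spec):
    """A full pipeline run on the 25-band phantom."""
    return run_pipeline(phantom_config(small_spec))


@pytest.fixture(scope="session")
def tilted_mask():
    """Mask + truth of a 70 deg inclined noiseless scene."""
    spec = PhantomSpec(seed=2, noise_sd=0.0, impulse_fraction=0.0, rotation_deg=70.0)
    mask, truth = generate_hand_mask(spec)
    return spec, mask, truth
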