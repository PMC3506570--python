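import numpy as np
import pytest

from cardiotract import PhantomSpec, TrackingParams, generate_phantom, run_phantom_pipeline


@pytest.fixture(scope="session")
def small_spec():
    """A compact LV segment at 1 mm resolution (fast, 6-voxel wall)."""
    return PhantomSpec(
        inner_radius=10.0,
        outer_radius=16.0,
        height=40.0,
        spacing=(1.0, 1.0, 1.0),
        alpha_endo=60.0,
        alpha_epi=-60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def sheep_run():
    """Default-condition normal-sheep study: pi*R tracts, 5 deg noise."""
    return run_phantom_pipeline("normal-sheep", seed=1, orientation_noise_sd=5.0)


@pytest.fixture(scope="session")
def sheep_run_noiseless():
    return run_phantom_pipeline("normal-sheep", seed=1, orientation_noise_sd=0.0)


@pytest.fixture(scope="session")
def remote_run():
    return run_phantom_pipeline("remote-zone", seed=1, orientation_noise_sd=5.0)


@pytest.fixture(scope="session")
def sheep_run_roi():
    return run_phantom_pipeline("normal-sheep", seed=1, orientation_noise_sd=5.0, length_mode="roi")
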