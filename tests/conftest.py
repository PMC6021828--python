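import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import moxquant as mq

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """Packaged reference coefficients of the dual-temperature SB-30 calibration."""
    return mq.reference_coefficients()


@pytest.fixture(scope="session")
def grid39():
    """Default 39-mixture calibration grid (corners included)."""
    return mq.gen_calibration_grid(39, seed=7)


@pytest.fixture(scope="session")
def noiseless_dataset(ref, grid39):
    """Noiseless observations of the 39-mixture grid under the reference model."""
    cfg = mq.SimulationConfig(noise_mode="variance", noise_value=0.0, seed=7)
    return mq.gen_observations(grid39, ref, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
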