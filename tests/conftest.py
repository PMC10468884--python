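import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import speckleperf as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_optics():
    return sp.OpticsConfig()


@pytest.fixture(scope="session")
def gradient_scene():
    return sp.build_gradient_scene()


@pytest.fixture(scope="session")
def gradient_runs():
    """Five seeded end-to-end gradient experiments (full pipeline)."""
    return [sp.run_gradient_experiment(seed=s, n_frames=64) for s in range(5)]


@pytest.fixture(scope="session")
def anastomosis_run():
    return sp.run_anastomosis_experiment(seed=11, n_frames=64)


@pytest.fixture(scope="session")
def occlusion_runs():
    return {
        "arterial": sp.run_occlusion_experiment("arterial", seed=3),
        "venous": sp.run_occlusion_experiment("venous", seed=3),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
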