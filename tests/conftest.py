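import numpy as np
import pytest

from sprintfusion.model import SprintVelocityModel
from sprintfusion.synthetic import NoiseModel, make_velocity_profile


@pytest.fixture(scope="session")
def default_truth():
    """Default second-order ground truth over 60 m."""
    return make_velocity_profile(model="order2", distance=60.0)


@pytest.fixture(scope="session")
def noiseless_results():
    """Fitted pipeline on a noiseless 60 m session (shared; read-only)."""
    model = SprintVelocityModel.from_synthetic(
        distance=60.0, noise=NoiseModel.noiseless())
    return model, model.fit()


@pytest.fixture(scope="session")
def noisy_results():
    """Fitted pipeline on a default-noise 60 m session (shared; read-only)."""
    model = SprintVelocityModel.from_synthetic(distance=60.0, seed=0)
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
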