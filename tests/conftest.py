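import numpy as np
import pytest

from synbal import InputTrajectory, SimSettings, random_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_relu_config():
    return random_fixture(6, density=0.5, seed=7, n_inputs=2, n_outputs=2)


@pytest.fixture
def random_inputs(rng):
    def make(n_channels=2, n_steps=40, dt=0.1, count=3):
        return [
            InputTrajectory.from_series(
                rng.normal(size=(n_channels, n_steps)), dt=dt
            )
            for _ in range(count)
        ]

    return make


@pytest.fixture
def sim():
    return SimSettings(dt=0.1)
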