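import numpy as np
import pytest

from dendrocensus.synth_neurons import (
    SyntheticVolumeSpec,
    make_volume_frame,
    random_feasible_spec,
)


@pytest.fixture(scope="session")
def volume_spec():
    return SyntheticVolumeSpec()


@pytest.fixture(scope="session")
def volume_frame(volume_spec):
    return make_volume_frame(volume_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def feasible_specs():
    """A reusable batch of feasible synthetic-neuron descriptor sets."""
    rng = np.random.default_rng(7)
    return [random_feasible_spec(rng) for _ in range(30)]
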