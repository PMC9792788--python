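import numpy as np
import pytest

from chronicgame import SamplingSpec, baseline_parameters, sample_parameters


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def sampling_spec():
    return SamplingSpec(seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_parameter_sets(sampling_spec):
    """A shared pool of assumption-respecting random games."""
    rng = sampling_spec.rng()
    return [sample_parameters(sampling_spec, rng) for _ in range(200)]
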