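import numpy as np
import pytest

from silentspeech.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """10 trials/class at the protocol sampling rate; enough to split."""
    return GeneratorConfig(n_per_class=10, seed=7)


@pytest.fixture(scope="session")
def small_trials(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
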