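import numpy as np
import pytest

from rdaunet import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def desk_phantom_config() -> PhantomConfig:
    return PhantomConfig.desk_scale()


@pytest.fixture(scope="session")
def phantom_sample(desk_phantom_config):
    return generate_phantom(desk_phantom_config, seed=7)


@pytest.fixture(scope="session")
def small_samples(desk_phantom_config):
    """A dozen 64x64 phantoms for pipeline tests."""
    return [generate_phantom(desk_phantom_config, seed=s) for s in range(12)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask(rng: np.random.Generator, size: int = 16, p: float = 0.4) -> np.ndarray:
    return (rng.random((size, size)) < p).astype(np.uint8)
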