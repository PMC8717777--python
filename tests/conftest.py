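import numpy as np
import pytest

from colnet.phantom import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A small but representative phantom configuration (32x32, 4 channels)."""
    return PhantomConfig(n_cases=10, height=32, width=32, n_channels=4,
                         core_radius_range=(2.0, 4.0),
                         ring_width_range=(1.5, 3.0),
                         noise_sd=0.05, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_mask(rng: np.random.Generator, shape=(16, 16),
                p: float = 0.3) -> np.ndarray:
    """Random nonempty binary mask."""
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if m.any():
            return m
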