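import numpy as np
import pytest

from sbpet import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom64_clean():
    """Noise-free default phantom, 64^3, no lesions."""
    return generate_phantom(PhantomParams(grid_size=64, seed=1))


@pytest.fixture(scope="session")
def phantom32_noisy():
    """Small noisy phantom with bias field."""
    return generate_phantom(
        PhantomParams(grid_size=32, seed=7, noise_sd=0.02, bias_amplitude=0.2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
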