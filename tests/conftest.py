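import numpy as np
import pytest

from gelband.synthetic import SyntheticGelSpec, generate_gel


@pytest.fixture(scope="session")
def clean_gel():
    """Uniform-background, noise-free, warp-free default-ladder gel."""
    spec = SyntheticGelSpec(
        noise_sigma=0.0, blur_sigma=0.0, warp_amplitude=0.0,
        background=(20.0, 0.0), seed=3,
    )
    return generate_gel(spec)


@pytest.fixture(scope="session")
def clean_gel_16bit():
    """Same geometry at 16-bit depth (negligible quantisation)."""
    spec = SyntheticGelSpec(
        noise_sigma=0.0, blur_sigma=0.0, warp_amplitude=0.0,
        background=(20.0 * 257, 0.0), seed=3,
        bit_depth=16, amplitude_per_ng=0.75 * 257,
    )
    return generate_gel(spec)


@pytest.fixture(scope="session")
def default_gel():
    """A gel under the generator's default (noisy, warped) conditions."""
    return generate_gel(SyntheticGelSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)

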