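import numpy as np
import pytest

from bonesep.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The default 22-bone phantom, generated once per session."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and blur-free variant with exact two-level intensities."""
    return generate_phantom(PhantomSpec(seed=0, noise_sd=0.0, blur_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
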