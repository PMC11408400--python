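import numpy as np
import pytest

from tmdkit.cube_io import HyperCube
from tmdkit import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cube(rng):
    """A small random digital-number cube with realistic dynamic range."""
    data = rng.uniform(100, 4000, size=(12, 10, 5))
    return HyperCube(data=data, wavelengths=np.linspace(400, 800, 5))


@pytest.fixture(scope="session")
def default_phantom():
    """One default 64x64x40 phantom shared across read-only tests."""
    return phantom.generate(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return phantom.generate(
        phantom.PhantomSpec(seed=7, noise_sigma=0.0, texture_sigma=0.0)
    )
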