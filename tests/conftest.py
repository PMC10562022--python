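import numpy as np
import pytest

from cutsct.phantom_sim import PhantomSpec, make_phantom
from cutsct.preprocess import extract_body_mask


@pytest.fixture(scope="session")
def phantom():
    """One 64x64x16 pelvic phantom with its label map (seed 7)."""
    return make_phantom(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """A quicker 32x32x8 phantom for volume-level plumbing tests."""
    return make_phantom(PhantomSpec(shape=(32, 32, 8)), seed=3)


@pytest.fixture(scope="session")
def phantom_mask(phantom):
    vol, _ = phantom
    return extract_body_mask(vol)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
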