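import numpy as np
import pytest
from hypothesis import settings

from rnst.backbones import build_backbone
from rnst.denoise import DenoiserSpec
from rnst.nst import NSTConfig
from rnst.phantoms import PhantomSpec, make_pair
from rnst.reconstruct import RNSTConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def backbone():
    """The seeded offline test backbone shared across the suite."""
    return build_backbone("tiny-random", seed=0)


@pytest.fixture(scope="session")
def phantom_pair():
    """(content, guidance, clean) triplet in frozen-guidance mode."""
    return make_pair(PhantomSpec(seed=1), mode="frozen")


@pytest.fixture()
def reduced_schedule():
    """Small-depth outer-loop schedule sized for 64x64 phantom tests."""
    return RNSTConfig(n0=20, n_step=10, n_style=2, n_line=3, n_iter=3,
                      mu=0.1, lam=0.3)


@pytest.fixture()
def nst_defaults():
    return NSTConfig()


@pytest.fixture()
def gaussian_denoiser():
    return DenoiserSpec("gaussian", kernel=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
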