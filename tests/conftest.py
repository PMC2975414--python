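import numpy as np
import pytest

from follikel import (
    BilateralParams,
    SpeckleParams,
    apply_speckle,
    default_phantom_spec,
    filter_iterative,
    generate_phantom,
)


@pytest.fixture(scope="session")
def packaged_clean():
    return generate_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def packaged_noisy(packaged_clean):
    return apply_speckle(packaged_clean, SpeckleParams(seed=0))


@pytest.fixture(scope="session")
def filtered_normalized_07(packaged_noisy):
    """Packaged noisy phantom after the proposed filter at its optimum."""
    params = BilateralParams(sigma_d=3.0, sigma_r=0.7, mode="normalized", iterations=5)
    return filter_iterative(packaged_noisy, params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
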