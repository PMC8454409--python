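import warnings

import numpy as np
import pytest

from perirad import PhantomSpec, build_ring_masks, generate_phantom
from perirad.texture import TextureConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*truncated at the grid boundary.*")
        warnings.filterwarnings("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair():
    """One positive-phenotype phantom with its ring compartments."""
    vol, mask = generate_phantom(PhantomSpec(seed=7))
    comps = build_ring_masks(mask, vol.spacing_mm)
    return vol, mask, comps


@pytest.fixture(scope="session")
def fast_config():
    return TextureConfig.fast()
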