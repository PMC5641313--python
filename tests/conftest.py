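import numpy as np
import pytest

from sbskit.mixture import estimate_pure_curves
from sbskit.profiles import make_block_profile


@pytest.fixture(scope="session")
def toy_block_profile():
    """The classic two-color toy layout: four alternating blocks of 10."""
    return make_block_profile(40, [(0, 10, 0), (10, 20, 1), (20, 30, 0), (30, 40, 1)])


@pytest.fixture(scope="session")
def pure_curves(tmp_path_factory):
    """Simulated pure-state P(s) curves shared across mixture tests."""
    cache = tmp_path_factory.mktemp("pure_cache")
    return estimate_pure_curves(n_beads=64, cache_dir=str(cache))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
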