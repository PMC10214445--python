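import numpy as np
import pytest

from vesiwrap.membrane import MembranePotentialParams


@pytest.fixture(scope="session")
def potential_params():
    return MembranePotentialParams()


@pytest.fixture(scope="session")
def small_vesicle():
    """642-bead vesicle shared by the dynamics tests."""
    from vesiwrap.membrane import build_vesicle
    return build_vesicle(642, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
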