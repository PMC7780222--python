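import numpy as np
import pytest

import virtopop as vp


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture(scope="session")
def grid17():
    return vp.SpaceGrid(17, 17)


@pytest.fixture(scope="session")
def grid33():
    return vp.SpaceGrid(33, 33)


@pytest.fixture(scope="session")
def grid129():
    return vp.SpaceGrid(129, 129)
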