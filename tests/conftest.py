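import numpy as np
import pytest

from krillspr import FleetPars, base_krill


@pytest.fixture(scope="session")
def base_lh():
    return base_krill()


@pytest.fixture(scope="session")
def base_fleet():
    return FleetPars(sl50=38.0, sl95=45.0, fm=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
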