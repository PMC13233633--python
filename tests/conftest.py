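import numpy as np
import pytest

from isnkit.fixtures import reference_pair
from isnkit.network import ISNetwork, ISPParams


@pytest.fixture(scope="session")
def ref_pair() -> ISPParams:
    """Inverse-designed stable-spiral pair: UP at (5, 10) Hz, Tr=-50/s, Det=1.5e4/s^2."""
    return reference_pair()


@pytest.fixture(scope="session")
def ref_net(ref_pair) -> ISNetwork:
    return ISNetwork.from_pair(ref_pair)


@pytest.fixture()
def leak_net() -> ISNetwork:
    """Two uncoupled pure-leak units (all weights and thresholds zero)."""
    return ISNetwork(n_pairs=1, weights=np.zeros((2, 2)),
                     thresholds=np.zeros(2), tau=0.010)
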