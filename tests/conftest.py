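import pytest

from cllrs.network_core import parse_network
from cllrs.synthetic_data import reconstructed_cll_network, toy_networks


@pytest.fixture(scope="session")
def toys():
    """Toy networks with their exhaustive ground-truth landscapes."""
    return toy_networks()


@pytest.fixture(scope="session")
def cll_card():
    """The reconstructed CLL/RS model card (39 nodes)."""
    return reconstructed_cll_network()


@pytest.fixture()
def swap_net():
    return parse_network("targets, factors\nA, B\nB, A\n")


@pytest.fixture()
def repressor_net():
    return parse_network("targets, factors\nR, R\nT, !R\n")
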