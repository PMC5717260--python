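import pytest

from netdyn.network import BooleanNetwork, NodeStatusProfile
from netdyn.synthetic import make_reference_p53_network


@pytest.fixture(scope="session")
def ref_net() -> BooleanNetwork:
    return make_reference_p53_network()


@pytest.fixture
def hold_net() -> BooleanNetwork:
    """Two nodes that each hold or follow the other (weight 1, basal 0)."""
    return BooleanNetwork(
        node_names=("X", "Y"),
        links=(("Y", "X", 1), ("X", "Y", 1)),
        basal={"X": 0, "Y": 0},
    )


@pytest.fixture
def oscillator_net() -> BooleanNetwork:
    """Two-node relaxation oscillator cycling 00 -> 10 -> 11 -> 01 -> 00."""
    return BooleanNetwork(
        node_names=("X", "Y"),
        links=(("Y", "X", -2), ("X", "Y", 2)),
        basal={"X": 1, "Y": -1},
    )


def profile_on(net: BooleanNetwork, **statuses: str) -> NodeStatusProfile:
    """All-N profile with the given node statuses overridden."""
    status = {n: "N" for n in net.node_names}
    status.update(statuses)
    return NodeStatusProfile(status)


@pytest.fixture
def make_profile():
    return profile_on
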