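import pytest

from netpharm.network_io import InteractionNetwork


def net_from_edges(edges, extra_nodes=()):
    net = InteractionNetwork()
    for u, v in edges:
        net.add_edge(u, v)
    for n in extra_nodes:
        net.add_node(n)
    return net


@pytest.fixture
def triangle():
    return net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc():
    return net_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star5():
    """Centre Z with 4 leaves."""
    return net_from_edges([("Z", l) for l in "ABCD"])
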