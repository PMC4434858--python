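import pytest

from netcooperate import MetabolicNetwork, figure1_networks


def net_from_edges(name, edges, extra_nodes=()):
    nodes = frozenset(u for e in edges for u in e) | frozenset(extra_nodes)
    return MetabolicNetwork(name=name, nodes=nodes, edges=frozenset(edges))


@pytest.fixture(scope="session")
def toy_pair():
    return figure1_networks()


@pytest.fixture(scope="session")
def blue(toy_pair):
    return toy_pair.consumer


@pytest.fixture(scope="session")
def red(toy_pair):
    return toy_pair.provider
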