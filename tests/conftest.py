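import pytest

from bacnet.io_formats import EdgeRecord
from bacnet.network import PPINetwork
from bacnet.synthetic import WorldConfig, generate_world


def net_from_pairs(pairs):
    return PPINetwork(EdgeRecord(a, b) for a, b in pairs)


@pytest.fixture(scope="session")
def default_world():
    """One desk-scale synthetic world shared by read-only tests."""
    return generate_world(seed=7)


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for faster statistical checks."""
    config = WorldConfig(
        n_target=80,
        n_background_edges=80,
        n_complexes=2,
        complex_size_range=(4, 6),
        n_reference_noise_edges=40,
        n_decoy_hits_per_kind=5,
        n_secondary_hits=8,
        n_decoy_domain_hits=10,
        n_unused_ddis=10,
    )
    return generate_world(seed=11, config=config)


@pytest.fixture
def triangle():
    return net_from_pairs([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return net_from_pairs([("a", "b"), ("b", "c")])


@pytest.fixture
def star5():
    return net_from_pairs([("hub", f"leaf{i}") for i in range(4)])
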