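import pytest

from regcore import bladder_core_model, breast_core_model
from regcore.network import Effect, Interaction, RegulatoryNetwork


@pytest.fixture(scope="session")
def bladder_model():
    return bladder_core_model()


@pytest.fixture(scope="session")
def breast_model():
    return breast_core_model()


def build_network(edges):
    """Network from (source, target, effect-str) triples."""
    net = RegulatoryNetwork()
    for s, t, e in edges:
        net.add_interaction(Interaction(s, t, Effect(e)))
    return net


@pytest.fixture
def three_cycle():
    return build_network(
        [("A", "B", "activation"), ("B", "C", "inhibition"), ("C", "A", "activation")]
    )
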