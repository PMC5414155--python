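import pytest

from emkin.em_kinetics import (
    anchored_parameter_set,
    build_model,
    decompose,
    reaction_forms,
)
from emkin.fba_core import FluxState
from emkin.network_model import MetabolicNetwork, Metabolite, Reaction
from emkin.synthetic_data import generate_toy_network


@pytest.fixture(scope="session")
def truth3():
    """Three-branch fermentation ground truth (14 reactions)."""
    return generate_toy_network(3, seed=2)


@pytest.fixture(scope="session")
def truth2():
    """Two-branch fermentation ground truth (11 reactions)."""
    return generate_toy_network(2, seed=1)


def linear_chain_model(producer_rev=0.5, consumer_rev=0.5, exporter_rev=0.5,
                       flux=5.0):
    """source -> a -> b -> sink with designed saturation margins.

    Reversibility R controls the margin: the forward capacity of a step is
    v/(1-R), so small R means a tight Vmax and a saturable node.
    """
    mets = [Metabolite(m) for m in ("a", "b")]
    rxns = [
        Reaction("PRD", {"a": -1.0}, -10 * flux, 0.0),
        Reaction("CNS", {"a": -1.0, "b": 1.0}, 0.0, 100 * flux),
        Reaction("EXB", {"b": -1.0}, 0.0, 100 * flux),
    ]
    net = MetabolicNetwork(mets, rxns)
    ref = FluxState(
        {"PRD": -flux, "CNS": flux, "EXB": flux}, "EXB", flux, "optimal"
    )
    tmpl = decompose(net)
    fractions = {
        r: {f: 1.0 for f in reaction_forms(tmpl, r)} for r in ("PRD", "CNS", "EXB")
    }
    revs = {
        "PRD": {0: producer_rev, 1: producer_rev},
        "CNS": {0: consumer_rev, 1: consumer_rev, 2: consumer_rev},
        "EXB": {0: exporter_rev, 1: exporter_rev},
    }
    params = anchored_parameter_set(tmpl, ref, fractions, revs)
    return build_model(net, tmpl, params, uptake_reaction="PRD")


@pytest.fixture()
def saturated_node_model():
    """Near-irreversible producer feeding a tight consumer: upregulating the
    producer twofold exceeds the consumer's capacity and 'a' accumulates."""
    return linear_chain_model(producer_rev=1e-9, consumer_rev=0.25,
                              exporter_rev=0.8)


@pytest.fixture()
def robust_chain_model():
    """Generous margins everywhere: twofold perturbations stay convergent."""
    return linear_chain_model(producer_rev=0.8, consumer_rev=0.8,
                              exporter_rev=0.8, flux=1.0)
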