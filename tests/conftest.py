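import networkx as nx
import numpy as np
import pytest

from homophilynet import Agent, KinNetwork, SocialNetwork, assign_traits


def make_kin_network(n: int, edges=(), traits=None, seed: int | None = None) -> KinNetwork:
    """Build a KinNetwork with synthetic disjoint grandparent sets.

    Intended for friendship/metrics tests where kinship provenance is
    irrelevant; grandparent sets are disjoint so the edge rule is not implied.
    """
    agents = [
        Agent(id=i, trait=0.0,
              grandparents=frozenset({4 * i, 4 * i + 1, 4 * i + 2, 4 * i + 3}))
        for i in range(n)
    ]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    net = KinNetwork(agents=agents, graph=g)
    if traits is not None:
        agents = [
            Agent(id=a.id, trait=float(t), grandparents=a.grandparents)
            for a, t in zip(net.agents, traits)
        ]
        net = KinNetwork(agents=agents, graph=net.graph)
    elif seed is not None:
        net = assign_traits(net, seed=seed)
    return net


def make_social(n: int, kin_edges=(), full_extra=(), traits=None, nu: int = 2,
                seed: int | None = None) -> SocialNetwork:
    """SocialNetwork whose full graph is kin_edges plus full_extra friend edges."""
    kin = make_kin_network(n, kin_edges, traits=traits, seed=seed)
    net = SocialNetwork.from_kin(kin, nu=nu)
    extra = [e for e in full_extra if not net.kin.has_edge(*e)]
    net.full.add_edges_from(extra, is_kin=False)
    return net


def social_from_graph(graph: nx.Graph, nu: int = 2,
                      kin_graph: nx.Graph | None = None) -> SocialNetwork:
    """Wrap an arbitrary networkx graph (nodes relabelled 0..n-1) as a SocialNetwork."""
    g = nx.convert_node_labels_to_integers(graph, ordering="sorted")
    kin_edges = list(kin_graph.edges) if kin_graph is not None else []
    return make_social(g.number_of_nodes(), kin_edges=kin_edges,
                       full_extra=list(g.edges), nu=nu)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
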