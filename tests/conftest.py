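import networkx as nx
import numpy as np
import pytest

from cernet.cerna import CeRNANetwork


@pytest.fixture(scope="session")
def study():
    """One end-to-end synthetic study shared across tests (read-only)."""
    from cernet.synthetic import simulate_study

    return simulate_study(seed=2024)


def make_bipartite_network(rng: np.random.Generator, n_lnc=4, n_mrna=8, p=0.4) -> CeRNANetwork:
    """Small random bipartite ceRNA network with dummy edge evidence."""
    net = CeRNANetwork()
    lncs = [f"L{i}" for i in range(n_lnc)]
    mrnas = [f"M{i}" for i in range(n_mrna)]
    for l in lncs:
        for m in mrnas:
            if rng.random() < p:
                net.graph.add_node(l, node_class="lncRNA")
                net.graph.add_node(m, node_class="mRNA")
                net.graph.add_edge(
                    l, m, shared_mirnas=frozenset({"mirX"}), n_shared=1, p_value=1e-5
                )
    return net


def nx_from_edges(nodes, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g
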