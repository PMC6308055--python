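"""Centrality analysis and consensus hub detection on the ceRNA network.

Three node-level metrics are used: degree (incident edge count),
betweenness (unnormalized shortest-path counts over unordered node
pairs) and closeness ((n-1)/sum of distances, computed within each
connected component). Hubs are the intersection of the top-k lists
under the three metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cerna import CeRNANetwork
from .errors import InvalidArgumentError

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "centrality_table",
    "HubReport",
    "hub_consensus",
]


def _as_graph(network: CeRNANetwork | nx.Graph) -> nx.Graph:
    g = network.graph if isinstance(network, CeRNANetwork) else network
    if g.number_of_nodes() == 0:
        raise InvalidArgumentError("network is empty")
    return g


def degree_centrality(network: CeRNANetwork | nx.Graph) -> dict[str, int]:
    """Incident edge count per node."""
    g = _as_graph(network)
    return {n: int(d) for n, d in g.degree()}


def betweenness_centrality(network: CeRNANetwork | nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness: sum over unordered pairs {s,t} (s,t != v)
    of the fraction of shortest s-t paths passing through v.

    Disconnected graphs are handled naturally (pairs in different
    components contribute nothing).
    """
    g = _as_graph(network)
    return dict(nx.betweenness_centrality(g, normalized=False))


def closeness_centrality(
    network: CeRNANetwork | nx.Graph, convention: str = "n-1"
) -> dict[str, float]:
    """Closeness per node, computed within its connected component.

    ``convention`` selects the numerator constant: ``"n-1"`` (default)
    gives (m-1)/sum(dist) for a component of m nodes; ``"n"`` gives
    m/sum(dist). Isolated nodes have undefined closeness (NaN).
    """
    if convention not in ("n-1", "n"):
        raise InvalidArgumentError(f"convention must be 'n-1' or 'n', got {convention!r}")
    g = _as_graph(network)
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        m = len(comp)
        if m == 1:
            out[next(iter(comp))] = float("nan")
            continue
        sub = g.subgraph(comp)
        for v in comp:
            total = sum(nx.single_source_shortest_path_length(sub, v).values())
            numer = m - 1 if convention == "n-1" else m
            out[v] = numer / total
    return out


def centrality_table(
    network: CeRNANetwork | nx.Graph, closeness_convention: str = "n-1"
) -> pd.DataFrame:
    """All three centralities for every node, indexed by node id."""
    g = _as_graph(network)
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    clo = closeness_centrality(g, convention=closeness_convention)
    classes = {n: g.nodes[n].get("node_class", "") for n in g.nodes}
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "node_class": [classes[n] for n in nodes],
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass
class HubReport:
    """Top-k lists per centrality metric and their three-way intersection."""

    top_k: int
    top_degree: list[str]
    top_betweenness: list[str]
    top_closeness: list[str]
    hub_nodes: set[str]

    def to_dict(self) -> dict:
        return {
            "top_k": self.top_k,
            "top_degree": self.top_degree,
            "top_betweenness": self.top_betweenness,
            "top_closeness": self.top_closeness,
            "hub_nodes": sorted(self.hub_nodes),
        }


def _top_k(values: pd.Series, k: int, include_ties: bool) -> list[str]:
    # Descending value, then lexicographic node id; NaN sorts last.
    filled = values.fillna(-np.inf)
    order = sorted(filled.index, key=lambda n: (-filled[n], n))
    top = order[:k]
    if include_ties and len(order) > k:
        boundary = filled[top[-1]]
        for n in order[k:]:
            if filled[n] == boundary:
                top.append(n)
            else:
                break
    return top


def hub_consensus(table: pd.DataFrame, k: int = 30, include_ties: bool = False) -> HubReport:
    """Intersect the top-k nodes under degree, betweenness and closeness.

    Ties at the top-k boundary are broken lexicographically by node id
    (deterministic); set ``include_ties`` to keep every node tied with
    the boundary value instead.
    """
    if k <= 0:
        raise InvalidArgumentError(f"k must be positive, got {k}")
    if k > len(table):
        raise InvalidArgumentError(f"k={k} exceeds node count {len(table)}")
    tops = {
        metric: _top_k(table[metric], k, include_ties)
        for metric in ("degree", "betweenness", "closeness")
    }
    hubs = set(tops["degree"]) & set(tops["betweenness"]) & set(tops["closeness"])
    return HubReport(
        top_k=k,
        top_degree=tops["degree"],
        top_betweenness=tops["betweenness"],
        top_closeness=tops["closeness"],
        hub_nodes=hubs,
    )
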