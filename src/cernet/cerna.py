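"""Shared-miRNA hypergeometric test and bipartite ceRNA network assembly.

Two RNAs that bind many of the same miRNAs are candidate competing
endogenous RNAs (ceRNAs): the lncRNA can titrate miRNAs away from the
mRNA ("sponging"). For a candidate lncRNA-mRNA pair the evidence is the
upper hypergeometric tail of the observed shared-miRNA count x given
the background of T miRNAs, of which M interact with the lncRNA and k
with the mRNA:

    P(X >= x) = 1 - sum_{i=0}^{x-1} C(k,i) C(T-k, M-i) / C(T, M)

Pairs with P below a significance threshold, both members of which are
differentially expressed, become the edges of a bipartite lncRNA-mRNA
network whose edges carry their mediating miRNA sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import InvalidArgumentError, NotFoundError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "CeRNAPairStats",
    "CeRNANetwork",
    "hypergeometric_tail",
    "shared_mirna_stats",
    "test_all_pairs",
    "build_network",
]

LNCRNA = "lncRNA"
MRNA = "mRNA"


@dataclass
class InteractionTable:
    """RNA -> miRNA interaction records for a single RNA class.

    ``table`` holds columns ``rna_id`` and ``mirna_id``; duplicate
    records are collapsed (only set membership matters, not CLIP read
    multiplicity).
    """

    table: pd.DataFrame
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in (LNCRNA, MRNA):
            raise InvalidArgumentError(f"rna_class must be lncRNA or mRNA, got {self.rna_class!r}")
        required = {"rna_id", "mirna_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise InvalidArgumentError(f"interaction table missing columns: {sorted(missing)}")
        self.table = self.table[["rna_id", "mirna_id"]].drop_duplicates().reset_index(drop=True)
        self._sets: dict[str, frozenset[str]] = {
            rna: frozenset(grp) for rna, grp in self.table.groupby("rna_id")["mirna_id"]
        }

    @property
    def rna_ids(self) -> list[str]:
        return sorted(self._sets)

    @property
    def mirna_universe(self) -> frozenset[str]:
        return frozenset(self.table["mirna_id"])

    def mirnas_of(self, rna_id: str) -> frozenset[str]:
        try:
            return self._sets[rna_id]
        except KeyError:
            raise NotFoundError(f"RNA {rna_id!r} not in {self.rna_class} table") from None


@dataclass
class CeRNAPairStats:
    """Counting summary for one candidate lncRNA-mRNA pair.

    T: background miRNA count; M: miRNAs of the lncRNA; k: miRNAs of
    the mRNA; x: shared; shared_mirnas: the shared ids; p_value: upper
    hypergeometric tail (None until tested).
    """

    lncrna_id: str
    mrna_id: str
    T: int
    M: int
    k: int
    x: int
    shared_mirnas: frozenset[str] = frozenset()
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.M, self.k) and self.M <= self.T and self.k <= self.T):
            raise InvalidArgumentError(
                f"inconsistent pair counts T={self.T}, M={self.M}, k={self.k}, x={self.x}"
            )


def hypergeometric_tail(T: int, M: int, k: int, x: int) -> float:
    """Upper tail P(X >= x) for X ~ Hypergeometric(T, M, k).

    X is the overlap between a fixed k-subset and a uniformly drawn
    M-subset of a T-element background. Computed by summing the pmf
    from x upward in log space (log-binomials via gammaln), which is
    the same quantity as the complement form 1 - sum_{i<x} but remains
    accurate when the tail is tiny. Stable for T well beyond 1e4.
    """
    for name, v in (("T", T), ("M", M), ("k", k), ("x", x)):
        if int(v) != v or v < 0:
            raise InvalidArgumentError(f"{name} must be a non-negative integer, got {v}")
    if not (x <= min(M, k) and M <= T and k <= T):
        raise InvalidArgumentError(
            f"need 0 <= x <= min(M,k) and M,k <= T; got T={T}, M={M}, k={k}, x={x}"
        )
    if x == 0:
        return 1.0  # empty sum in the complement form

    def log_comb(n: int, r: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    # pmf(i) = C(k,i) C(T-k, M-i) / C(T,M), support max(0, M-(T-k)) <= i <= min(M,k)
    lo = max(x, M - (T - k))
    hi = min(M, k)
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1)
    log_pmf = log_comb(k, i) + log_comb(T - k, M - i) - float(log_comb(T, np.array(M)))
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def shared_mirna_stats(
    lnc_table: InteractionTable,
    mrna_table: InteractionTable,
    lncrna_id: str,
    mrna_id: str,
    background_size: int | None = None,
) -> CeRNAPairStats:
    """Count the shared-miRNA configuration for one lncRNA-mRNA pair.

    The background T defaults to the number of distinct miRNAs in the
    union of the two interaction tables — the only background under
    which both M and k are well defined; pass ``background_size`` to
    override (e.g. a curated genome-wide miRNA count).
    """
    lnc_set = lnc_table.mirnas_of(lncrna_id)
    mrna_set = mrna_table.mirnas_of(mrna_id)
    T = background_size or len(lnc_table.mirna_universe | mrna_table.mirna_universe)
    shared = lnc_set & mrna_set
    return CeRNAPairStats(
        lncrna_id=lncrna_id,
        mrna_id=mrna_id,
        T=T,
        M=len(lnc_set),
        k=len(mrna_set),
        x=len(shared),
        shared_mirnas=frozenset(shared),
    )


def test_all_pairs(
    lnc_table: InteractionTable,
    mrna_table: InteractionTable,
    lnc_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
    alpha: float = 0.001,
    background_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric-test every (lncRNA, mRNA) pair in the cross product.

    Returns one row per pair with columns lncrna_id, mrna_id, T, M, k,
    x, shared_mirnas (frozenset), p_value, significant. Significance is
    strict p < alpha, uncorrected.
    """
    if lnc_ids is None:
        lnc_ids = lnc_table.rna_ids
    if mrna_ids is None:
        mrna_ids = mrna_table.rna_ids
    if not lnc_ids or not mrna_ids:
        raise InvalidArgumentError("lnc_ids and mrna_ids must be non-empty")

    T = background_size or len(lnc_table.mirna_universe | mrna_table.mirna_universe)
    lnc_sets = {l: lnc_table.mirnas_of(l) for l in lnc_ids}
    mrna_sets = {m: mrna_table.mirnas_of(m) for m in mrna_ids}

    tail_cache: dict[tuple[int, int, int], float] = {}
    rows = []
    for l in lnc_ids:
        ls = lnc_sets[l]
        for m in mrna_ids:
            ms = mrna_sets[m]
            shared = ls & ms
            key = (len(ls), len(ms), len(shared))
            p = tail_cache.get(key)
            if p is None:
                p = tail_cache[key] = hypergeometric_tail(T, len(ls), len(ms), len(shared))
            rows.append(
                {
                    "lncrna_id": l,
                    "mrna_id": m,
                    "T": T,
                    "M": len(ls),
                    "k": len(ms),
                    "x": len(shared),
                    "shared_mirnas": frozenset(shared),
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CeRNANetwork:
    """Bipartite lncRNA-mRNA graph; miRNAs live on edges, not as nodes.

    Each edge carries ``shared_mirnas`` (frozenset), ``n_shared`` and
    ``p_value``. Nodes carry ``node_class`` in {lncRNA, mRNA}. Nodes
    with no surviving edge are excluded.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def lncrna_nodes(self) -> set[str]:
        return {n for n, c in self.graph.nodes(data="node_class") if c == LNCRNA}

    @property
    def mrna_nodes(self) -> set[str]:
        return {n for n, c in self.graph.nodes(data="node_class") if c == MRNA}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Edges as (lncrna_id, mrna_id) tuples."""
        out = set()
        for u, v in self.graph.edges:
            if self.graph.nodes[u]["node_class"] == LNCRNA:
                out.add((u, v))
            else:
                out.add((v, u))
        return out


def build_network(
    pair_stats: pd.DataFrame,
    deg_lnc_ids: set[str],
    deg_mrna_ids: set[str],
    alpha: float = 0.001,
) -> CeRNANetwork:
    """Assemble the ceRNA network from tested pairs and the DEG sets.

    An edge survives iff p_value < alpha and both endpoints are
    differentially expressed. An empty result is a valid empty network.
    """
    net = CeRNANetwork()
    keep = pair_stats[
        (pair_stats["p_value"] < alpha)
        & pair_stats["lncrna_id"].isin(deg_lnc_ids)
        & pair_stats["mrna_id"].isin(deg_mrna_ids)
    ]
    for row in keep.sort_values(["lncrna_id", "mrna_id"]).itertuples(index=False):
        net.graph.add_node(row.lncrna_id, node_class=LNCRNA)
        net.graph.add_node(row.mrna_id, node_class=MRNA)
        net.graph.add_edge(
            row.lncrna_id,
            row.mrna_id,
            shared_mirnas=frozenset(row.shared_mirnas),
            n_shared=int(row.x),
            p_value=float(row.p_value),
        )
    if net.graph.number_of_edges() == 0:
        logger.warning("ceRNA network is empty (no pair passed alpha=%g with DEG endpoints)", alpha)
    return net
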