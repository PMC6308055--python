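"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (exhaustive
enumeration, BFS, direct linear algebra) so it shares no code path
with the implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import defaultdict, deque
from fractions import Fraction

import numpy as np

# ---------------------------------------------------------------------------
# hypergeometric tail by exhaustive enumeration


def enumerate_overlap_tails(T: int, k: int) -> dict[tuple[int, int], Fraction]:
    """Exact P(X >= x) for every (M, x), by enumerating all subsets of a
    T-element background against the fixed k-set {0..k-1}.

    Returns {(M, x): tail} with exact rational arithmetic.
    """
    marked = set(range(k))
    counts: dict[int, defaultdict[int, int]] = {m: defaultdict(int) for m in range(T + 1)}
    for size in range(T + 1):
        for subset in itertools.combinations(range(T), size):
            counts[size][len(marked.intersection(subset))] += 1
    tails: dict[tuple[int, int], Fraction] = {}
    for m in range(T + 1):
        total = sum(counts[m].values())
        for x in range(min(m, k) + 1):
            ge = sum(c for o, c in counts[m].items() if o >= x)
            tails[(m, x)] = Fraction(ge, total)
    return tails


# ---------------------------------------------------------------------------
# graph oracles (adjacency as dict of sets; no networkx)


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_counts(adj: dict, source) -> tuple[dict, dict]:
    """(distances, number of shortest paths) from source, via the DP
    sigma[t] = sum of sigma[u] over predecessors u on shortest paths."""
    dist = bfs_distances(adj, source)
    sigma = {source: 1}
    for t in sorted(dist, key=dist.get):
        if t == source:
            continue
        sigma[t] = sum(sigma[u] for u in adj[t] if u in dist and dist[u] == dist[t] - 1)
    return dist, sigma


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalized betweenness over unordered pairs {s,t}, s != t != v:
    sum of sigma_st(v)/sigma_st with sigma_st(v) = sigma_sv * sigma_vt
    when v lies on a shortest s-t path."""
    nodes = sorted(adj)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = shortest_path_counts(adj, s)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return bc


def closeness_oracle(adj: dict, convention: str = "n-1") -> dict:
    """(m-1)/sum(dist) (or m/sum) within each connected component; NaN
    for isolated nodes."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        m = len(dist)
        if m == 1:
            out[v] = float("nan")
            continue
        total = sum(dist.values())
        out[v] = (m - 1 if convention == "n-1" else m) / total
    return out


def degree_oracle(edges: list[tuple]) -> dict:
    deg: defaultdict = defaultdict(int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return dict(deg)


def edges_to_adj(nodes: list, edges: list[tuple]) -> dict:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def random_graph(rng: np.random.Generator, n_max: int = 12):
    """Random Erdos-Renyi-style graph with 2..n_max nodes; returns
    (nodes, edges). Isolated nodes are possible."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.8))
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges


# ---------------------------------------------------------------------------
# RWR fixed point by direct linear solve


def rwr_linear_solve(matrix: np.ndarray, p0: np.ndarray, r: float) -> np.ndarray:
    """Solve (I - (1-r) M) P = r P_0 directly."""
    n = matrix.shape[0]
    return np.linalg.solve(np.eye(n) - (1.0 - r) * matrix, r * p0)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by hand


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Hand-rolled BH: sort ascending, q_i = p_i * m / i, cumulative min
    from the largest rank down, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
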