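"""Random walk with restart (RWR) gene prioritization with a permutation null.

A walker starts from a uniform distribution over seed genes and at each
step either moves to a uniformly chosen neighbor (probability 1-r) or
restarts at the seed distribution (probability r):

    P_{i+1} = (1 - r) M P_i + r P_0

where M is the column-stochastic normalized adjacency. The iteration is
a contraction (factor 1-r in L1), so it converges to the unique fixed
point of (I - (1-r)M) P = r P_0; iteration stops when the L1 step
difference drops below the tolerance. Statistical significance of a
node's stationary probability is assessed against seed sets of the same
size drawn at random from a candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cerna import CeRNANetwork, MRNA
from .errors import InvalidArgumentError, NotFoundError

__all__ = [
    "PropagationConfig",
    "NormalizedAdjacency",
    "PropagationResult",
    "PermutationResult",
    "column_normalize",
    "rwr",
    "permutation_test",
]


@dataclass
class PropagationConfig:
    """RWR parameters.

    restart_r: probability of jumping back to the seed distribution at
    each step (0.8 by default); tolerance: L1 convergence threshold;
    seeds: seed node ids (the walker's restart support).
    """

    seeds: list[str]
    restart_r: float = 0.8
    tolerance: float = 1e-6
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_r <= 1.0:
            raise InvalidArgumentError(f"restart_r must be in (0, 1], got {self.restart_r}")
        if self.tolerance <= 0:
            raise InvalidArgumentError(f"tolerance must be positive, got {self.tolerance}")
        if not self.seeds:
            raise InvalidArgumentError("seeds must be non-empty")


@dataclass
class NormalizedAdjacency:
    """Column-stochastic adjacency over an explicit node ordering."""

    nodes: list[str]
    matrix: np.ndarray
    node_class: dict[str, str] = field(default_factory=dict)

    def index_of(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise NotFoundError(f"node {node!r} not in network") from None


def column_normalize(network: CeRNANetwork) -> NormalizedAdjacency:
    """Column-wise normalized adjacency: A_ij = 1/degree(j) per edge {i,j}.

    Columns of isolated nodes (degree 0) are replaced by the uniform
    distribution so the matrix stays column-stochastic.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise InvalidArgumentError("network is empty")
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.zeros((n, n))
    for u, v in g.edges:
        mat[idx[u], idx[v]] = 1.0
        mat[idx[v], idx[u]] = 1.0
    colsums = mat.sum(axis=0)
    dangling = colsums == 0
    colsums[dangling] = 1.0
    mat /= colsums
    mat[:, dangling] = 1.0 / n
    classes = {n_: g.nodes[n_].get("node_class", "") for n_ in nodes}
    return NormalizedAdjacency(nodes=nodes, matrix=mat, node_class=classes)


@dataclass
class PropagationResult:
    """Stationary RWR probabilities plus convergence diagnostics."""

    probabilities: pd.Series
    iterations: int
    converged: bool
    mass_history: list[float] = field(default_factory=list)


def rwr(adjacency: NormalizedAdjacency, config: PropagationConfig) -> PropagationResult:
    """Iterate P_{i+1} = (1-r) M P_i + r P_0 to its stationary vector.

    P_0 puts mass 1/N on each of the N seed nodes. Stops when the L1
    difference of successive vectors falls below the tolerance; hitting
    max_iterations flags non-convergence without raising.
    """
    missing = [s for s in config.seeds if s not in adjacency.nodes]
    if missing:
        raise NotFoundError(f"seed node(s) not in network: {missing}")
    n = len(adjacency.nodes)
    p0 = np.zeros(n)
    for s in config.seeds:
        p0[adjacency.nodes.index(s)] = 1.0 / len(config.seeds)

    r = config.restart_r
    mat = adjacency.matrix
    p = p0.copy()
    mass = [float(p.sum())]
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        p_next = (1.0 - r) * (mat @ p) + r * p0
        mass.append(float(p_next.sum()))
        if np.abs(p_next - p).sum() < config.tolerance:
            p = p_next
            converged = True
            break
        p = p_next
    return PropagationResult(
        probabilities=pd.Series(p, index=adjacency.nodes, name="probability"),
        iterations=iterations,
        converged=converged,
        mass_history=mass,
    )


@dataclass
class PermutationResult:
    """Per-node permutation statistics for the RWR scores.

    theta counts permuted seed sets whose run gave the node a strictly
    higher probability than the observed run; p_g = theta / n_permutations.
    """

    theta: pd.Series
    p_g: pd.Series
    n_permutations: int
    rng_seed: int


def permutation_test(
    adjacency: NormalizedAdjacency,
    config: PropagationConfig,
    observed: PropagationResult,
    n_permutations: int = 1000,
    rng_seed: int = 0,
    candidate_pool: list[str] | None = None,
    exclude_seeds: bool = False,
) -> PermutationResult:
    """Permutation null for RWR probabilities.

    Each permutation draws ``len(seeds)`` distinct nodes uniformly from
    the candidate pool (default: all mRNA nodes, matching the type of
    typical seed genes), reruns RWR from scratch with those seeds, and
    increments theta_g for every gene g whose permuted probability
    strictly exceeds its observed one. Ties do not increment.
    """
    if n_permutations <= 0:
        raise InvalidArgumentError(f"n_permutations must be positive, got {n_permutations}")
    if candidate_pool is None:
        candidate_pool = sorted(
            n for n, c in adjacency.node_class.items() if c == MRNA
        ) or list(adjacency.nodes)
    pool = [n for n in candidate_pool if n in set(adjacency.nodes)]
    if exclude_seeds:
        pool = [n for n in pool if n not in set(config.seeds)]
    n_seeds = len(config.seeds)
    if len(pool) < n_seeds:
        raise InvalidArgumentError(
            f"candidate pool ({len(pool)}) smaller than seed count ({n_seeds})"
        )

    rng = np.random.default_rng(rng_seed)
    obs = observed.probabilities.to_numpy()
    theta = np.zeros(len(adjacency.nodes), dtype=int)
    for _ in range(n_permutations):
        drawn = list(rng.choice(pool, size=n_seeds, replace=False))
        perm_cfg = PropagationConfig(
            seeds=drawn,
            restart_r=config.restart_r,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
        )
        perm = rwr(adjacency, perm_cfg).probabilities.to_numpy()
        theta += perm > obs
    theta_s = pd.Series(theta, index=adjacency.nodes, name="theta")
    return PermutationResult(
        theta=theta_s,
        p_g=theta_s / n_permutations,
        n_permutations=n_permutations,
        rng_seed=rng_seed,
    )
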