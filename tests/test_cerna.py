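"""Hypergeometric shared-miRNA test and bipartite network assembly."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet.cerna import (
    InteractionTable,
    build_network,
    hypergeometric_tail,
    shared_mirna_stats,
)
from cernet.cerna import test_all_pairs as score_all_pairs
from cernet.errors import InvalidArgumentError, NotFoundError
from cernet.synthetic import generate_interaction_tables


def table_from_sets(sets: dict[str, set[str]], rna_class: str) -> InteractionTable:
    rows = [(rna, mir) for rna, mirs in sets.items() for mir in mirs]
    return InteractionTable(pd.DataFrame(rows, columns=["rna_id", "mirna_id"]), rna_class)


class TestHypergeometricTail:
    def test_x_zero_is_one(self):
        assert hypergeometric_tail(10, 4, 5, 0) == 1.0

    def test_small_closed_form(self):
        # T=10, M=4, k=5, x=3: complement form gives 1 - 155/210 = 11/42.
        assert hypergeometric_tail(10, 4, 5, 3) == pytest.approx(float(Fraction(11, 42)), rel=1e-12)

    def test_full_overlap_closed_form(self):
        assert hypergeometric_tail(100, 8, 8, 8) == pytest.approx(1 / math.comb(100, 8), rel=1e-9)

    def test_large_background_stability(self):
        # Tiny tails at starBase-scale backgrounds stay finite and positive.
        p = hypergeometric_tail(20000, 50, 60, 30)
        assert 0.0 < p < 1e-30

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_agrees_with_scipy_sf(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(1, 500))
        M = int(rng.integers(0, T + 1))
        k = int(rng.integers(0, T + 1))
        x = int(rng.integers(0, min(M, k) + 1))
        ours = hypergeometric_tail(T, M, k, x)
        ref = stats.hypergeom.sf(x - 1, T, k, M)
        assert ours == pytest.approx(float(ref), rel=1e-8, abs=1e-300)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_nonincreasing_in_x(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(2, 100))
        M = int(rng.integers(1, T + 1))
        k = int(rng.integers(1, T + 1))
        tails = [hypergeometric_tail(T, M, k, x) for x in range(min(M, k) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 4, 11, 0), (10, 4, 5, 5), (-1, 0, 0, 0)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(InvalidArgumentError):
            hypergeometric_tail(*args)


class TestSharedMirnaStats:
    def test_disjoint_sets_share_nothing(self):
        lnc = table_from_sets({"l1": {"a", "b", "c"}}, "lncRNA")
        mrna = table_from_sets({"m1": {"d", "e"}}, "mRNA")
        s = shared_mirna_stats(lnc, mrna, "l1", "m1")
        assert (s.M, s.k, s.x) == (3, 2, 0)
        assert s.T == 5  # union background

    def test_identical_sets_fully_overlap(self):
        mirs = {"a", "b", "c", "d", "e"}
        lnc = table_from_sets({"l1": mirs}, "lncRNA")
        mrna = table_from_sets({"m1": mirs}, "mRNA")
        s = shared_mirna_stats(lnc, mrna, "l1", "m1")
        assert s.x == s.M == s.k == 5
        assert s.shared_mirnas == frozenset(mirs)

    def test_counts_match_bruteforce_intersections(self):
        rng = np.random.default_rng(12)
        universe = [f"mir{i}" for i in range(40)]
        lnc_sets = {f"l{i}": set(rng.choice(universe, size=rng.integers(3, 12), replace=False)) for i in range(5)}
        mrna_sets = {f"m{i}": set(rng.choice(universe, size=rng.integers(3, 12), replace=False)) for i in range(8)}
        lnc = table_from_sets(lnc_sets, "lncRNA")
        mrna = table_from_sets(mrna_sets, "mRNA")
        T = len(set().union(*lnc_sets.values()) | set().union(*mrna_sets.values()))
        for l, ls in lnc_sets.items():
            for m, ms in mrna_sets.items():
                s = shared_mirna_stats(lnc, mrna, l, m)
                assert (s.T, s.M, s.k, s.x) == (T, len(ls), len(ms), len(ls & ms))

    def test_absent_rna_not_found(self):
        lnc = table_from_sets({"l1": {"a"}}, "lncRNA")
        mrna = table_from_sets({"m1": {"a"}}, "mRNA")
        with pytest.raises(NotFoundError):
            shared_mirna_stats(lnc, mrna, "l9", "m1")


@pytest.fixture(scope="module")
def planted():
    lnc, mrna, truth = generate_interaction_tables(5, 50, 100, 8, 3, 8, 11)
    return lnc, mrna, truth


@pytest.fixture(scope="module")
def stats_and_truth():
    lnc, mrna, truth = generate_interaction_tables(5, 40, 120, 8, 6, 8, 23)
    return score_all_pairs(lnc, mrna, alpha=0.001), truth


class TestTestAllPairs:
    def test_planted_pairs_exactly_recovered(self, planted):
        lnc, mrna, truth = planted
        res = score_all_pairs(lnc, mrna, alpha=0.001)
        sig = {(r.lncrna_id, r.mrna_id) for r in res[res["significant"]].itertuples()}
        assert sig == set(truth.cerna_pairs)

    def test_alpha_zero_yields_nothing(self, planted):
        lnc, mrna, _ = planted
        res = score_all_pairs(lnc, mrna, alpha=0.0)
        assert not res["significant"].any()

    def test_zero_overlap_never_significant(self, planted):
        lnc, mrna, _ = planted
        res = score_all_pairs(lnc, mrna, alpha=0.999)
        zero = res[res["x"] == 0]
        assert (zero["p_value"] == 1.0).all()
        assert not zero["significant"].any()

    def test_empty_id_list_rejected(self, planted):
        lnc, mrna, _ = planted
        with pytest.raises(InvalidArgumentError):
            score_all_pairs(lnc, mrna, [], ["mrna_0000"])


class TestBuildNetwork:
    def test_no_degs_gives_empty_network(self, stats_and_truth):
        pair_stats, _ = stats_and_truth
        net = build_network(pair_stats, set(), set(), alpha=0.001)
        assert net.n_edges == 0
        assert net.lncrna_nodes == set() and net.mrna_nodes == set()

    def test_edges_are_planted_pairs_with_deg_endpoints(self, stats_and_truth):
        pair_stats, truth = stats_and_truth
        pairs = sorted(truth.cerna_pairs)
        kept = pairs[:4]  # pretend only these endpoints are differential
        deg_lnc = {l for l, _ in kept}
        deg_mrna = {m for _, m in kept}
        net = build_network(pair_stats, deg_lnc, deg_mrna, alpha=0.001)
        expected = {
            (l, m)
            for l, m in set(
                pair_stats[pair_stats["p_value"] < 0.001][["lncrna_id", "mrna_id"]].itertuples(
                    index=False, name=None
                )
            )
            if l in deg_lnc and m in deg_mrna
        }
        assert net.edge_pairs() == expected

    def test_network_is_strictly_bipartite(self, stats_and_truth):
        pair_stats, truth = stats_and_truth
        deg_lnc = {l for l, _ in truth.cerna_pairs}
        deg_mrna = {m for _, m in truth.cerna_pairs}
        net = build_network(pair_stats, deg_lnc, deg_mrna, alpha=0.001)
        for u, v in net.graph.edges:
            assert {net.graph.nodes[u]["node_class"], net.graph.nodes[v]["node_class"]} == {
                "lncRNA",
                "mRNA",
            }
        # every node supports at least one edge
        assert all(d > 0 for _, d in net.graph.degree())

    def test_edge_count_monotone_in_alpha(self, stats_and_truth):
        pair_stats, truth = stats_and_truth
        deg_lnc = {l for l, _ in truth.cerna_pairs}
        deg_mrna = {m for _, m in truth.cerna_pairs}
        counts = [
            build_network(pair_stats, deg_lnc, deg_mrna, alpha=a).n_edges
            for a in (1e-9, 1e-6, 1e-3, 0.1, 1.0)
        ]
        assert counts == sorted(counts)

    def test_edge_count_monotone_in_deg_shrinkage(self, stats_and_truth):
        pair_stats, truth = stats_and_truth
        deg_lnc = {l for l, _ in truth.cerna_pairs}
        deg_mrna = {m for _, m in truth.cerna_pairs}
        full = build_network(pair_stats, deg_lnc, deg_mrna, alpha=0.001).n_edges
        smaller = build_network(
            pair_stats, set(sorted(deg_lnc)[:2]), deg_mrna, alpha=0.001
        ).n_edges
        assert smaller <= full
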