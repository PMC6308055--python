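"""Probe filtering, aggregation and the paired differential screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cernet.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidArgumentError,
    NotFoundError,
)
from cernet.expression import (
    ExpressionMatrix,
    aggregate_probes,
    filter_probe_hits,
    paired_t_test,
    screen_degs,
    validate_candidate,
)
from cernet.synthetic import generate_paired_expression


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "transcript_id", "mismatches"])


class TestFilterProbeHits:
    def test_four_clean_unique_probes_accepted(self):
        hits = hits_frame([(f"p{i}", "tx1", 0) for i in range(4)])
        assert filter_probe_hits(hits) == {"tx1"}

    def test_mismatched_probe_dropped_then_rejected(self):
        hits = hits_frame([("p1", "tx1", 0), ("p2", "tx1", 0), ("p3", "tx1", 0), ("p4", "tx1", 1)])
        assert filter_probe_hits(hits) == set()

    def test_multimapping_probe_counts_for_neither(self):
        # pX hits both transcripts, so each keeps only 3 informative probes.
        rows = [(f"a{i}", "txA", 0) for i in range(3)] + [(f"b{i}", "txB", 0) for i in range(3)]
        rows += [("pX", "txA", 0), ("pX", "txB", 0)]
        assert filter_probe_hits(hits_frame(rows)) == set()

    def test_threshold_is_configurable(self):
        hits = hits_frame([(f"p{i}", "tx1", 0) for i in range(3)])
        assert filter_probe_hits(hits, min_probes=3) == {"tx1"}
        assert filter_probe_hits(hits, min_probes=4) == set()

    def test_empty_table_gives_empty_set(self):
        assert filter_probe_hits(hits_frame([])) == set()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidArgumentError):
            filter_probe_hits(hits_frame([("p", "t", 0)]), min_probes=0)


class TestAggregateProbes:
    def test_single_probe_row_copied(self):
        pm = pd.DataFrame([[1.0, 2.0]], index=["p1"], columns=["s1", "s2"])
        out = aggregate_probes(pm, {"p1": "g1"})
        assert list(out.values.loc["g1"]) == [1.0, 2.0]

    def test_two_probe_mean(self):
        pm = pd.DataFrame([[2.0, 4.0], [4.0, 8.0]], index=["p1", "p2"], columns=["s1", "s2"])
        out = aggregate_probes(pm, {"p1": "g1", "p2": "g1"})
        assert list(out.values.loc["g1"]) == [3.0, 6.0]

    def test_matches_bruteforce_groupwise_mean(self):
        rng = np.random.default_rng(4)
        pm = pd.DataFrame(
            rng.normal(size=(20, 6)),
            index=[f"p{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        mapping = {f"p{i}": f"g{i % 5}" for i in range(20)}
        out = aggregate_probes(pm, mapping)
        for g in {f"g{i}" for i in range(5)}:
            probes = [p for p, gg in mapping.items() if gg == g]
            for s in pm.columns:
                expected = sum(pm.loc[p, s] for p in probes) / len(probes)
                assert out.values.loc[g, s] == pytest.approx(expected)

    def test_commutes_with_column_permutation(self):
        rng = np.random.default_rng(5)
        pm = pd.DataFrame(
            rng.normal(size=(8, 4)),
            index=[f"p{i}" for i in range(8)],
            columns=list("abcd"),
        )
        mapping = {f"p{i}": f"g{i % 3}" for i in range(8)}
        direct = aggregate_probes(pm, mapping).values
        permuted = aggregate_probes(pm[["d", "b", "a", "c"]], mapping).values
        pd.testing.assert_frame_equal(direct, permuted[direct.columns])

    def test_gene_without_probes_excluded_with_warning(self, caplog):
        pm = pd.DataFrame([[1.0]], index=["p1"], columns=["s1"])
        with caplog.at_level("WARNING"):
            out = aggregate_probes(pm, {"p1": "g1", "p_missing": "g2"})
        assert "g2" not in out.values.index
        assert any("g2" in r.message for r in caplog.records)


class TestPairedTTest:
    def test_symmetric_differences_give_t_zero(self):
        t, p = paired_t_test(np.array([0.0, 0.5, -0.5, 0.0]), np.zeros(4))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        # d = (1,2,3,4): t = 2.5 / (sqrt(5/3)/2) = 3.8730, p = 0.030466
        t, p = paired_t_test(np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4))
        assert t == pytest.approx(2.5 / (np.sqrt(5 / 3) / 2), rel=1e-12)
        assert t == pytest.approx(3.8730, abs=1e-4)
        assert p == pytest.approx(0.030466, abs=1e-5)

    def test_constant_differences_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test(np.array([2.0, 2.0, 2.0]), np.zeros(3))

    def test_single_pair_insufficient(self):
        with pytest.raises(InsufficientDataError):
            paired_t_test(np.array([1.0]), np.array([0.0]))

    @given(st.integers(0, 2**32 - 1), st.integers(3, 30))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_and_scipy_agreement(self, seed, n):
        rng = np.random.default_rng(seed)
        tumor = rng.normal(size=n)
        normal = rng.normal(size=n)
        if np.std(tumor - normal, ddof=1) == 0:
            return
        t, p = paired_t_test(tumor, normal)
        t_rev, p_rev = paired_t_test(normal, tumor)
        assert t_rev == pytest.approx(-t)
        assert p_rev == pytest.approx(p)
        ref = stats.ttest_rel(tumor, normal)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestScreenDegs:
    def test_matches_per_gene_paired_t(self):
        m, _ = generate_paired_expression(25, 6, 0.2, 1.5, 0.5, 3)
        table = screen_degs(m, alpha=0.01)
        tumor_cols = [t for t, _ in m.pairing]
        normal_cols = [n for _, n in m.pairing]
        for g in m.values.index:
            t, p = paired_t_test(
                m.values.loc[g, tumor_cols].to_numpy(), m.values.loc[g, normal_cols].to_numpy()
            )
            assert table.loc[g, "t"] == pytest.approx(t)
            assert table.loc[g, "p"] == pytest.approx(p)
            assert table.loc[g, "significant"] == (p < 0.01)

    def test_alpha_one_marks_all_nondegenerate(self):
        m, _ = generate_paired_expression(20, 5, 0.1, 1.0, 0.5, 8)
        table = screen_degs(m, alpha=1.0)
        assert table["significant"].all()

    def test_degenerate_gene_flagged_not_significant(self):
        values = pd.DataFrame(
            {"T0": [1.0, 2.0], "T1": [2.0, 3.0], "N0": [0.0, 1.0], "N1": [1.0, 1.5]},
            index=["flat", "ok"],
        )
        matrix = ExpressionMatrix(values, [("T0", "N0"), ("T1", "N1")])
        table = screen_degs(matrix, alpha=0.5)
        assert bool(table.loc["flat", "degenerate"])
        assert not bool(table.loc["flat", "significant"])
        assert not bool(table.loc["ok", "degenerate"])

    def test_power_example_recall_and_fpr(self):
        # Planted effect 2.0, noise 0.5, 44 pairs: the screen at 0.001
        # recovers >= 90% of planted genes with few false positives.
        m, truth = generate_paired_expression(200, 44, 0.1, 2.0, 0.5, 1)
        table = screen_degs(m, alpha=0.001)
        sig = set(table.index[table["significant"]])
        recall = len(sig & truth.de_genes) / len(truth.de_genes)
        fpr = len(sig - truth.de_genes) / (200 - len(truth.de_genes))
        assert recall >= 0.9
        assert fpr <= 0.01


class TestValidateCandidate:
    def test_planted_up_gene_detected(self):
        m, truth = generate_paired_expression(50, 34, 0.2, 2.0, 0.5, 6)
        g = sorted(truth.up_genes)[0]
        direction, p = validate_candidate(m, g)
        assert direction == 1
        assert p < 0.05

    def test_planted_down_gene_detected(self):
        m, truth = generate_paired_expression(50, 34, 0.2, 2.0, 0.5, 6)
        g = sorted(truth.down_genes)[0]
        direction, p = validate_candidate(m, g)
        assert direction == -1
        assert p < 0.05

    def test_unknown_gene_not_found(self):
        m, _ = generate_paired_expression(10, 4, 0.0, 1.0, 0.5, 1)
        with pytest.raises(NotFoundError):
            validate_candidate(m, "nope")

    def test_null_p_values_are_uniform(self):
        # Under the null, p-values across 50 independent simulations
        # should be U(0,1) (Kolmogorov-Smirnov).
        ps = []
        for seed in range(50):
            m, _ = generate_paired_expression(5, 20, 0.0, 1.0, 0.5, seed)
            ps.append(validate_candidate(m, m.values.index[0])[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01
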