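import math

import numpy as np
import pytest
from scipy import stats

from kfnet.abundance import normalize_counts
from kfnet.io_model import (AbundanceMatrix, CollapseMap, Edge, HostMicrobialNetwork,
                            ExpressionMatrix, NodeAnnotation)
from kfnet.network import (CorrelationRecord, add_false_negatives,
                           build_network, correlate_all,
                           remove_false_positives, spearman)
from kfnet.synthetic import make_fp_fixture

from conftest import spearman_oracle


GENE_ANNS = [
    NodeAnnotation("G1", "gene", "up", "cell_cycle"),
    NodeAnnotation("G2", "gene", "down", "other"),
]
MICROBE_ANNS = [
    NodeAnnotation("M1", "microbe", "none", "microbe"),
    NodeAnnotation("M2", "microbe", "none", "microbe"),
]


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4])[0] == 1.0
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_worked_example_exact(self):
        # closed form 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=4, n=5
        rho, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == 0.8

    def test_matches_rank_then_pearson_oracle_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman(x, y)
            assert abs(rho - spearman_oracle(x, y)) < 1e-12

    def test_p_value_matches_scipy_t_approximation(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=(2, n))
            rho, p = spearman(x, y)
            ref_rho, ref_p = stats.spearmanr(x, y)
            assert abs(rho - ref_rho) < 1e-12
            assert abs(p - ref_p) < 1e-9

    def test_constant_vector_yields_sentinel(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman([1, 2], [3, 4])

    def test_exact_permutation_p_closed_form(self):
        # n=3, perfect concordance: of the 3! permutations only the
        # identity and the reversal reach |rho| = 1, so p = 2/6
        rho, p = spearman([1, 2, 3], [1, 2, 3], p_method="permutation")
        assert rho == 1.0
        assert p == pytest.approx(1 / 3, abs=1e-15)

    def test_permutation_limited_to_small_n(self):
        x = list(range(12))
        with pytest.raises(ValueError, match="n < 10"):
            spearman(x, x, p_method="permutation")


def _matrices(rng, n_m=2, n_g=2, n_s=12):
    a = AbundanceMatrix([f"M{i+1}" for i in range(n_m)],
                        [f"S{j+1}" for j in range(n_s)],
                        rng.random((n_m, n_s)))
    e = ExpressionMatrix([f"G{i+1}" for i in range(n_g)],
                         [f"S{j+1}" for j in range(n_s)],
                         rng.normal(size=(n_g, n_s)))
    return a, e


class TestCorrelateAll:
    def test_all_unordered_pairs_present(self, rng):
        records = correlate_all(*_matrices(rng))
        assert len(records) == 6  # C(4,2)
        keys = {r.key() for r in records}
        assert ("G1", "M1") in keys and ("G1", "G2") in keys

    def test_records_match_pairwise_spearman(self, rng):
        a, e = _matrices(rng, 3, 3, 15)
        profiles = {**{m: a.values[i] for i, m in enumerate(a.otu_ids)},
                    **{g: e.values[i] for i, g in enumerate(e.gene_ids)}}
        for rec in correlate_all(a, e):
            rho, p = spearman(profiles[rec.u], profiles[rec.v])
            assert abs(rec.rho - rho) < 1e-12
            assert abs(rec.p_value - p) < 1e-12

    def test_column_order_alignment(self, rng):
        a, e = _matrices(rng, 2, 2, 10)
        shuffled = e.reorder_samples(list(reversed(e.sample_ids)))
        r1 = {r.key(): r.rho for r in correlate_all(a, e)}
        r2 = {r.key(): r.rho for r in correlate_all(a, shuffled)}
        assert r1 == r2

    def test_sample_mismatch_lists_symmetric_difference(self, rng):
        a, e = _matrices(rng, 2, 2, 5)
        bad = ExpressionMatrix(e.gene_ids, ["S1", "S2", "S3", "S4", "SX"],
                               e.values)
        with pytest.raises(ValueError, match="S5.*SX|SX.*S5"):
            correlate_all(a, bad)

    def test_constant_profile_yields_sentinel_records(self, rng):
        a, e = _matrices(rng, 2, 2, 8)
        a.values[0] = 3.0
        recs = {r.key(): r for r in correlate_all(a, e)}
        assert not recs[("G1", "M1")].defined
        assert recs[("G1", "G2")].defined


class TestBuildNetwork:
    def _records(self):
        return [CorrelationRecord("G1", "G2", 0.5, 0.01),
                CorrelationRecord("G1", "M1", 0.40, 0.001),   # rho at boundary
                CorrelationRecord("G2", "M1", -0.7, 0.2),     # p too large
                CorrelationRecord("M1", "M2", -0.45, 0.05)]   # p at boundary

    def test_strict_thresholds_and_signs(self):
        net = build_network(self._records(), GENE_ANNS + MICROBE_ANNS)
        edges = {e.sorted_endpoints(): e for e in net.edges()}
        assert set(edges) == {("G1", "G2")}
        assert edges[("G1", "G2")].sign == "positive"
        assert edges[("G1", "G2")].origin == "measured"

    def test_isolated_nodes_retained(self):
        net = build_network(self._records(), GENE_ANNS + MICROBE_ANNS)
        assert set(net.node_ids) == {"G1", "G2", "M1", "M2"}

    def test_sentinel_record_never_forms_edge(self):
        recs = [CorrelationRecord("G1", "M1", float("nan"), float("nan"))]
        net = build_network(recs, GENE_ANNS + MICROBE_ANNS)
        assert net.n_edges == 0

    def test_unannotated_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            build_network([CorrelationRecord("G1", "GX", 0.9, 0.001)], GENE_ANNS)

    def test_sign_bookkeeping(self, rng):
        recs = [CorrelationRecord(f"M{i+1}", f"G{j+1}", rho, 0.001)
                for i in range(2) for j, rho in enumerate([0.6, -0.6])]
        anns = GENE_ANNS + MICROBE_ANNS
        net = build_network(recs, anns)
        pos = sum(e.sign == "positive" for e in net.edges())
        neg = sum(e.sign == "negative" for e in net.edges())
        assert pos + neg == net.n_edges == 4


class TestRemoveFalsePositives:
    def test_fixture_loses_exactly_the_four_scenes(self):
        raw, expected = make_fp_fixture()
        corrected, log = remove_false_positives(raw)
        assert corrected == expected
        assert len(log) == 4
        assert sorted(e.rule for e in log) == [
            "incoherent_negative", "incoherent_positive", "parallel",
            "self_loop"]
        assert raw.n_edges - corrected.n_edges == 4

    def test_idempotent(self):
        raw, _ = make_fp_fixture()
        once, _ = remove_false_positives(raw)
        twice, log2 = remove_false_positives(once)
        assert twice == once and log2 == []

    def test_coherent_negative_up_down_edge_kept(self):
        raw, _ = make_fp_fixture()
        corrected, _ = remove_false_positives(raw)
        assert corrected.has_edge("GB", "GC")  # up vs down, negative

    def test_microbe_edges_exempt_from_coherence_rules(self):
        net = make_fp_fixture()[0]
        corrected, _ = remove_false_positives(net)
        assert corrected.has_edge("M1", "GC")

    def test_parallel_resolution_keeps_largest_abs_rho(self):
        raw, _ = make_fp_fixture()
        corrected, _ = remove_false_positives(raw)
        kept = [e for e in corrected.edges()
                if e.sorted_endpoints() == ("GA", "M1")]
        assert len(kept) == 1 and kept[0].rho == 0.60


class TestAddFalseNegatives:
    def _setup(self):
        net = HostMicrobialNetwork()
        net.add_node(NodeAnnotation("collapsed:r", "microbe", "none", "microbe"))
        for a in GENE_ANNS:
            net.add_node(a)
        cmap = CollapseMap({"o1": "collapsed:r", "o2": "collapsed:r"})
        return net, cmap

    def _raw(self, rhos, p=0.01, gene="G1"):
        return [CorrelationRecord(o, gene, r, p)
                for o, r in zip(["o1", "o2"], rhos)]

    def test_all_subnodes_passing_adds_mean_rho_max_p_edge(self):
        net, cmap = self._setup()
        raw = [CorrelationRecord("o1", "G1", 0.6, 0.01),
               CorrelationRecord("o2", "G1", 0.7, 0.02)]
        out = add_false_negatives(net, cmap, raw)
        edges = list(out.edges())
        assert len(edges) == 1
        e = edges[0]
        assert e.sorted_endpoints() == ("G1", "collapsed:r")
        assert e.rho == pytest.approx(0.65, abs=1e-15)
        assert e.p_value == 0.02
        assert e.origin == "inferred" and e.sign == "positive"

    def test_one_weak_subnode_blocks_the_edge(self):
        net, cmap = self._setup()
        assert add_false_negatives(net, cmap, self._raw([0.6, 0.2])).n_edges == 0

    def test_conflicting_signs_block_the_edge(self):
        net, cmap = self._setup()
        assert add_false_negatives(net, cmap, self._raw([0.6, -0.6])).n_edges == 0

    def test_existing_edge_not_duplicated_and_idempotent(self):
        net, cmap = self._setup()
        raw = self._raw([0.6, 0.7])
        once = add_false_negatives(net, cmap, raw)
        twice = add_false_negatives(once, cmap, raw)
        assert twice == once

    def test_singleton_collapse_groups_ignored(self):
        net = HostMicrobialNetwork()
        net.add_node(NodeAnnotation("solo", "microbe", "none", "microbe"))
        for a in GENE_ANNS:
            net.add_node(a)
        cmap = CollapseMap({"solo": "solo"})
        out = add_false_negatives(net, cmap,
                                  [CorrelationRecord("solo", "G1", 0.9, 0.001)])
        assert out.n_edges == 0

    def test_member_absent_from_raw_records_is_an_error(self):
        net, cmap = self._setup()
        with pytest.raises(ValueError, match="absent from raw"):
            add_false_negatives(net, cmap,
                                [CorrelationRecord("o1", "G1", 0.6, 0.01)])
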