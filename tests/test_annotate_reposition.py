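import itertools
from math import comb

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from idsn.annotate_reposition import (
    CATEGORIES,
    _rank_transform,
    benjamini_hochberg,
    cluster_consistency_pvalue,
    cluster_contribution_report,
    edge_source_attribution,
    hypergeometric_enrichment,
    pathway_consistency,
    repositioning_candidates,
    top_similar_pairs,
)
from idsn.core_io import AnnotationTable, CohortError, SimilarityNetwork
from idsn.synthetic_data import make_planted_network


def _net(M, source="fused"):
    ids = [f"d{i}" for i in range(M.shape[0])]
    return SimilarityNetwork(ids=ids, matrix=np.asarray(M, float), source=source)


def _sym(values, n):
    """Build a symmetric matrix with unit diagonal from upper-tri values."""
    M = np.eye(n)
    iu = np.triu_indices(n, k=1)
    M[iu] = values
    return M + M.T - np.diag(np.diag(M))


def hypergeom_enumeration_oracle(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all n-subsets."""
    universe = list(range(N))
    inset = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(inset & set(draw)) >= k:
            hits += 1
    return hits / total


class TestRankTransform:
    def test_spans_unit_interval(self, rng):
        M = _sym(rng.random(10), 5)
        R = _rank_transform(M)
        iu = np.triu_indices(5, k=1)
        assert R[iu].min() == 0.0 and R[iu].max() == 1.0
        assert np.allclose(R, R.T) and np.all(np.diag(R) == 0)

    def test_monotone_in_values(self):
        M = _sym([0.1, 0.5, 0.9], 3)
        R = _rank_transform(M)
        assert R[0, 1] < R[0, 2] < R[1, 2]


class TestEdgeAttribution:
    def _three_nets(self, chem_vals, pharm_vals, fused_vals, n):
        return (
            _net(_sym(fused_vals, n), "fused"),
            _net(_sym(chem_vals, n), "chem"),
            _net(_sym(pharm_vals, n), "pharm"),
        )

    def test_rule_application(self):
        # 5 drugs, one cluster; 10 pairs with controlled rank patterns
        n = 5
        rng = np.random.default_rng(0)
        chem = rng.permutation(np.linspace(0.1, 0.9, 10))
        pharm = rng.permutation(np.linspace(0.1, 0.9, 10))
        fused = rng.permutation(np.linspace(0.1, 0.9, 10))
        f, c, p = self._three_nets(chem, pharm, fused, n)
        labels = {d: 0 for d in f.ids}
        att = edge_source_attribution(f, c, p, labels, margin=0.05)
        rc, rp, rf = (_rank_transform(x) for x in (c.matrix, p.matrix,
                                                   f.matrix))
        pos = f.index_of()
        for (a, b), cat in att.categories.items():
            i, j = pos[a], pos[b]
            if rf[i, j] > max(rc[i, j], rp[i, j]) + 0.05:
                expect = "fusion_value"
            elif rc[i, j] > rp[i, j]:
                expect = "chemical_structure"
            elif rp[i, j] > rc[i, j]:
                expect = "drug_targets"
            else:
                expect = "fusion_value"
            assert cat == expect

    def test_chem_wins_when_fused_within_margin(self):
        # pair (0,1): chem rank high, pharm low, fused below chem+margin
        f, c, p = self._three_nets(
            chem_vals=[0.9, 0.5, 0.1], pharm_vals=[0.1, 0.5, 0.9],
            fused_vals=[0.85, 0.5, 0.2], n=3,
        )
        labels = {d: 0 for d in f.ids}
        att = edge_source_attribution(f, c, p, labels, margin=0.05)
        assert att.categories[("d0", "d1")] == "chemical_structure"
        assert att.categories[("d1", "d2")] == "drug_targets"

    def test_fused_exceeding_both_wins(self):
        f, c, p = self._three_nets(
            chem_vals=[0.5, 0.9, 0.1], pharm_vals=[0.5, 0.9, 0.1],
            fused_vals=[0.95, 0.5, 0.1], n=3,
        )
        labels = {d: 0 for d in f.ids}
        att = edge_source_attribution(f, c, p, labels, margin=0.05)
        # pair (0,1): equal chem/pharm ranks, fused rank above both by >margin
        assert att.categories[("d0", "d1")] == "fusion_value"

    def test_tie_goes_to_fusion(self):
        f, c, p = self._three_nets(
            chem_vals=[0.5, 0.9, 0.1], pharm_vals=[0.5, 0.9, 0.1],
            fused_vals=[0.5, 0.9, 0.1], n=3,
        )
        labels = {d: 0 for d in f.ids}
        att = edge_source_attribution(f, c, p, labels, margin=0.05)
        assert all(v == "fusion_value" for v in att.categories.values())

    def test_between_cluster_pairs_ignored(self):
        f, c, p = self._three_nets([0.5] * 3, [0.4] * 3, [0.6] * 3, 3)
        labels = {"d0": 0, "d1": 0, "d2": 1}
        att = edge_source_attribution(f, c, p, labels)
        assert set(att.categories) == {("d0", "d1")}

    def test_id_mismatch_errors(self):
        f, c, p = self._three_nets([0.5], [0.4], [0.6], 2)
        c.ids = ["x0", "x1"]
        with pytest.raises(CohortError):
            edge_source_attribution(f, c, p, {"d0": 0, "d1": 0})


class TestContributionReport:
    def _attribution(self, cats):
        from idsn.annotate_reposition import EdgeAttribution
        return EdgeAttribution(
            categories=cats,
            supports={k: (0, 0, 0) for k in cats},
            margin=0.05,
        )

    def test_all_pharm_entirely_determined(self):
        cats = {("d0", "d1"): "drug_targets", ("d0", "d2"): "drug_targets",
                ("d1", "d2"): "drug_targets"}
        labels = {"d0": 0, "d1": 0, "d2": 0}
        report = cluster_contribution_report(self._attribution(cats), labels)
        assert report.per_cluster[0]["drug_targets"] == 100.0
        assert report.entirely_determined[0] == "drug_targets"
        assert report.dominated[0] == "drug_targets"

    def test_counted_percentages(self):
        cats = {("d0", "d1"): "chemical_structure",
                ("d0", "d2"): "chemical_structure",
                ("d1", "d2"): "chemical_structure",
                ("d2", "d3"): "drug_targets"}
        labels = {f"d{i}": 0 for i in range(4)}
        report = cluster_contribution_report(self._attribution(cats), labels)
        pc = report.per_cluster[0]
        assert pc["chemical_structure"] == 75.0
        assert pc["drug_targets"] == 25.0
        assert pc["fusion_value"] == 0.0

    def test_percentages_sum_to_100(self, rng):
        pairs = list(itertools.combinations([f"d{i}" for i in range(8)], 2))
        cats = {p: CATEGORIES[rng.integers(3)] for p in pairs}
        labels = {f"d{i}": i % 2 for i in range(8)}
        cats = {p: c for p, c in cats.items()
                if labels[p[0]] == labels[p[1]]}
        report = cluster_contribution_report(self._attribution(cats), labels)
        for pc in report.per_cluster.values():
            assert sum(pc.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(report.global_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_singleton_cluster_reported_without_edges(self):
        labels = {"d0": 0, "d1": 0, "d2": 1}
        cats = {("d0", "d1"): "drug_targets"}
        report = cluster_contribution_report(self._attribution(cats), labels)
        assert report.singletons == [1]
        assert 1 not in report.per_cluster


class TestTopSimilarPairs:
    def test_single_max_pair(self):
        net = _net(_sym([0.2, 0.9, 0.5], 3))
        report = top_similar_pairs(net, 1)
        assert (report.rows[0].drug_i, report.rows[0].drug_j) == ("d0", "d2")

    def test_full_sorted_list(self):
        net = _net(_sym([0.2, 0.9, 0.5], 3))
        sims = [r.similarity for r in top_similar_pairs(net, 3).rows]
        assert sims == sorted(sims, reverse=True)

    def test_ties_broken_lexicographically_and_stable(self):
        net = _net(_sym([0.5, 0.5, 0.5, 0.9, 0.1, 0.5], 4))
        r1 = top_similar_pairs(net, 3)
        r2 = top_similar_pairs(net, 3)
        pairs1 = [(r.drug_i, r.drug_j) for r in r1.rows]
        pairs2 = [(r.drug_i, r.drug_j) for r in r2.rows]
        assert pairs1 == pairs2
        assert pairs1[0] == ("d1", "d2")  # 0.9 first
        assert pairs1[1] == ("d0", "d1")  # lexicographically first 0.5 tie

    def test_too_many_requested_errors(self):
        net = _net(_sym([0.5], 2))
        with pytest.raises(CohortError):
            top_similar_pairs(net, 2)


class TestPathwayConsistency:
    def test_all_consistent(self):
        net = _net(_sym([0.9, 0.8, 0.7], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "A", "d2": "A"})
        fraction, _ = pathway_consistency(top_similar_pairs(net, 3), annot)
        assert fraction == 1.0

    def test_three_of_four(self):
        net = _net(_sym(np.linspace(0.9, 0.3, 6), 4))
        annot = AnnotationTable("p", {"d0": "A", "d1": "A", "d2": "A", "d3": "B"})
        fraction, report = pathway_consistency(top_similar_pairs(net, 4), annot)
        consistent = sum(r.consistent for r in report.rows)
        assert fraction == pytest.approx(consistent / 4)

    def test_unannotated_pairs_dropped_and_counted(self):
        net = _net(_sym([0.9, 0.8, 0.7], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "A"})
        fraction, report = pathway_consistency(top_similar_pairs(net, 3), annot)
        assert report.dropped_unannotated == 2
        assert fraction == 1.0

    def test_order_invariance(self):
        net = _net(_sym([0.9, 0.8, 0.7], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "B", "d2": "A"})
        f1, _ = pathway_consistency(top_similar_pairs(net, 3), annot)
        sub = net.subset(["d2", "d0", "d1"])
        f2, _ = pathway_consistency(top_similar_pairs(sub, 3), annot)
        assert f1 == f2

    def test_zero_annotated_errors(self):
        net = _net(_sym([0.9], 2))
        annot = AnnotationTable("p", {})
        with pytest.raises(CohortError):
            pathway_consistency(top_similar_pairs(net, 1), annot)


class TestClusterConsistencyPvalue:
    def test_reproducible_and_bounded(self):
        net, truth = make_planted_network(3, 8, seed=3)
        annot = AnnotationTable("p", truth.label_of)
        a = cluster_consistency_pvalue(truth.cluster_of, net, annot,
                                       top_n=40, n_perm=199, seed=5)
        b = cluster_consistency_pvalue(truth.cluster_of, net, annot,
                                       top_n=40, n_perm=199, seed=5)
        assert a == b
        for row in a.values():
            if not np.isnan(row["p"]):
                assert 1 / 200 <= row["p"] <= 1.0

    def test_perfectly_consistent_cluster_small_p(self):
        net, truth = make_planted_network(4, 8, seed=1)
        annot = AnnotationTable("p", truth.label_of)
        result = cluster_consistency_pvalue(truth.cluster_of, net, annot,
                                            top_n=60, n_perm=999, seed=0)
        ps = [r["p"] for r in result.values() if r["n_pairs"] >= 10]
        assert ps and all(p <= 0.05 for p in ps)
        assert all(p >= 1 / 1000 for p in ps)

    def test_cluster_without_top_pairs_is_na(self):
        net, truth = make_planted_network(2, 5, seed=2)
        labels = dict(truth.cluster_of)
        labels[net.ids[0]] = 99  # singleton cluster: no within pairs
        annot = AnnotationTable("p", truth.label_of)
        result = cluster_consistency_pvalue(labels, net, annot,
                                            top_n=10, n_perm=199, seed=0)
        assert np.isnan(result[99]["p"])

    def test_min_permutations_enforced(self):
        net, truth = make_planted_network(2, 5, seed=2)
        annot = AnnotationTable("p", truth.label_of)
        with pytest.raises(CohortError):
            cluster_consistency_pvalue(truth.cluster_of, net, annot,
                                       top_n=10, n_perm=50, seed=0)


class TestRepositioningCandidates:
    def test_all_consistent_empty(self):
        net = _net(_sym([0.9, 0.8, 0.95], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "A", "d2": "A"})
        assert repositioning_candidates(net, annot, 0.7).rows == []

    def test_single_candidate(self):
        net = _net(_sym([0.8, 0.2, 0.1], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "B", "d2": "A"})
        rows = repositioning_candidates(net, annot, 0.7).rows
        assert len(rows) == 1
        assert (rows[0].drug_i, rows[0].drug_j) == ("d0", "d1")
        assert (rows[0].pathway_i, rows[0].pathway_j) == ("A", "B")

    def test_strict_threshold(self):
        net = _net(_sym([0.7, 0.69, 0.1], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "B", "d2": "C"})
        assert repositioning_candidates(net, annot, 0.7).rows == []

    def test_sorted_descending(self):
        net = _net(_sym([0.8, 0.9, 0.75], 3))
        annot = AnnotationTable("p", {"d0": "A", "d1": "B", "d2": "C"})
        sims = [r.similarity for r in repositioning_candidates(net, annot, 0.7).rows]
        assert sims == sorted(sims, reverse=True)

    def test_bad_threshold_errors(self):
        net = _net(_sym([0.8], 2))
        annot = AnnotationTable("p", {"d0": "A", "d1": "B"})
        with pytest.raises(CohortError):
            repositioning_candidates(net, annot, 1.2)


class TestHypergeometricEnrichment:
    def test_closed_form_value(self):
        rows = hypergeometric_enrichment(
            cluster_targets={0: {f"g{i}" for i in range(4)}},
            gene_sets={"S": {f"g{i}" for i in range(5)}},
            universe={f"g{i}" for i in range(10)},
        )
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        expect = comb(5, 4) * comb(5, 0) / comb(10, 4)
        assert rows[0].p_value == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(5 / 210)

    def test_zero_overlap_p_is_one(self):
        rows = hypergeometric_enrichment(
            cluster_targets={0: {"g8", "g9"}},
            gene_sets={"S": {"g0"}},
            universe={f"g{i}" for i in range(10)},
        )
        assert rows[0].p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            N = int(rng.integers(6, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, min(N, 7)))
            universe = {f"g{i}" for i in range(N)}
            gset = {f"g{i}" for i in range(K)}
            draw = set(rng.choice(sorted(universe), size=n, replace=False))
            rows = hypergeometric_enrichment({0: draw}, {"S": gset}, universe)
            k = len(draw & gset)
            assert rows[0].p_value == pytest.approx(
                hypergeom_enumeration_oracle(N, K, n, k), abs=1e-12
            )

    def test_empty_universe_errors(self):
        with pytest.raises(CohortError):
            hypergeometric_enrichment({0: set()}, {"S": {"g"}}, set())

    def test_targets_outside_universe_error(self):
        with pytest.raises(CohortError):
            hypergeometric_enrichment({0: {"gX"}}, {"S": {"g0"}}, {"g0"})


class TestBenjaminiHochberg:
    def test_monotone_after_step_up(self, rng):
        p = rng.random(20)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.random(25)
        q = benjamini_hochberg(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
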