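"""Simpson-distance clustering, membership matrix, enrichment suites."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenorules import CallMatrix
from phenorules.community import (
    MEMBER,
    NEVER_CO_TESTED,
    bootstrap_expected_system_pairs,
    build_membership_matrix,
    cluster_ppaps,
    cluster_systems,
    fisher_enrichment,
    measure_correlations,
    measure_extreme_enrichment,
    simpson_distance,
    stage_type_rule_enrichment,
    system_pair_enrichment,
)
from phenorules.ppap import PPAP, all_ppaps
from phenorules.selection import SignificantRuleSet

from conftest import exact_fisher_two_tailed


def make_ppap(query, nodes, edges=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return PPAP(query=query, graph=g)


def atlas_from_rows(rows):
    return SignificantRuleSet(rules=pd.DataFrame(rows))


def rule_row(lhs, rhs, **kw):
    base = {"lhs": lhs, "rhs": rhs, "n11": 3, "n10": 2, "n01": 4, "n00": 60, "N": 69,
            "support": 0.04, "confidence_fwd": 0.6, "confidence_rev": 0.43,
            "lift": 4.0, "polarity": 0.4, "significance_p": 1e-3, "q": 0.01}
    base.update(kw)
    return base


class TestSimpsonDistance:
    def test_worked_example(self):
        assert simpson_distance({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(1 / 3)

    def test_containment_gives_zero(self):
        assert simpson_distance({"a", "b"}, {"a", "b", "c"}) == 0.0
        assert simpson_distance({"a"}, {"a"}) == 0.0

    def test_disjoint_gives_one(self):
        assert simpson_distance({"a"}, {"b", "c"}) == 1.0

    def test_empty_undefined(self):
        assert np.isnan(simpson_distance(set(), {"a"}))

    def test_bounded(self):
        rng = np.random.default_rng(0)
        universe = list(range(30))
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(1, 20), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 20), replace=False))
            assert 0.0 <= simpson_distance(a, b) <= 1.0


class TestClusterPPAPs:
    def test_identical_ppaps_cluster_together(self):
        ppaps = [
            make_ppap("a", {"a", "x", "y"}),
            make_ppap("b", {"b", "x", "y"}),
            make_ppap("c", {"c", "z", "w", "v"}),
        ]
        # a and b overlap heavily, c is distinct
        res = cluster_ppaps(ppaps, k=2)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        ppaps, truth = [], []
        for block in range(3):
            members = [f"b{block}_p{i}" for i in range(12)]
            for q in members:
                others = [m for m in members if m != q]
                size = int(rng.integers(5, 10))
                nodes = {q} | set(rng.choice(others, size, replace=False))
                ppaps.append(make_ppap(q, nodes))
                truth.append(block)
        res = cluster_ppaps(ppaps, k=3)
        labels = [res.labels[p.query] for p in sorted(ppaps, key=lambda p: p.query)]
        truth_sorted = [t for _, t in sorted(zip(ppaps, truth), key=lambda z: z[0].query)]
        assert adjusted_rand_score(truth_sorted, labels) >= 0.8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ppaps = [
            make_ppap(f"q{i}", {f"q{i}"} | set(rng.choice(20, 6, replace=False).astype(str)))
            for i in range(10)
        ]
        res1 = cluster_ppaps(ppaps, k=3)
        res2 = cluster_ppaps(list(reversed(ppaps)), k=3)
        part1 = {}
        for item, lab in res1.labels.items():
            part1.setdefault(lab, set()).add(item)
        part2 = {}
        for item, lab in res2.labels.items():
            part2.setdefault(lab, set()).add(item)
        assert set(map(frozenset, part1.values())) == set(map(frozenset, part2.values()))

    def test_k_exceeding_items_rejected(self):
        with pytest.raises(ValueError):
            cluster_ppaps([make_ppap("a", {"a"}), make_ppap("b", {"b"})], k=5)

    def test_system_level_clustering(self):
        systems_of = {"p0": ("s0",), "p1": ("s0",), "p2": ("s1",), "p3": ("s1",)}
        ppaps = [
            make_ppap("p0", {"p0", "p1"}),
            make_ppap("p1", {"p1", "p0"}),
            make_ppap("p2", {"p2", "p3"}),
            make_ppap("p3", {"p3", "p2"}),
        ]
        res = cluster_systems(ppaps, systems_of, k=2)
        assert res.labels["s0"] != res.labels["s1"]


class TestMembershipMatrix:
    def _setup(self):
        g = nx.DiGraph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        ppaps = all_ppaps(g)
        df = pd.DataFrame(
            {"s1": ["A", "A", "N"], "s2": ["N", "A", "A"], "s3": ["NT", "N", "A"]},
            index=["a", "b", "c"],
        )
        return ppaps, CallMatrix(df)

    def test_own_column_is_member(self):
        ppaps, calls = self._setup()
        mm = build_membership_matrix(ppaps, calls)
        assert all(mm.loc[q, q] == MEMBER for q in mm.index)

    def test_symmetry(self):
        ppaps, calls = self._setup()
        mm = build_membership_matrix(ppaps, calls)
        for i in mm.index:
            for j in mm.columns:
                assert (mm.loc[i, j] == MEMBER) == (mm.loc[j, i] == MEMBER)

    def test_never_co_tested_cell(self):
        g = nx.DiGraph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        ppaps = all_ppaps(g)
        df = pd.DataFrame(
            {"s1": ["A", "A", "NT", "NT"], "s2": ["NT", "NT", "A", "A"]},
            index=["a", "b", "c", "d"],
        )
        mm = build_membership_matrix(ppaps, CallMatrix(df))
        assert mm.loc["a", "c"] == NEVER_CO_TESTED
        assert mm.loc["a", "b"] == MEMBER
        assert mm.loc["b", "d"] == NEVER_CO_TESTED


class TestFisherEnrichment:
    def test_balanced_table(self):
        rec = fisher_enrichment([[5, 5], [5, 5]], tail="two")
        assert rec.fold == 1.0 and rec.p == pytest.approx(1.0)

    def test_worked_example(self):
        rec = fisher_enrichment([[2, 0], [0, 8]], tail="two")
        assert rec.p == pytest.approx(1 / 45, abs=1e-12)

    def test_one_tailed_leq_two_tailed_for_enriched(self):
        one = fisher_enrichment([[8, 2], [2, 8]], tail="one")
        two = fisher_enrichment([[8, 2], [2, 8]], tail="two")
        assert one.fold > 1 and one.p <= two.p

    def test_one_tailed_not_evaluated_below_fold_one(self):
        rec = fisher_enrichment([[1, 9], [9, 1]], tail="one")
        assert np.isnan(rec.p) and rec.direction == "negative"

    def test_degenerate_margins_flagged(self):
        rec = fisher_enrichment([[0, 0], [3, 4]], tail="two")
        assert rec.degenerate and rec.p == 1.0

    def test_matches_exact_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(80):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, 4))
            rec = fisher_enrichment([[a, b], [c, d]], tail="two")
            if not rec.degenerate:
                assert rec.p == pytest.approx(exact_fisher_two_tailed(a, b, c, d), abs=1e-9)


class TestStageTypeEnrichment:
    def test_single_category(self):
        atlas = atlas_from_rows([rule_row("a", "b"), rule_row("b", "c")])
        st_of = {"a": "adult_trait", "b": "adult_trait", "c": "adult_trait"}
        out = stage_type_rule_enrichment(atlas, st_of)
        assert len(out) == 1
        assert out.iloc[0]["observed"] == 2

    def test_planted_same_category_diagonal_enriched(self):
        rng = np.random.default_rng(4)
        phenos = {f"t{i}": "adult_trait" for i in range(10)}
        phenos.update({f"g{i}": "adult_gene" for i in range(10)})
        rows = [rule_row(f"t{i}", f"t{j}") for i in range(10) for j in range(10) if i < j]
        atlas = atlas_from_rows(rows)
        out = stage_type_rule_enrichment(atlas, phenos).set_index("category")
        diag = out.loc["adult_trait=>adult_trait"]
        assert diag["fold"] > 1 and diag["corrected"] < 0.05

    def test_holm_correction_not_below_raw(self):
        phenos = {f"t{i}": "adult_trait" for i in range(6)}
        phenos.update({f"g{i}": "adult_gene" for i in range(6)})
        rows = [rule_row("t0", "t1"), rule_row("g0", "g1"), rule_row("t2", "g2")]
        out = stage_type_rule_enrichment(atlas_from_rows(rows), phenos)
        ok = out["p"].notna()
        assert (out.loc[ok, "corrected"] >= out.loc[ok, "p"] - 1e-12).all()


class TestSystemPairEnrichment:
    def test_single_system_no_between_pairs(self):
        atlas = atlas_from_rows([rule_row("a", "b")])
        out = system_pair_enrichment(atlas, {"a": "s0", "b": "s0"})
        assert len(out) == 0

    def test_observed_counts_conserve_between_system_rules(self):
        systems = {f"p{i}": f"s{i % 3}" for i in range(9)}
        rows = [rule_row(f"p{i}", f"p{j}") for i in range(9) for j in range(i + 1, 9)][:14]
        atlas = atlas_from_rows(rows)
        out = system_pair_enrichment(atlas, systems)
        n_between = sum(
            1 for r in atlas.rules.itertuples() if systems[r.lhs] != systems[r.rhs]
        )
        assert out["observed"].sum() == n_between

    def test_planted_cross_system_coupling_detected(self):
        systems = {f"a{i}": "sA" for i in range(8)}
        systems.update({f"b{i}": "sB" for i in range(8)})
        systems.update({f"c{i}": "sC" for i in range(8)})
        # all rules concentrate on the sA--sB pair
        rows = [rule_row(f"a{i}", f"b{i}") for i in range(8)]
        out = system_pair_enrichment(atlas_from_rows(rows), systems).set_index("category")
        rec = out.loc["sA--sB"]
        assert rec["fold"] > 1 and rec["q"] < 0.01 and rec["significant"]


class TestBootstrap:
    def test_single_system_expected_zero(self):
        codes = [-1] * 50  # every possible pair is within-system
        expected, p = bootstrap_expected_system_pairs(codes, 10, B=200, seed=0, observed=0)
        assert expected == 0.0
        assert p == 1.0

    def test_null_mean_gives_half_p(self):
        # 8 systems x 5 phenotypes: 780 pairs, 28 between-system categories
        systems = np.repeat(np.arange(8), 5)
        pairs = [(i, j) for i in range(40) for j in range(i + 1, 40)]
        codes = []
        cat = {}
        for i, j in pairs:
            si, sj = systems[i], systems[j]
            codes.append(-1 if si == sj else cat.setdefault((min(si, sj), max(si, sj)), len(cat)))
        import math

        M, n = len(codes), 50
        counts = pd.Series([c for c in codes if c >= 0]).value_counts()
        analytic_mean = sum(
            1 - math.comb(M - m, n) / math.comb(M, n) for m in counts
        )
        expected, p = bootstrap_expected_system_pairs(
            codes, n, B=4000, seed=1, observed=analytic_mean
        )
        assert expected == pytest.approx(analytic_mean, rel=0.05)
        assert abs(p - 0.5) <= 0.1

    def test_expected_monotone_in_n_rules(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(-1, 6, 200)
        prev = 0.0
        for n in (5, 20, 60, 120):
            expected, _ = bootstrap_expected_system_pairs(codes, n, B=500, seed=2)
            assert expected >= prev - 1e-9
            prev = expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bootstrap_expected_system_pairs([0, 1], 5, B=100)
        with pytest.raises(ValueError):
            bootstrap_expected_system_pairs([0, 1], 1, B=0)


class TestMeasureExtremes:
    def test_constant_measure_empty(self):
        rows = [rule_row("a", "b"), rule_row("c", "d")]
        atlas = atlas_from_rows(rows)
        out = measure_extreme_enrichment(atlas, "support", {"a": "x", "c": "x"})
        assert len(out) == 0

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            measure_extreme_enrichment(atlas_from_rows([rule_row("a", "b")]), "bogus", {})

    def test_planted_high_support_category_detected(self):
        rows = [rule_row(f"hi{i}", f"hj{i}", support=0.5 + 0.01 * i) for i in range(10)]
        rows += [rule_row(f"lo{i}", f"lj{i}", support=0.01 + 0.001 * i) for i in range(30)]
        atlas = atlas_from_rows(rows)
        cats = {f"hi{i}": "HOT" for i in range(10)}
        cats.update({f"lo{i}": "COLD" for i in range(30)})
        out = measure_extreme_enrichment(atlas, "support", cats).set_index("category")
        rec = out.loc["HOT:upper"]
        assert rec["fold"] > 1 and rec["corrected"] < 0.01


class TestMeasureCorrelations:
    def _atlas(self, n=40, seed=6):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            sup = rng.uniform(0.01, 0.3)
            rows.append(
                rule_row(
                    f"x{i}", f"y{i}", support=sup, confidence_fwd=min(1, sup * 3),
                    polarity=rng.uniform(0, 2), significance_p=rng.uniform(1e-6, 0.1),
                )
            )
        return atlas_from_rows(rows)

    def test_six_pairs_reported(self):
        out = measure_correlations(self._atlas())
        assert len(out) == 6
        assert set(out.columns) >= {"measure_a", "measure_b", "rho", "p"}

    def test_matches_rank_transform_pearson_oracle(self):
        atlas = self._atlas()
        out = measure_correlations(atlas)
        sup = atlas.rules["support"].to_numpy()
        conf = atlas.rules["confidence_fwd"].to_numpy()
        ref = stats.pearsonr(stats.rankdata(sup), stats.rankdata(conf)).statistic
        row = out[(out["measure_a"] == "support") & (out["measure_b"] == "confidence")]
        assert row["rho"].iloc[0] == pytest.approx(ref, abs=1e-9)

    def test_perfectly_coupled_columns(self):
        rows = [
            rule_row(f"x{i}", f"y{i}", support=i * 0.01 + 0.01, confidence_fwd=1 - i * 0.01)
            for i in range(20)
        ]
        out = measure_correlations(atlas_from_rows(rows)).set_index(["measure_a", "measure_b"])
        assert out.loc[("support", "confidence"), "rho"] == pytest.approx(-1.0)

    def test_too_few_rules_rejected(self):
        with pytest.raises(ValueError):
            measure_correlations(atlas_from_rows([rule_row("a", "b")]))


class TestNewickExport:
    def test_tree_parses_and_has_all_leaves(self):
        rng = np.random.default_rng(7)
        ppaps = [
            make_ppap(f"q{i}", {f"q{i}"} | set(rng.choice(20, 6, replace=False).astype(str)))
            for i in range(8)
        ]
        from phenorules.community import linkage_to_newick

        res = cluster_ppaps(ppaps, k=3)
        newick = linkage_to_newick(res)
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {p.query for p in ppaps}
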