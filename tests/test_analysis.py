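"""Cohort-level ordering statistics."""

import itertools

import numpy as np
import pytest

from clonorder import (
    OrderClass,
    branching_stats,
    classify_early_late,
    count_distinct_orderings,
    homozygous_fraction,
    merge_trees,
    pairwise_order_summary,
    serial_new_event_parents,
    single_mutant_clone_size,
    trio_order_test,
    vaf_concordance,
    vaf_proxy_early,
)
from clonorder.analysis import fisher_exact_from_table, ordered_pair_fraction
from clonorder.model import ROOT, MutationTree

from conftest import (
    chain_tree,
    fisher_two_sided_oracle,
    genotype_from_codes,
    make_variant,
    multinomial_exact_pvalues_oracle,
)


def tree_from_genes(edges):
    """Build a labeled tree from (child_gene_id, parent_gene_id|None) pairs."""
    parent, variants = {}, {}
    for child, par in edges:
        parent[child] = par if par else ROOT
        variants[child] = make_variant(child)
    return MutationTree(parent, variants)


class TestEarlyLate:
    def test_chain(self):
        tree = chain_tree(["DNMT3A", "NPM1"])
        a, b = tree.nodes
        calls = classify_early_late(tree)
        assert calls[a] is OrderClass.EARLY and calls[b] is OrderClass.LATE

    def test_exactly_root_children_are_early(self):
        tree = tree_from_genes([("DNMT3A_1", None), ("NPM1_1", None),
                                ("FLT3_1", "NPM1_1"), ("NRAS_1", "NPM1_1")])
        calls = classify_early_late(tree)
        early = {n for n, c in calls.items() if c is OrderClass.EARLY}
        assert early == {n for n in tree.nodes if tree.parent[n] == ROOT}
        assert early == {"DNMT3A_1", "NPM1_1"}

    def test_single_mutation_early(self):
        tree = chain_tree(["NPM1"])
        assert classify_early_late(tree)[tree.nodes[0]] is OrderClass.EARLY


class TestPairwiseOrder:
    def test_binomial_nine_one_closed_form(self):
        """9 vs 1 precedence: two-sided exact binomial p = 22/1024."""
        trees = [tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1")])] * 9
        trees += [tree_from_genes([("FLT3_1", None), ("DNMT3A_1", "FLT3_1")])]
        summary = pairwise_order_summary(trees, "GENE")
        row = summary[(summary.g1 == "DNMT3A") & (summary.g2 == "FLT3")].iloc[0]
        assert row["n_g1_first"] == 9 and row["n_g2_first"] == 1
        assert row["binomial_p"] == pytest.approx(0.021484375, abs=1e-12)

    def test_symmetric_counts_give_p_one(self):
        trees = [tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1")])] * 3
        trees += [tree_from_genes([("FLT3_1", None), ("DNMT3A_1", "FLT3_1")])] * 3
        summary = pairwise_order_summary(trees, "GENE")
        row = summary[(summary.g1 == "DNMT3A") & (summary.g2 == "FLT3")].iloc[0]
        assert row["binomial_p"] == pytest.approx(1.0)

    def test_disjoint_branches_cooccur_without_order(self):
        trees = [tree_from_genes([("DNMT3A_1", None), ("FLT3_1", None)])] * 4
        summary = pairwise_order_summary(trees, "GENE")
        row = summary[(summary.g1 == "DNMT3A") & (summary.g2 == "FLT3")].iloc[0]
        assert row["n_same_patient"] == 4
        assert row["n_same_clone"] == 0
        assert row["n_g1_first"] == row["n_g2_first"] == 0
        assert np.isnan(row["binomial_p"])

    def test_precedence_antisymmetry(self):
        trees = [
            tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1"), ("NPM1_1", "DNMT3A_1")]),
            tree_from_genes([("FLT3_1", None), ("DNMT3A_1", "FLT3_1")]),
            tree_from_genes([("NPM1_1", None), ("DNMT3A_1", "NPM1_1"), ("FLT3_1", "DNMT3A_1")]),
        ]
        summary = pairwise_order_summary(trees, "GENE").set_index(["g1", "g2"])
        for g1, g2 in itertools.permutations(["DNMT3A", "FLT3", "NPM1"], 2):
            assert summary.loc[(g1, g2), "n_g1_first"] == summary.loc[(g2, g1), "n_g2_first"]
            assert (summary.loc[(g1, g2), "n_g1_first"] + summary.loc[(g1, g2), "n_g2_first"]
                    <= summary.loc[(g1, g2), "n_same_clone"])

    def test_self_pair_reported_separately(self):
        trees = [tree_from_genes([("NRAS_1", None), ("NRAS_2", None)])] * 2
        summary = pairwise_order_summary(trees, "GENE")
        row = summary[(summary.g1 == "NRAS") & (summary.g2 == "NRAS")].iloc[0]
        assert row["n_same_patient"] == 2
        assert row["n_same_clone"] == 0  # disjoint branches


class TestTrioOrder:
    def test_single_observation_p_one(self):
        assert trio_order_test([1, 0, 0, 0, 0, 0]) == pytest.approx(1.0)

    def test_uniform_counts_p_one(self):
        assert trio_order_test([2] * 6) == pytest.approx(1.0)

    def test_concentrated_counts_match_enumeration(self):
        oracle = multinomial_exact_pvalues_oracle(4)
        assert trio_order_test([4, 0, 0, 0, 0, 0]) == pytest.approx(
            oracle[(4, 0, 0, 0, 0, 0)], abs=1e-12
        )

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_matches_sequence_enumeration_oracle(self, n):
        """Every count vector at size n agrees with the 6^n enumeration."""
        oracle = multinomial_exact_pvalues_oracle(n)
        for vec, expected in oracle.items():
            assert trio_order_test(list(vec)) == pytest.approx(expected, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            trio_order_test([0] * 6)
        with pytest.raises(ValueError):
            trio_order_test([1, 2, 3])


class TestMergedGraph:
    def test_identical_chains_stack_weights(self):
        trees = [tree_from_genes([("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1")])] * 2
        g = merge_trees(trees, "GENE")
        assert g.nodes[("DNMT3A",)]["count"] == 2
        assert g.nodes[("DNMT3A", "NPM1")]["count"] == 2

    def test_shared_prefix_splits(self):
        trees = [
            tree_from_genes([("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1")]),
            tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1")]),
        ]
        g = merge_trees(trees, "GENE")
        assert g.nodes[("DNMT3A",)]["count"] == 2
        assert g.nodes[("DNMT3A", "NPM1")]["count"] == 1
        assert g.nodes[("DNMT3A", "FLT3")]["count"] == 1

    def test_min_count_drops_rare_keys(self):
        trees = [tree_from_genes([("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1")])] * 4
        g = merge_trees(trees, "GENE", min_count=5)
        assert ("DNMT3A",) not in g.nodes

    def test_weights_decrease_along_extensions(self):
        trees = [
            tree_from_genes([("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1"), ("FLT3_1", "NPM1_1")]),
            tree_from_genes([("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1")]),
            tree_from_genes([("DNMT3A_1", None)]),
        ]
        g = merge_trees(trees, "GENE")
        for key in g.nodes:
            for _, child in g.out_edges(key):
                assert g.nodes[key]["count"] >= g.nodes[child]["count"]


class TestDistinctOrderings:
    def test_prefix_is_indistinct(self):
        trees = [
            tree_from_genes([("A_1", None, ), ("B_1", "A_1")]),
            tree_from_genes([("A_1", None), ("B_1", "A_1"), ("C_1", "B_1")]),
        ]
        assert count_distinct_orderings(trees) == 1

    def test_reversed_orders_distinct(self):
        trees = [
            tree_from_genes([("A_1", None), ("B_1", "A_1")]),
            tree_from_genes([("B_1", None), ("A_1", "B_1")]),
        ]
        assert count_distinct_orderings(trees) == 2

    def test_empty_cohort(self):
        assert count_distinct_orderings([]) == 0

    def test_invariant_to_duplication_and_order(self):
        trees = [
            tree_from_genes([("A_1", None), ("B_1", "A_1")]),
            tree_from_genes([("B_1", None), ("A_1", "B_1")]),
            tree_from_genes([("A_1", None), ("C_1", "A_1")]),
        ]
        base = count_distinct_orderings(trees)
        assert count_distinct_orderings(trees[::-1]) == base
        assert count_distinct_orderings(trees + [trees[0]]) == base


class TestBranching:
    def test_linear_cohort_has_no_branch_points(self):
        stats = branching_stats([chain_tree(["DNMT3A", "NPM1", "FLT3"])])
        assert stats.n_branch_points == 0
        assert stats.post_branch_pathway_fraction.empty

    def test_post_branch_composition(self):
        tree = tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1"),
                                ("IDH1_1", "DNMT3A_1")])
        stats = branching_stats([tree])
        assert stats.n_branch_points == 1
        assert stats.post_branch_pathway_fraction["SIGNALING"] == pytest.approx(0.5)
        assert stats.post_branch_pathway_fraction["DNA_METHYLATION"] == pytest.approx(0.5)

    def test_signaling_only_branching_cohort(self):
        trees = [
            tree_from_genes([("NPM1_1", None), ("FLT3_1", "NPM1_1"), ("NRAS_1", "NPM1_1")]),
            tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1"), ("KRAS_1", "DNMT3A_1")]),
        ]
        stats = branching_stats(trees)
        assert stats.post_branch_pathway_fraction["SIGNALING"] == pytest.approx(1.0)
        assert set(stats.branch_point_genes.index) == {"NPM1", "DNMT3A"}


class TestCloneSizeAndVaf:
    def test_clone_size_difference(self):
        codes = np.zeros((100, 2), dtype=np.int8)
        codes[:80, 0] = 1
        codes[:60, 1] = 1
        m = genotype_from_codes(codes)
        assert single_mutant_clone_size(m, "V0", "V1") == pytest.approx(0.20)

    def test_identical_columns_zero(self):
        codes = np.zeros((50, 2), dtype=np.int8)
        codes[:20, :] = 1
        m = genotype_from_codes(codes)
        assert single_mutant_clone_size(m, "V0", "V1") == 0.0

    def test_denominators_are_per_variant(self):
        codes = np.array([[1, 3], [1, 1], [0, 0], [3, 0]], dtype=np.int8)
        m = genotype_from_codes(codes)
        # first: 2/3 called mutant; second: 1/3
        assert single_mutant_clone_size(m, "V0", "V1") == pytest.approx(2 / 3 - 1 / 3)

    def test_perfect_linearity_r_one(self):
        pairs = [(x / 2, x) for x in (0.1, 0.3, 0.5, 0.7)]
        result = vaf_concordance(pairs)
        assert result.defined and result.r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            vaf_concordance([(0.1, 0.2), (0.2, 0.4)])

    def test_zero_variance_flagged(self):
        result = vaf_concordance([(0.1, 0.2), (0.1, 0.4), (0.1, 0.6)])
        assert not result.defined and np.isnan(result.r)

    @pytest.mark.parametrize("vaf,expected", [
        (0.45, OrderClass.EARLY), (0.3, OrderClass.EARLY), (0.05, OrderClass.LATE),
    ])
    def test_vaf_proxy_cutoff(self, vaf, expected):
        assert vaf_proxy_early(vaf) is expected


class TestHomozygousFraction:
    def test_mixed_codes(self):
        m = genotype_from_codes([[1], [1], [2], [2], [0], [3]])
        assert homozygous_fraction(m, "V0") == pytest.approx(0.5)

    def test_no_hom_cells(self):
        m = genotype_from_codes([[1], [1], [0]])
        assert homozygous_fraction(m, "V0") == 0.0

    def test_all_hom(self):
        m = genotype_from_codes([[2], [2]])
        assert homozygous_fraction(m, "V0") == 1.0

    def test_no_mutant_cells_undefined(self):
        m = genotype_from_codes([[0], [3]])
        assert np.isnan(homozygous_fraction(m, "V0"))


class TestSerialParents:
    def test_forced_npm1_parents_fill_one_cell(self):
        merged = tree_from_genes([
            ("NPM1_1", None), ("FLT3_9", "NPM1_1"), ("NRAS_9", "NPM1_1"),
        ])
        result = serial_new_event_parents(merged, earlier_variant_ids={"NPM1_1"})
        assert set(result.new_events) == {"FLT3_9", "NRAS_9"}
        assert result.table[0, 0] == 2  # both parents NPM1-or-DNAme
        assert result.table[1, 0] == 0

    def test_fisher_p_matches_hypergeometric_oracle(self):
        merged = tree_from_genes([
            ("DNMT3A_1", None), ("NPM1_1", "DNMT3A_1"), ("RUNX1_1", "DNMT3A_1"),
            ("FLT3_9", "NPM1_1"), ("NRAS_9", "DNMT3A_1"), ("KRAS_9", "RUNX1_1"),
        ])
        earlier = {"DNMT3A_1", "NPM1_1", "RUNX1_1"}
        result = serial_new_event_parents(merged, earlier)
        assert result.table is not None
        assert result.fisher_p == pytest.approx(fisher_two_sided_oracle(result.table), abs=1e-12)

    def test_zero_new_events_no_test(self):
        merged = tree_from_genes([("NPM1_1", None)])
        result = serial_new_event_parents(merged, earlier_variant_ids={"NPM1_1"})
        assert result.new_events == [] and result.table is None and result.fisher_p is None


class TestOrderedPairFraction:
    def test_counts_only_mixed_comparable_pairs(self):
        trees = [
            tree_from_genes([("DNMT3A_1", None), ("FLT3_1", "DNMT3A_1")]),
            tree_from_genes([("FLT3_1", None), ("DNMT3A_1", "FLT3_1")]),
            tree_from_genes([("DNMT3A_1", None), ("FLT3_1", None)]),  # incomparable
        ]
        frac, n = ordered_pair_fraction(trees)
        assert n == 2 and frac == pytest.approx(0.5)
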