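"""Tree likelihood, exhaustive enumeration, MCMC search, cell attachment."""

import itertools
import math

import numpy as np
import pytest

from clonorder import (
    ErrorModel,
    GenotypeMatrix,
    PatientDataset,
    Timepoint,
    VariantStatus,
    attach_cells,
    binarize_genotypes,
    enumerate_trees_exact,
    infer_tree_mcmc,
    merge_samples,
    sample_random_tree,
    simulate_genotype_matrix,
    tree_log_likelihood,
)
from clonorder.inference import _is_valid_tree
from clonorder.model import ROOT, BinaryMatrix, MutationTree
from clonorder.synthetic import patient_rng

from conftest import binary_from_codes, chain_tree, genotype_from_codes, make_variant, naive_tree_log_likelihood


class TestBinarize:
    def test_code_map(self):
        m = genotype_from_codes([[0, 1, 2, 3]],
                                [make_variant(f"V{i}", "NPM1") for i in range(4)])
        assert binarize_genotypes(m).calls.tolist() == [[0, 1, 1, 3]]

    def test_idempotent_on_binary_input(self):
        m = genotype_from_codes([[0, 1], [1, 0]])
        b = binarize_genotypes(m)
        assert np.array_equal(b.calls, m.calls)

    def test_vus_mask_from_status(self):
        variants = [make_variant("V0", "NPM1"),
                    make_variant("V1", "NPM1", status=VariantStatus.VUS)]
        m = genotype_from_codes([[0, 0]], variants)
        assert binarize_genotypes(m).vus_mask.tolist() == [False, True]


class TestMergeSamples:
    def _sample(self, sid, variants, codes, tp=Timepoint.DIAGNOSIS):
        return GenotypeMatrix([f"{sid}c{i}" for i in range(len(codes))], variants,
                              np.array(codes, dtype=np.int8), sample_id=sid, timepoint=tp)

    def test_single_sample_identity_on_codes(self):
        v = [make_variant("NPM1_1")]
        s = self._sample("s1", v, [[1], [2], [3]])
        merged = merge_samples(PatientDataset("p", [s]))
        assert merged.calls.tolist() == [[1], [1], [3]]

    def test_absent_variant_assumed_wildtype(self):
        """A variant with no column at one timepoint scores 0 for those cells."""
        v1, v2 = make_variant("NPM1_1"), make_variant("FLT3_1")
        s1 = self._sample("dx", [v1], [[1], [0]])
        s2 = self._sample("rel", [v1, v2], [[1, 1]], tp=Timepoint.RELAPSE)
        merged = merge_samples(PatientDataset("p", [s1, s2]))
        assert merged.variant_ids == ["NPM1_1", "FLT3_1"]
        assert merged.calls.tolist() == [[1, 0], [0, 0], [1, 1]]
        assert merged.cell_ids[0].startswith("dx:")

    def test_cell_counts_add(self):
        v = [make_variant("NPM1_1")]
        s1 = self._sample("a", v, [[0]] * 300)
        s2 = self._sample("b", v, [[0]] * 500)
        assert merge_samples(PatientDataset("p", [s1, s2])).n_cells == 800

    def test_conflicting_metadata_rejected(self):
        s1 = self._sample("a", [make_variant("X_1", "NPM1", pos=100)], [[0]])
        s2 = self._sample("b", [make_variant("X_1", "NPM1", pos=200)], [[0]])
        with pytest.raises(ValueError, match="conflicting"):
            merge_samples(PatientDataset("p", [s1, s2]))


class TestTreeLogLikelihood:
    def test_single_cell_closed_form(self):
        """One cell, one mutation, observed 1: LL = log((1/2)[(1-beta) + alpha])."""
        tree = chain_tree(["NPM1"])
        data = binary_from_codes([[1]], list(tree.variants.values()))
        err = ErrorModel(0.05, 0.2)
        expected = math.log(0.5 * ((1 - 0.2) + 0.05))
        assert tree_log_likelihood(tree, data, err) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_gives_zero(self):
        tree = chain_tree(["NPM1", "FLT3"])
        data = binary_from_codes(np.full((4, 2), 3), list(tree.variants.values()))
        assert tree_log_likelihood(tree, data, ErrorModel(0.01, 0.2)) == 0.0

    def test_matches_naive_product_oracle(self, small_pool, err):
        """Vectorized log-sum-exp equals the direct per-cell product to 1e-9."""
        for seed in range(5):
            rng = patient_rng(21, seed)
            tree = sample_random_tree(4, 0.3, small_pool, 0.7, rng)
            matrix, _ = simulate_genotype_matrix(tree, rng.dirichlet([1.0] * 5), 30,
                                                 err, 0.1, 0.05, rng)
            data = binarize_genotypes(matrix)
            assert tree_log_likelihood(tree, data, err) == pytest.approx(
                naive_tree_log_likelihood(tree, data, err), abs=1e-9
            )

    def test_true_tree_beats_every_edge_swap(self, small_pool):
        """Noise-free data: the generating 3-mutation tree dominates all trees."""
        rng = patient_rng(22, 0)
        tree = sample_random_tree(3, 0.4, small_pool, 0.7, rng)
        matrix, _ = simulate_genotype_matrix(tree, np.full(4, 0.25), 120,
                                             ErrorModel(0.0, 0.0), 0.0, 0.0, rng)
        data = binarize_genotypes(matrix)
        err = ErrorModel(1e-6, 1e-6)
        ll_true = tree_log_likelihood(tree, data, err)
        n = 3
        for cand in itertools.product(range(-1, n), repeat=n):
            if any(cand[i] == i for i in range(n)) or not _is_valid_tree(cand):
                continue
            parent = {data.variant_ids[i]: (ROOT if p < 0 else data.variant_ids[p])
                      for i, p in enumerate(cand)}
            if parent == tree.parent:
                continue
            other = MutationTree(parent)
            assert tree_log_likelihood(other, data, err) < ll_true

    def test_tree_variant_missing_from_data_rejected(self):
        tree = chain_tree(["NPM1", "FLT3"])
        data = binary_from_codes([[1]], [make_variant(list(tree.nodes)[0], "NPM1")])
        with pytest.raises(ValueError, match="absent from data"):
            tree_log_likelihood(tree, data, ErrorModel(0.01, 0.2))


class TestEnumerateExact:
    @pytest.mark.parametrize("n,expected", [(2, 3), (3, 16)])
    def test_tree_count_matches_cayley(self, n, expected):
        """(n+1)^(n-1) labeled rooted trees on n mutations."""
        count = sum(
            1 for cand in itertools.product(range(-1, n), repeat=n)
            if not any(cand[i] == i for i in range(n)) and _is_valid_tree(cand)
        )
        assert count == expected == (n + 1) ** (n - 1)

    def test_best_dominates_all_enumerated(self, err):
        rng = patient_rng(23, 0)
        data = binary_from_codes(rng.integers(0, 2, size=(20, 3)))
        best, best_ll = enumerate_trees_exact(data, err)
        n = 3
        for cand in itertools.product(range(-1, n), repeat=n):
            if any(cand[i] == i for i in range(n)) or not _is_valid_tree(cand):
                continue
            parent = {data.variant_ids[i]: (ROOT if p < 0 else data.variant_ids[p])
                      for i, p in enumerate(cand)}
            assert tree_log_likelihood(MutationTree(parent), data, err) <= best_ll + 1e-9

    def test_refuses_large_instances(self, err):
        data = binary_from_codes(np.zeros((2, 7)))
        with pytest.raises(ValueError, match="refusing"):
            enumerate_trees_exact(data, err)


class TestMcmc:
    def test_matches_exhaustive_on_small_instances(self, small_pool, err):
        for seed in range(5):
            rng = patient_rng(24, seed)
            tree = sample_random_tree(4, 0.3, small_pool, 0.6, rng)
            matrix, _ = simulate_genotype_matrix(tree, rng.dirichlet([1.0] * 5), 50,
                                                 err, 0.1, 0.05, rng)
            data = binarize_genotypes(matrix)
            _, ll_exact = enumerate_trees_exact(data, err)
            inferred = infer_tree_mcmc(data, err, seed=seed)
            assert inferred.log_likelihood == pytest.approx(ll_exact, abs=1e-9)

    def test_recovers_noise_free_chain(self):
        tree = chain_tree(["DNMT3A", "NPM1", "FLT3", "NRAS", "IDH1"])
        rng = patient_rng(25, 0)
        matrix, _ = simulate_genotype_matrix(tree, np.full(6, 1 / 6), 240,
                                             ErrorModel(0.0, 0.0), 0.0, 0.0, rng)
        data = binarize_genotypes(matrix)
        inferred = infer_tree_mcmc(data, ErrorModel(1e-6, 1e-6), seed=1)
        assert inferred.parent == tree.parent

    def test_same_seed_same_tree(self, small_pool, err):
        rng = patient_rng(26, 0)
        tree = sample_random_tree(5, 0.3, small_pool, 0.7, rng)
        matrix, _ = simulate_genotype_matrix(tree, rng.dirichlet([1.0] * 6), 100,
                                             err, 0.1, 0.05, rng)
        data = binarize_genotypes(matrix)
        t1 = infer_tree_mcmc(data, err, seed=7)
        t2 = infer_tree_mcmc(data, err, seed=7)
        assert t1.parent == t2.parent

    def test_vus_contracted_from_returned_tree(self, err):
        """VUS variants join the search but not the returned driver tree."""
        variants = [make_variant("NPM1_1"),
                    make_variant("X_1", "WEIRD", status=VariantStatus.VUS)]
        rng = patient_rng(27, 0)
        codes = np.zeros((60, 2), dtype=np.int8)
        codes[:30, 0] = 1
        codes[:15, 1] = 1
        data = binary_from_codes(codes, variants, vus=np.array([False, True]))
        inferred = infer_tree_mcmc(data, err, seed=0)
        assert set(inferred.nodes) == {"NPM1_1"}

    def test_all_missing_rejected(self, err):
        data = binary_from_codes(np.full((3, 2), 3))
        with pytest.raises(ValueError, match="informative"):
            infer_tree_mcmc(data, err, seed=0)


class TestAttachCells:
    def test_exact_match_attaches_to_node(self):
        tree = chain_tree(["DNMT3A", "NPM1"])
        a, b = tree.nodes
        data = binary_from_codes([[1, 0]], list(tree.variants.values()))
        att = attach_cells(tree, data, ErrorModel(0.01, 0.2))
        assert att["c0"] == a

    def test_all_missing_cell_attaches_to_root(self):
        tree = chain_tree(["DNMT3A", "NPM1"])
        data = binary_from_codes([[3, 3]], list(tree.variants.values()))
        att = attach_cells(tree, data, ErrorModel(0.01, 0.2))
        assert att["c0"] == ROOT

    def test_recovery_rate_on_simulated_data(self, small_pool):
        """alpha=0.01, beta=0.2, 500 cells: >=80% true-node attachment (10 seeds)."""
        err = ErrorModel(0.01, 0.2)
        rates = []
        for seed in range(10):
            rng = patient_rng(28, seed)
            tree = sample_random_tree(3, 0.2, small_pool, 0.8, rng)
            matrix, truth = simulate_genotype_matrix(tree, rng.dirichlet([1.0] * 4), 500,
                                                     err, 0.0, 0.0, rng)
            data = binarize_genotypes(matrix)
            att = attach_cells(tree, data, err)
            rates.append(np.mean([att[c] == truth[c] for c in data.cell_ids]))
        assert np.mean(rates) >= 0.80
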