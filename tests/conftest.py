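"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from clonorder import (
    BinaryMatrix,
    ErrorModel,
    GenotypeMatrix,
    MutationTree,
    Pathway,
    Variant,
    linear_tree,
)
from clonorder.model import ROOT


def make_variant(vid: str, gene: str | None = None, **kwargs) -> Variant:
    defaults = dict(chrom="1", pos=1000, ref="A", alt="T")
    defaults.update(kwargs)
    return Variant(vid, gene or vid.split("_")[0], **defaults)


@pytest.fixture
def small_pool() -> dict:
    return {
        Pathway.DNA_METHYLATION: ["DNMT3A", "IDH1"],
        Pathway.SIGNALING: ["FLT3", "NRAS"],
        Pathway.NPM1: ["NPM1"],
    }


@pytest.fixture
def err() -> ErrorModel:
    return ErrorModel(0.01, 0.2)


def chain_tree(genes: list[str]) -> MutationTree:
    """Linear tree with one variant per gene: root -> genes[0] -> ..."""
    vids = [f"{g}_{i}" for i, g in enumerate(genes)]
    variants = {vid: make_variant(vid, g) for vid, g in zip(vids, genes)}
    return linear_tree(vids, variants)


def binary_from_codes(codes, variants=None, vus=None) -> BinaryMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    n_cells, n_var = codes.shape
    if variants is None:
        variants = [make_variant(f"V{j}", "DNMT3A") for j in range(n_var)]
    if vus is None:
        vus = np.zeros(n_var, dtype=bool)
    return BinaryMatrix([f"c{i}" for i in range(n_cells)], variants, codes, vus)


def genotype_from_codes(codes, variants=None, sample_id="s") -> GenotypeMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    n_cells, n_var = codes.shape
    if variants is None:
        variants = [make_variant(f"V{j}", "DNMT3A") for j in range(n_var)]
    return GenotypeMatrix([f"c{i}" for i in range(n_cells)], variants, codes, sample_id=sample_id)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_tree_log_likelihood(tree: MutationTree, data: BinaryMatrix, err: ErrorModel) -> float:
    """Direct per-cell, per-node product implementation (no vectorization)."""
    nodes = [ROOT] + tree.nodes
    total = 0.0
    for i in range(data.n_cells):
        cell_sum = 0.0
        for node in nodes:
            on_path = set(tree.root_path(node)) if node != ROOT else set()
            p = 1.0
            for j, vid in enumerate(data.variant_ids):
                if vid not in tree.parent:
                    continue
                obs = int(data.calls[i, j])
                if obs == 3:
                    continue
                expected = 1 if vid in on_path else 0
                if expected == 0:
                    p *= err.alpha if obs == 1 else 1.0 - err.alpha
                else:
                    p *= 1.0 - err.beta if obs == 1 else err.beta
            cell_sum += p
        total += math.log(cell_sum / len(nodes))
    return total


def clopper_pearson_lower_oracle(k: int, n: int, level: float = 0.95, iters: int = 80) -> float:
    """Definitional Clopper-Pearson lower bound by bisection on the binomial tail.

    The lower bound is the p solving P(X >= k | n, p) = (1 - level)/2,
    with the tail computed by direct pmf summation (log-space).
    """
    if k == 0:
        return 0.0
    alpha2 = (1.0 - level) / 2.0
    log_comb = [math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1) for i in range(n + 1)]

    def upper_tail(p: float) -> float:
        if p <= 0.0:
            return 0.0
        if p >= 1.0:
            return 1.0
        return sum(
            math.exp(log_comb[i] + i * math.log(p) + (n - i) * math.log1p(-p))
            for i in range(k, n + 1)
        )

    lo, hi = 0.0, 1.0
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if upper_tail(mid) < alpha2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def multinomial_exact_pvalues_oracle(n: int, k: int = 6) -> dict[tuple, float]:
    """Exact multinomial test oracle by enumerating all k**n ordered sequences.

    Under the uniform null every sequence is equiprobable, so an outcome
    vector's probability is (its multiplicity) / k**n; the p-value of an
    observed vector is the fraction of sequences whose outcome multiplicity
    does not exceed the observed multiplicity. Integer arithmetic
    throughout.
    """
    grid = np.indices((k,) * n).reshape(n, -1).T  # (k**n, n) category sequences
    outcomes = np.zeros((grid.shape[0], k), dtype=np.int64)
    for cat in range(k):
        outcomes[:, cat] = (grid == cat).sum(axis=1)
    uniq, inverse, counts = np.unique(outcomes, axis=0, return_inverse=True, return_counts=True)
    pvals = {}
    total = k**n
    for idx in range(uniq.shape[0]):
        mult = counts[idx]
        numerator = int(counts[counts <= mult].sum())
        pvals[tuple(int(x) for x in uniq[idx])] = numerator / total
    return pvals


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x: int) -> float:
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, col1 - row2), min(col1, row1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))
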