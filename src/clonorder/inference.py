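"""Maximum-likelihood mutation-tree inference from noisy single-cell genotypes.

The model follows the single-cell infinite-sites framework: a rooted tree
whose non-root nodes are mutation events, each occurring exactly once and
never reverting. A cell attaches to some node and carries exactly the
mutations on that node's root path. Observations are corrupted by a global
false-positive rate ``alpha`` (wildtype read as mutant) and a false-negative
allele-dropout rate ``beta`` (mutant read as wildtype); missing calls carry
no information. The tree likelihood marginalizes each cell's attachment
uniformly over all nodes (root included):

    log L(T) = sum_cells log( (1/N) sum_nodes prod_variants P(obs | exp, alpha, beta) )

Search is Metropolis MCMC over labeled rooted trees with two symmetric
moves (prune-and-reattach of a subtree; swap of two node labels), plus an
exhaustive enumeration oracle for small instances (the number of labeled
rooted trees on n mutations is (n+1)^(n-1)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .model import ROOT, BinaryMatrix, ErrorModel, GenotypeMatrix, MutationTree, PatientDataset, Variant, VariantStatus

__all__ = [
    "binarize_genotypes",
    "merge_samples",
    "tree_log_likelihood",
    "enumerate_trees_exact",
    "infer_tree_mcmc",
    "attach_cells",
]

MAX_EXACT_VARIANTS = 6


# ---------------------------------------------------------------------------
# binarization and sample merging
# ---------------------------------------------------------------------------

def binarize_genotypes(matrix: GenotypeMatrix) -> BinaryMatrix:
    """Collapse zygosity: codes 0->0, 1->1, 2->1, 3->3.

    Zygosity is ignored for tree building; hom-or-LOH calls count as mutant.
    """
    calls = matrix.calls.copy()
    calls[calls == 2] = 1
    vus_mask = np.array([v.status is VariantStatus.VUS for v in matrix.variants], dtype=bool)
    return BinaryMatrix(list(matrix.cell_ids), list(matrix.variants), calls, vus_mask)


def merge_samples(patient: PatientDataset) -> BinaryMatrix:
    """Merge a patient's samples into one binary mutation matrix.

    Rows are concatenated over the union of variants (ordered by first
    appearance); a variant with no column in some sample is scored 0
    (wildtype, not missing) for that sample's cells — mutations absent at
    one timepoint but present at another are assumed wildtype when absent.
    Cell ids are prefixed with their sample_id.
    """
    if not patient.samples:
        raise ValueError(f"patient {patient.patient_id!r} has no samples")
    union: dict[str, Variant] = {}
    for sample in patient.samples:
        for v in sample.variants:
            union.setdefault(v.variant_id, v)
    variant_ids = list(union)
    blocks, cell_ids = [], []
    for sample in patient.samples:
        binary = binarize_genotypes(sample)
        block = np.zeros((binary.n_cells, len(variant_ids)), dtype=np.int8)
        for j, vid in enumerate(variant_ids):
            if vid in binary.variant_ids:
                block[:, j] = binary.column(vid)
        blocks.append(block)
        cell_ids.extend(f"{sample.sample_id}:{c}" for c in sample.cell_ids)
    calls = np.vstack(blocks) if blocks else np.zeros((0, len(variant_ids)), dtype=np.int8)
    variants = [union[vid] for vid in variant_ids]
    vus_mask = np.array([v.status is VariantStatus.VUS for v in variants], dtype=bool)
    return BinaryMatrix(cell_ids, variants, calls, vus_mask)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class _LikelihoodWorkspace:
    """Per-dataset precomputation for fast repeated tree scoring.

    Duplicate observation rows are collapsed to unique rows with weights;
    per-row we store the log-probability under all-wildtype expectation
    (``base``) and the per-variant increment for a mutant expectation
    (``delta``). Missing calls contribute 0 either way.
    """

    variant_ids: list[str]
    weights: np.ndarray        # (u,)
    base: np.ndarray           # (u,)
    delta: np.ndarray          # (u, m)
    L0: np.ndarray             # (u, m) log P(obs | expected 0)
    L1: np.ndarray             # (u, m) log P(obs | expected 1)
    finite: bool               # fast base+delta path is numerically valid
    n_cells: int
    row_of_cell: np.ndarray    # (n_cells,) -> unique-row index

    @classmethod
    def build(cls, calls: np.ndarray, variant_ids: list[str], err: ErrorModel) -> "_LikelihoodWorkspace":
        alpha, beta = err.alpha, err.beta
        uniq, inverse, counts = np.unique(calls, axis=0, return_inverse=True, return_counts=True)
        la = math.log(alpha) if alpha > 0 else -np.inf
        lb = math.log(beta) if beta > 0 else -np.inf
        l1a, l1b = math.log1p(-alpha), math.log1p(-beta)
        L0 = np.where(uniq == 1, la, np.where(uniq == 0, l1a, 0.0))
        L1 = np.where(uniq == 1, l1b, np.where(uniq == 0, lb, 0.0))
        finite = bool(np.isfinite(L0).all() and np.isfinite(L1).all())
        return cls(
            variant_ids=list(variant_ids),
            weights=counts.astype(float),
            base=L0.sum(axis=1),
            delta=L1 - L0 if finite else L1,
            L0=L0,
            L1=L1,
            finite=finite,
            n_cells=calls.shape[0],
            row_of_cell=inverse,
        )

    def scores(self, expected: np.ndarray) -> np.ndarray:
        """(u, nodes) attachment log-probabilities for expected genotypes."""
        if self.finite:
            return self.base[:, None] + self.delta @ expected.T
        # exact-zero error rates produce -inf log-probs; avoid -inf + inf
        mask = expected[None, :, :] == 1.0  # (1, nodes, m)
        return np.where(mask, self.L1[:, None, :], self.L0[:, None, :]).sum(axis=2)

    def log_likelihood(self, expected: np.ndarray) -> float:
        s = self.scores(expected)
        mx = s.max(axis=1)
        # guard fully -inf rows (possible when alpha or beta is exactly 0)
        safe = np.where(np.isfinite(mx), mx, 0.0)
        with np.errstate(divide="ignore"):
            lse = safe + np.log(np.exp(s - safe[:, None]).sum(axis=1))
        return float((self.weights * (lse - math.log(expected.shape[0]))).sum())


def _expected_genotypes(parents: np.ndarray) -> np.ndarray:
    """(n+1, n) expected binary genotype per attachment node.

    Row 0 is the root (all wildtype); row i+1 is mutation i's node whose
    genotype is the indicator of mutations on its root path. ``parents``
    codes the root as -1.
    """
    n = parents.shape[0]
    expected = np.zeros((n + 1, n), dtype=np.float64)
    done = np.zeros(n, dtype=bool)
    for i in range(n):
        chain = []
        j = i
        while j >= 0 and not done[j]:
            chain.append(j)
            j = parents[j]
        tail = expected[j + 1] if j >= 0 else expected[0]
        for k in reversed(chain):
            expected[k + 1] = tail
            expected[k + 1, k] = 1.0
            tail = expected[k + 1]
            done[k] = True
    return expected


def _parents_array(tree: MutationTree, variant_ids: list[str]) -> np.ndarray:
    index = {vid: i for i, vid in enumerate(variant_ids)}
    missing = [n for n in tree.nodes if n not in index]
    if missing:
        raise ValueError(f"tree node(s) {missing} absent from data")
    # positions in `variant_ids` order restricted to tree nodes
    tree_ids = [vid for vid in variant_ids if vid in tree.parent]
    pos = {vid: i for i, vid in enumerate(tree_ids)}
    parents = np.empty(len(tree_ids), dtype=np.int64)
    for vid in tree_ids:
        p = tree.parent[vid]
        parents[pos[vid]] = -1 if p == ROOT else pos[p]
    return parents


def _tree_from_parents(parents: np.ndarray, variant_ids: list[str], variants: dict[str, Variant]) -> MutationTree:
    parent_map = {
        variant_ids[i]: (ROOT if p < 0 else variant_ids[p]) for i, p in enumerate(parents)
    }
    return MutationTree(parent_map, {vid: variants[vid] for vid in parent_map if vid in variants})


def tree_log_likelihood(tree: MutationTree, data: BinaryMatrix, err: ErrorModel) -> float:
    """Marginal log-likelihood of ``data`` under ``tree``.

    Only the data columns corresponding to tree nodes enter the product;
    every tree node must be a data variant. Missing observations contribute
    probability 1.
    """
    tree_ids = [vid for vid in data.variant_ids if vid in tree.parent]
    cols = [data.variant_index(v) for v in tree_ids]
    parents = _parents_array(tree, data.variant_ids)
    ws = _LikelihoodWorkspace.build(data.calls[:, cols], tree_ids, err)
    return ws.log_likelihood(_expected_genotypes(parents))


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def _is_valid_tree(parents: tuple[int, ...]) -> bool:
    n = len(parents)
    for start in range(n):
        seen = set()
        j = start
        while j >= 0:
            if j in seen:
                return False
            seen.add(j)
            j = parents[j]
    return True


def enumerate_trees_exact(data: BinaryMatrix, err: ErrorModel) -> tuple[MutationTree, float]:
    """Score every labeled rooted mutation tree and return the best.

    Refuses instances with more than 6 variants (there are (n+1)^(n-1)
    trees). Ties are broken toward the lexicographically smallest canonical
    parent-vector.
    """
    n = len(data.variants)
    if n == 0:
        raise ValueError("no variants to build a tree over")
    if n > MAX_EXACT_VARIANTS:
        raise ValueError(f"refusing exhaustive enumeration for {n} > {MAX_EXACT_VARIANTS} variants")
    ws = _LikelihoodWorkspace.build(data.calls, data.variant_ids, err)
    best_ll = -np.inf
    best_parents: np.ndarray | None = None
    best_key: tuple[str, ...] | None = None
    vmap = data.variant_map()
    for cand in itertools.product(range(-1, n), repeat=n):
        if any(cand[i] == i for i in range(n)) or not _is_valid_tree(cand):
            continue
        parents = np.array(cand, dtype=np.int64)
        ll = ws.log_likelihood(_expected_genotypes(parents))
        if ll > best_ll + 1e-12:
            best_ll, best_parents, best_key = ll, parents, None
        elif ll >= best_ll - 1e-12:
            if best_key is None:
                best_key = _tree_from_parents(best_parents, data.variant_ids, vmap).canonical_parent_vector()
            key = _tree_from_parents(parents, data.variant_ids, vmap).canonical_parent_vector()
            if key < best_key:
                best_parents, best_key = parents, key
                best_ll = max(best_ll, ll)
    tree = _tree_from_parents(best_parents, data.variant_ids, vmap)
    tree.log_likelihood = best_ll
    return tree, best_ll


# ---------------------------------------------------------------------------
# MCMC search
# ---------------------------------------------------------------------------

def _random_tree_parents(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rooted tree via random attachment plus relabeling."""
    parents = np.empty(n, dtype=np.int64)
    order = rng.permutation(n)
    placed: list[int] = []
    for idx in order:
        parents[idx] = -1 if not placed else int(rng.choice([-1] + placed))
        placed.append(idx)
    return parents


def _descendants(parents: np.ndarray, v: int) -> np.ndarray:
    n = parents.shape[0]
    mark = np.zeros(n, dtype=bool)
    mark[v] = True
    changed = True
    while changed:
        newly = (~mark) & (parents >= 0) & mark[np.maximum(parents, 0)]
        changed = bool(newly.any())
        mark |= newly
    return mark


def infer_tree_mcmc(
    data: BinaryMatrix,
    err: ErrorModel,
    n_iter: int | None = None,
    n_chains: int = 2,
    seed: int = 0,
) -> MutationTree:
    """MCMC maximum-likelihood search over mutation trees.

    Runs ``n_chains`` independent seeded chains of Metropolis MCMC with two
    symmetric proposals — prune-and-reattach a subtree, or swap two node
    labels — and returns the best tree visited across all chains. Variants
    flagged VUS participate in the search (they inform tree architecture)
    and are contracted out of the returned tree, so downstream order
    inference sees drivers only. ``n_iter=None`` picks an instance-size
    default of ``1500 + 250 * n_variants**2`` iterations per chain.

    The returned tree carries the recomputed driver-only log-likelihood; the
    search-space (pre-contraction) optimum is stored on
    ``tree.search_log_likelihood``.
    """
    n = len(data.variants)
    if n == 0:
        raise ValueError("no variants to build a tree over")
    informative = (data.calls != 3).any(axis=1)
    if not informative.any():
        raise ValueError("zero informative cells (all calls missing)")
    if n_iter is None:
        # scale with the (n+1)^(n-1) search space: generous for small trees,
        # bounded for panel-sized ones
        n_iter = 1500 + 250 * n * n
    ws = _LikelihoodWorkspace.build(data.calls, data.variant_ids, err)
    vmap = data.variant_map()

    best_ll = -np.inf
    best_parents: np.ndarray | None = None
    best_key: tuple[str, ...] | None = None

    def consider(parents: np.ndarray, ll: float) -> None:
        nonlocal best_ll, best_parents, best_key
        if ll > best_ll + 1e-12:
            best_ll, best_parents, best_key = ll, parents.copy(), None
        elif ll >= best_ll - 1e-12:
            if best_key is None:
                best_key = _tree_from_parents(best_parents, data.variant_ids, vmap).canonical_parent_vector()
            key = _tree_from_parents(parents, data.variant_ids, vmap).canonical_parent_vector()
            if key < best_key:
                best_parents, best_key = parents.copy(), key

    for chain in range(n_chains):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, chain])
        if chain == 0:
            parents = np.full(n, -1, dtype=np.int64)  # star tree
        else:
            parents = _random_tree_parents(n, rng)
        ll = ws.log_likelihood(_expected_genotypes(parents))
        consider(parents, ll)
        for _ in range(n_iter):
            prop = parents.copy()
            if n >= 2 and rng.random() < 0.5:
                i, j = rng.choice(n, size=2, replace=False)
                # label swap = exchange rows i and j of the parent relation
                perm = np.arange(n)
                perm[i], perm[j] = j, i
                remap = np.where(parents >= 0, perm[np.maximum(parents, 0)], -1)
                prop = remap[perm]
            else:
                v = int(rng.integers(n))
                inside = _descendants(parents, v)
                choices = np.flatnonzero(~inside)
                new_parent = int(rng.choice(np.append(choices, -1)))
                prop[v] = new_parent
            ll_prop = ws.log_likelihood(_expected_genotypes(prop))
            if ll_prop >= ll or math.log(rng.random()) < ll_prop - ll:
                parents, ll = prop, ll_prop
                consider(parents, ll)

    tree = _tree_from_parents(best_parents, data.variant_ids, vmap)
    tree.search_log_likelihood = best_ll  # type: ignore[attr-defined]
    vus = [vid for vid, v in vmap.items() if v.status is VariantStatus.VUS and vid in tree.parent]
    for vid in vus:
        tree = tree.contract(vid)
    tree.search_log_likelihood = best_ll  # survives contraction copies
    tree.log_likelihood = tree_log_likelihood(tree, data, err) if tree.nodes else 0.0
    return tree


# ---------------------------------------------------------------------------
# cell attachment
# ---------------------------------------------------------------------------

def attach_cells(tree: MutationTree, data: BinaryMatrix, err: ErrorModel) -> dict[str, str]:
    """Maximum-likelihood attachment node per cell.

    Ties are broken toward the node closest to the root (the root itself
    first), then lexicographically; an all-missing cell therefore attaches
    to the root.
    """
    tree_ids = [vid for vid in data.variant_ids if vid in tree.parent]
    cols = [data.variant_index(v) for v in tree_ids]
    parents = _parents_array(tree, data.variant_ids)
    ws = _LikelihoodWorkspace.build(data.calls[:, cols], tree_ids, err)
    scores = ws.scores(_expected_genotypes(parents))  # (u, n+1)
    node_names = [ROOT] + tree_ids
    depths = np.array([tree.depth(n) for n in node_names])
    # stable preference: (depth, name) with ROOT first
    order = sorted(range(len(node_names)), key=lambda i: (depths[i], i != 0, node_names[i]))
    best_per_row = []
    for u in range(scores.shape[0]):
        row = scores[u]
        mx = row.max()
        best = next(i for i in order if row[i] == mx)
        best_per_row.append(node_names[best])
    return {cell: best_per_row[ws.row_of_cell[i]] for i, cell in enumerate(data.cell_ids)}
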