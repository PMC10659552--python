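"""Cohort-level mutation-order analyses.

Operations over inferred per-patient mutation trees: early/late calls,
pairwise and trio ordering with exact tests, merged cohort graphs
(prefix tries over root sequences), distinct-ordering counts, branching
composition, clone-size and VAF concordance, serial-sample new-event parent
enrichment, and homozygosity summaries.

"Same clone" for two mutations means both lie on one root path of the
inferred tree; events in disjoint branches co-occur in a patient but are
not ordered.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .filtering import compute_mutated_fraction
from .model import ROOT, GenotypeMatrix, MutationTree
from .pathways import Pathway

__all__ = [
    "OrderClass",
    "classify_early_late",
    "pairwise_order_summary",
    "ordered_pair_fraction",
    "trio_order_test",
    "trio_order_summary",
    "merge_trees",
    "count_distinct_orderings",
    "branching_stats",
    "single_mutant_clone_size",
    "vaf_concordance",
    "vaf_proxy_early",
    "serial_new_event_parents",
    "fisher_exact_from_table",
    "homozygous_fraction",
]


class OrderClass(str, Enum):
    EARLY = "EARLY"
    LATE = "LATE"


def classify_early_late(tree: MutationTree) -> dict[str, OrderClass]:
    """EARLY iff no mutation precedes the event (its parent is the root)."""
    return {
        node: OrderClass.EARLY if tree.parent[node] == ROOT else OrderClass.LATE
        for node in tree.nodes
    }


# ---------------------------------------------------------------------------
# pairwise ordering
# ---------------------------------------------------------------------------

def _label_events(tree: MutationTree, level: str) -> dict[str, str]:
    return {node: tree.label(node, level) for node in tree.nodes}


def pairwise_order_summary(
    trees: list[MutationTree],
    level: str = "GENE",
    counting: str = "patient",
) -> pd.DataFrame:
    """Co-occurrence and precedence summary over label pairs.

    For every ordered label pair (g1, g2): ``n_same_patient`` patients with
    both labels; ``n_same_clone`` where some g1/g2 event pair lies on one
    root path; ``n_g1_first``/``n_g2_first`` precedence counts;
    ``binomial_p`` the two-sided exact binomial test of n_g1_first against
    n_g1_first + n_g2_first under p = 1/2. ``counting="patient"`` scores
    each patient at most once per pair and direction; ``counting="event"``
    counts every comparable event pair. Self-pairs (g1 == g2, two distinct
    events of one label) are reported with empty precedence counts.
    """
    if counting not in {"patient", "event"}:
        raise ValueError("counting must be 'patient' or 'event'")
    same_patient: dict[tuple[str, str], int] = {}
    same_clone: dict[tuple[str, str], int] = {}
    first: dict[tuple[str, str], int] = {}

    for tree in trees:
        labels = _label_events(tree, level)
        present = sorted(set(labels.values()))
        clone_pairs: dict[tuple[str, str], int] = {}
        first_pairs: dict[tuple[str, str], int] = {}
        for a, b in itertools.combinations(tree.nodes, 2):
            la, lb = labels[a], labels[b]
            if tree.is_ancestor(a, b):
                anc_label, desc_label = la, lb
            elif tree.is_ancestor(b, a):
                anc_label, desc_label = lb, la
            else:
                continue
            key = tuple(sorted((la, lb)))
            clone_pairs[key] = clone_pairs.get(key, 0) + 1
            if anc_label != desc_label:
                first_pairs[(anc_label, desc_label)] = first_pairs.get((anc_label, desc_label), 0) + 1
        for g1, g2 in itertools.combinations_with_replacement(present, 2):
            if g1 == g2 and sum(1 for v in labels.values() if v == g1) < 2:
                continue
            same_patient[(g1, g2)] = same_patient.get((g1, g2), 0) + 1
        for key, count in clone_pairs.items():
            if key[0] == key[1]:  # self pairs have no direction
                same_clone[key] = same_clone.get(key, 0) + (1 if counting == "patient" else count)
        for key, count in first_pairs.items():
            inc = 1 if counting == "patient" else count
            skey = tuple(sorted(key))
            same_clone[skey] = same_clone.get(skey, 0) + inc
            first[key] = first.get(key, 0) + inc

    rows = []
    keys = set(same_patient) | set(same_clone) | {tuple(sorted(k)) for k in first}
    for g1, g2 in sorted(keys):
        for a, b in ([(g1, g2)] if g1 == g2 else [(g1, g2), (g2, g1)]):
            n1, n2 = first.get((a, b), 0), first.get((b, a), 0)
            if a != b and n1 + n2 > 0:
                p = float(stats.binomtest(n1, n1 + n2, 0.5).pvalue)
            else:
                p = float("nan")
            rows.append(
                {
                    "g1": a,
                    "g2": b,
                    "n_same_patient": same_patient.get(tuple(sorted((a, b))), 0),
                    "n_same_clone": same_clone.get(tuple(sorted((a, b))), 0),
                    "n_g1_first": n1,
                    "n_g2_first": n2,
                    "binomial_p": min(p, 1.0) if p == p else p,
                }
            )
    return pd.DataFrame(rows, columns=["g1", "g2", "n_same_patient", "n_same_clone",
                                       "n_g1_first", "n_g2_first", "binomial_p"])


def ordered_pair_fraction(
    trees: list[MutationTree],
    first_classes: set[Pathway] = frozenset({Pathway.DNA_METHYLATION, Pathway.NPM1}),
    second_class: Pathway = Pathway.SIGNALING,
) -> tuple[float, int]:
    """Fraction of comparable mixed event pairs with the first class ancestral.

    Counts every same-root-path event pair with one event in
    ``first_classes`` and the other in ``second_class``; returns
    (fraction first-class-first, number of comparable pairs).
    """
    n_first = n_total = 0
    for tree in trees:
        for a, b in itertools.combinations(tree.nodes, 2):
            pa, pb = tree.variants[a].pathway, tree.variants[b].pathway
            pair = {pa, pb}
            if not (pair & set(first_classes) and second_class in pair):
                continue
            if pa in first_classes and pb is second_class:
                early, late = a, b
            elif pb in first_classes and pa is second_class:
                early, late = b, a
            else:
                continue
            if tree.is_ancestor(early, late):
                n_first += 1
                n_total += 1
            elif tree.is_ancestor(late, early):
                n_total += 1
    return (n_first / n_total if n_total else float("nan")), n_total


# ---------------------------------------------------------------------------
# trio ordering
# ---------------------------------------------------------------------------

def trio_order_test(counts) -> float:
    """Exact multinomial goodness-of-fit p-value under a uniform null.

    ``counts`` are observed frequencies of the 6 orderings of a trio. The
    p-value is the total probability of all outcome vectors whose
    probability does not exceed the observed vector's. Computed in exact
    integer arithmetic (outcome probability is proportional to its
    multinomial coefficient when cells are equiprobable).
    """
    counts = [int(c) for c in counts]
    if len(counts) != 6 or any(c < 0 for c in counts):
        raise ValueError("counts must be 6 nonnegative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one observation")
    if n > 30:
        raise ValueError("exact multinomial enumeration limited to n <= 30")

    def multinomial_coef(vec) -> int:
        out, rem = 1, n
        for c in vec:
            out *= math.comb(rem, c)
            rem -= c
        return out

    observed = multinomial_coef(counts)
    total = 0
    for composition in _compositions(n, 6):
        coef = multinomial_coef(composition)
        if coef <= observed:
            total += coef
    return total / 6**n


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for head in range(n + 1):
        for tail in _compositions(n - head, k - 1):
            yield (head,) + tail


def trio_order_summary(trees: list[MutationTree], level: str = "GENE", max_n: int = 30) -> pd.DataFrame:
    """Observed ordering counts and exact multinomial p per label trio.

    For each patient, each ordered chain a -> b -> c of three distinct-label
    driver events on one root path contributes its label permutation once
    per patient. Trios with more than ``max_n`` observations are reported
    without a p-value.
    """
    counts: dict[frozenset, dict[tuple, int]] = {}
    for tree in trees:
        labels = _label_events(tree, level)
        seen = set()
        for a, b, c in itertools.permutations(tree.nodes, 3):
            if not (tree.is_ancestor(a, b) and tree.is_ancestor(b, c)):
                continue
            perm = (labels[a], labels[b], labels[c])
            if len(set(perm)) < 3 or perm in seen:
                continue
            seen.add(perm)
            counts.setdefault(frozenset(perm), {}).setdefault(perm, 0)
            counts[frozenset(perm)][perm] += 1
    rows = []
    for trio, perm_counts in counts.items():
        members = sorted(trio)
        perms = list(itertools.permutations(members))
        vec = [perm_counts.get(p, 0) for p in perms]
        n = sum(vec)
        p = trio_order_test(vec) if 1 <= n <= max_n else float("nan")
        rows.append({"trio": "|".join(members), "n": n, "multinomial_p": p,
                     **{"->".join(p_): c for p_, c in zip(perms, vec)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# merged cohort graphs and ordering counts
# ---------------------------------------------------------------------------

def merge_trees(trees: list[MutationTree], level: str = "GENE", min_count: int = 1) -> nx.DiGraph:
    """Prefix trie of root sequences with per-key patient counts.

    Node keys are the exact label sequences from the root; a node's weight
    counts the patients whose tree contains that root sequence. Keys seen
    fewer than ``min_count`` times are dropped (with their descendants; the
    result stays prefix-closed because a prefix is at least as frequent as
    its extensions).
    """
    counts: dict[tuple, int] = {}
    for tree in trees:
        labels = _label_events(tree, level)
        keys = {tuple(labels[v] for v in tree.root_path(node)) for node in tree.nodes}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
    graph = nx.DiGraph()
    graph.add_node((), count=len(trees), label="ROOT")
    for key in sorted(counts, key=len):
        if counts[key] < min_count:
            continue
        if key[:-1] not in graph.nodes:
            continue  # parent dropped -> drop children too
        graph.add_node(key, count=counts[key], label=key[-1])
        graph.add_edge(key[:-1], key, count=counts[key])
    return graph


def count_distinct_orderings(trees: list[MutationTree], level: str = "GENE") -> int:
    """Number of distinct maximal root-to-leaf label sequences in the cohort.

    Sequences that are strict prefixes of another collected sequence are
    indistinct from it and not counted separately.
    """
    sequences: set[tuple] = set()
    for tree in trees:
        labels = _label_events(tree, level)
        for leaf in tree.leaves():
            sequences.add(tuple(labels[v] for v in tree.root_path(leaf)))
    maximal = {
        s for s in sequences
        if not any(t != s and t[: len(s)] == s for t in sequences)
    }
    return len(maximal)


@dataclass
class BranchingStats:
    n_branch_points: int
    post_branch_pathway_fraction: pd.Series        # pathway -> fraction of post-branch events
    branch_point_genes: pd.Series                  # gene -> times a node of that gene branches
    signaling_child_rate: pd.DataFrame             # per gene: branching vs non-branching nodes


def branching_stats(trees: list[MutationTree], include_root: bool = True) -> BranchingStats:
    """Composition of events immediately following branch points.

    A branch point is a node (optionally including the root) with
    out-degree >= 2; post-branch events are its children. Also reports, per
    gene, the fraction of children that are signaling events, stratified by
    whether the node branches.
    """
    post_branch: list[str] = []
    branch_genes: dict[str, int] = {}
    child_rows: list[dict] = []
    n_branch = 0
    for tree in trees:
        kids = tree.children_map()
        for node, children in kids.items():
            if node == ROOT and not include_root:
                continue
            if node != ROOT:
                gene = tree.variants[node].gene
                n_signaling = sum(
                    1 for c in children if tree.variants[c].pathway is Pathway.SIGNALING
                )
                if children:
                    child_rows.append(
                        {
                            "gene": gene,
                            "branches": len(children) >= 2,
                            "n_children": len(children),
                            "n_signaling_children": n_signaling,
                        }
                    )
            if len(children) >= 2:
                n_branch += 1
                if node != ROOT:
                    gene = tree.variants[node].gene
                    branch_genes[gene] = branch_genes.get(gene, 0) + 1
                post_branch.extend(tree.variants[c].pathway.value for c in children)
    if post_branch:
        comp = pd.Series(post_branch).value_counts(normalize=True).sort_index()
    else:
        comp = pd.Series(dtype=float)
    if child_rows:
        df = pd.DataFrame(child_rows)
        rate = (
            df.groupby(["gene", "branches"])[["n_children", "n_signaling_children"]]
            .sum()
            .assign(signaling_fraction=lambda d: d["n_signaling_children"] / d["n_children"])
            .reset_index()
        )
    else:
        rate = pd.DataFrame(columns=["gene", "branches", "n_children",
                                     "n_signaling_children", "signaling_fraction"])
    return BranchingStats(
        n_branch_points=n_branch,
        post_branch_pathway_fraction=comp,
        branch_point_genes=pd.Series(branch_genes, dtype=int).sort_index(),
        signaling_child_rate=rate,
    )


# ---------------------------------------------------------------------------
# clone sizes, VAF concordance, homozygosity
# ---------------------------------------------------------------------------

def single_mutant_clone_size(matrix: GenotypeMatrix, first_variant: str, second_variant: str) -> float:
    """Mutated-fraction difference between an earlier and a later mutation.

    Each fraction uses its own called-cell denominator; the difference
    proxies the clone carrying only the earlier mutation and may be
    negative under noise (reported as-is).
    """
    f1, _, _ = compute_mutated_fraction(matrix, first_variant)
    f2, _, _ = compute_mutated_fraction(matrix, second_variant)
    return f1 - f2


@dataclass
class ConcordanceResult:
    r: float
    n: int
    defined: bool


def vaf_concordance(pairs: list[tuple[float, float]]) -> ConcordanceResult:
    """Pearson correlation between delta-VAF and delta cell fraction.

    ``pairs`` holds (delta VAF, delta mutated-cell fraction) for same-root-
    path variant pairs. Requires >= 3 pairs; zero variance in either
    coordinate yields an undefined (flagged) result.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        return ConcordanceResult(float("nan"), len(pairs), False)
    r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(r, len(pairs), True)


def vaf_proxy_early(vaf: float, cutoff: float = 0.3) -> OrderClass:
    """Bulk-VAF proxy for mutation order: EARLY iff VAF >= cutoff."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"VAF must lie in [0, 1], got {vaf}")
    return OrderClass.EARLY if vaf >= cutoff else OrderClass.LATE


def homozygous_fraction(matrix: GenotypeMatrix, variant_id: str) -> float:
    """Fraction of mutant cells called homozygous (code 2 / codes {1, 2}).

    NaN when the variant has no mutant cells.
    """
    col = matrix.column(variant_id)
    n_mut = int(((col == 1) | (col == 2)).sum())
    if n_mut == 0:
        return float("nan")
    return int((col == 2).sum()) / n_mut


# ---------------------------------------------------------------------------
# serial samples
# ---------------------------------------------------------------------------

@dataclass
class SerialParentResult:
    new_events: list[str]
    parents: dict[str, str]                      # new event -> parent node (ROOT = none)
    table: np.ndarray | None                     # 2x2 contingency table
    fisher_p: float | None


def fisher_exact_from_table(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tails)."""
    return float(stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")[1])


def serial_new_event_parents(
    merged_tree: MutationTree,
    earlier_variant_ids: set[str],
    parent_classes: set[Pathway] = frozenset({Pathway.NPM1, Pathway.DNA_METHYLATION}),
    new_event_class: Pathway = Pathway.SIGNALING,
) -> SerialParentResult:
    """Parent-node enrichment for events newly gained at a later timepoint.

    New events are merged-tree nodes absent from the earlier sample's
    variant set. Each new event of ``new_event_class`` contributes its
    parent node (the root counts as "no prior mutation"). Available nodes
    are every node of the earlier tree plus the root. The 2x2 table crosses
    parent class (NPM1-or-DNA-methylation vs other incl. root) with role
    (parent of a new signaling event vs other available node); the p-value
    is the two-sided Fisher exact test. With no new signaling events the
    result carries no table or test.
    """
    new_events = [n for n in merged_tree.nodes if n not in earlier_variant_ids]
    parents = {n: merged_tree.parent[n] for n in new_events}
    new_signaling = [
        n for n in new_events if merged_tree.variants[n].pathway is new_event_class
    ]
    if not new_signaling:
        return SerialParentResult(new_events, parents, None, None)

    def in_class(node: str) -> bool:
        if node == ROOT:
            return False
        return merged_tree.variants[node].pathway in parent_classes

    available = [ROOT] + [n for n in merged_tree.nodes if n in earlier_variant_ids]
    parent_nodes = [parents[n] for n in new_signaling]
    used = set(parent_nodes)
    k_class = sum(1 for p in parent_nodes if in_class(p))
    k_other = len(parent_nodes) - k_class
    rest = [n for n in available if n not in used]
    r_class = sum(1 for n in rest if in_class(n))
    r_other = len(rest) - r_class
    table = np.array([[k_class, r_class], [k_other, r_other]], dtype=int)
    return SerialParentResult(new_events, parents, table, fisher_exact_from_table(table))
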