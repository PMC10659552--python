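"""Tree validation and cleaning: cell support, low-support pruning, ITD merging.

Cell support for an ordered ancestor-descendant pair (a, b) on one root
path is the fraction of b-mutant cells that also carry a, among b-mutant
cells with a non-missing call for a. Pairs with support below 50% are
low-support; variants contributing to many low-support pairs (breaking
ties toward more distal nodes) are removed greedily. Multiple FLT3-ITD
records that plausibly describe one biological insertion event are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import MAX_EXACT_VARIANTS, enumerate_trees_exact, infer_tree_mcmc
from .model import BinaryMatrix, ErrorModel, MutationTree, Variant, VariantClass, VariantStatus

logger = logging.getLogger(__name__)

__all__ = [
    "compute_cell_support",
    "flag_low_support",
    "prune_low_support_variants",
    "merge_itds",
]

LOW_SUPPORT_THRESHOLD = 0.5


def compute_cell_support(data: BinaryMatrix, tree: MutationTree) -> pd.DataFrame:
    """Support table over same-root-path ordered driver pairs.

    Columns: ancestor, descendant, n_informative (descendant-mutant cells
    with a call for the ancestor), n_both, support, defined. Pairs with a
    zero denominator have support NaN and defined=False.
    """
    vmap = data.variant_map()
    drivers = [n for n in tree.nodes
               if n not in vmap or vmap[n].status is not VariantStatus.VUS]
    rows = []
    for b in drivers:
        path = tree.root_path(b)[:-1]  # strict ancestors, root-most first
        if not path:
            continue
        col_b = data.column(b)
        b_mut = col_b == 1
        for a in path:
            if a not in drivers:
                continue
            col_a = data.column(a)
            informative = b_mut & (col_a != 3)
            n_info = int(informative.sum())
            n_both = int((informative & (col_a == 1)).sum())
            support = n_both / n_info if n_info else float("nan")
            rows.append(
                {
                    "ancestor": a,
                    "descendant": b,
                    "n_informative": n_info,
                    "n_both": n_both,
                    "support": support,
                    "defined": n_info > 0,
                }
            )
    return pd.DataFrame(rows, columns=["ancestor", "descendant", "n_informative",
                                       "n_both", "support", "defined"])


def flag_low_support(table: pd.DataFrame, threshold: float = LOW_SUPPORT_THRESHOLD) -> pd.DataFrame:
    """Add a ``low_support`` flag: support strictly below threshold.

    Undefined supports (no informative cells) are flagged low.
    """
    table = table.copy()
    if table.empty:
        table["low_support"] = pd.Series(dtype=bool)
        return table
    table["low_support"] = (~table["defined"].astype(bool)) | (table["support"] < threshold)
    return table


def prune_low_support_variants(
    tree: MutationTree,
    table: pd.DataFrame,
    data: BinaryMatrix,
    threshold: float = LOW_SUPPORT_THRESHOLD,
) -> tuple[MutationTree, list[str]]:
    """Iteratively remove the variant most implicated in low-support pairs.

    Score per variant: (number of low-support pairs it appears in, root
    distance, variant_id); the maximum count wins, ties broken toward the
    more distal node, then lexicographically smallest id. The node is
    contracted (children reattach to its parent), supports are recomputed,
    and the loop repeats until no low-support pair remains. Terminates in at
    most n_variants iterations and never removes the root.
    """
    tree = tree.copy()
    removed: list[str] = []
    if "low_support" not in table.columns:
        table = flag_low_support(table, threshold)
    while True:
        low = table[table["low_support"]] if not table.empty else table
        if low.empty:
            break
        counts: dict[str, int] = {}
        for _, row in low.iterrows():
            counts[row["ancestor"]] = counts.get(row["ancestor"], 0) + 1
            counts[row["descendant"]] = counts.get(row["descendant"], 0) + 1
        victim = min(counts, key=lambda v: (-counts[v], -tree.depth(v), v))
        removed.append(victim)
        tree = tree.contract(victim)
        if not tree.nodes:
            logger.warning("pruning removed every variant; returning root-only tree")
            break
        table = flag_low_support(compute_cell_support(data, tree), threshold)
    return tree, removed


# ---------------------------------------------------------------------------
# FLT3-ITD merging
# ---------------------------------------------------------------------------

@dataclass
class ItdMergeResult:
    variants: list[Variant]          # surviving variant set (merged representatives)
    tree: MutationTree | None        # re-inferred tree (None when no tree given)
    data: BinaryMatrix | None        # matrix with merged columns
    log: list[dict] = field(default_factory=list)


def _is_substring(short: str, long: str, contiguous: bool = True) -> bool:
    if contiguous:
        return short in long
    it = iter(long)
    return all(ch in it for ch in short)


def _merge_columns(data: BinaryMatrix, member_ids: list[str], rep_id: str) -> BinaryMatrix:
    """Union-merge member columns into the representative's column.

    The merged call is 1 if any member is mutant, 3 only if all members are
    missing, else 0.
    """
    cols = np.stack([data.column(m) for m in member_ids], axis=1)
    merged = np.where((cols == 1).any(axis=1), 1, np.where((cols == 3).all(axis=1), 3, 0)).astype(np.int8)
    keep = [i for i, v in enumerate(data.variants) if v.variant_id not in member_ids or v.variant_id == rep_id]
    variants = [data.variants[i] for i in keep]
    calls = data.calls[:, keep].copy()
    rep_pos = [v.variant_id for v in variants].index(rep_id)
    calls[:, rep_pos] = merged
    vus_mask = data.vus_mask[keep]
    return BinaryMatrix(list(data.cell_ids), variants, calls, vus_mask)


def _reinfer(data: BinaryMatrix, err: ErrorModel, seed: int) -> MutationTree:
    if len(data.variants) <= MAX_EXACT_VARIANTS:
        tree, _ = enumerate_trees_exact(data, err)
        return tree
    return infer_tree_mcmc(data, err, seed=seed)


def _itd_low_support_pairs(tree: MutationTree, data: BinaryMatrix, itd_ids: set[str]) -> int:
    table = flag_low_support(compute_cell_support(data, tree))
    if table.empty:
        return 0
    low = table[table["low_support"]]
    return int((low["ancestor"].isin(itd_ids) | low["descendant"].isin(itd_ids)).sum())


def merge_itds(
    variants: list[Variant],
    tree: MutationTree | None = None,
    data: BinaryMatrix | None = None,
    err: ErrorModel | None = None,
    contiguous: bool = True,
    seed: int = 0,
) -> ItdMergeResult:
    """Merge ITD variants that likely represent one insertion event.

    Three rules, applied in order:

    R1 — same start locus and every insertion a (contiguous) substring of
    the group's longest insertion: merge.
    R2 — all remaining ITDs are terminal (leaf) children of one common
    parent node in the tree: merge.
    R3 — the unmerged tree has at least one low-support pair involving an
    ITD and the re-inferred fully merged tree has none: merge.

    Merged genotype = union over member columns (1 if any member mutant, 3
    only if all missing); the representative is the member with the longest
    insertion. When ``tree``/``data`` are given, the tree is re-inferred on
    the merged matrix. The operation is idempotent.
    """
    non_itd = [v.variant_id for v in variants if v.variant_class is not VariantClass.ITD]
    if non_itd:
        raise ValueError(f"non-ITD variant(s) passed to merge_itds: {non_itd}")
    err = err or ErrorModel()
    log: list[dict] = []
    current = list(variants)

    def do_merge(members: list[Variant], rule: str):
        nonlocal current, data, tree
        rep = max(members, key=lambda v: (len(v.alt), v.variant_id))
        member_ids = [v.variant_id for v in members]
        log.append({"rule": rule, "members": member_ids, "representative": rep.variant_id})
        current = [v for v in current if v.variant_id not in member_ids] + [rep]
        if data is not None:
            data = _merge_columns(data, member_ids, rep.variant_id)

    # R1: same locus, substrings of the longest
    changed = True
    while changed:
        changed = False
        by_locus: dict[tuple[str, int], list[Variant]] = {}
        for v in current:
            by_locus.setdefault((v.chrom, v.pos), []).append(v)
        for group in by_locus.values():
            if len(group) < 2:
                continue
            longest = max(group, key=lambda v: (len(v.alt), v.variant_id))
            members = [v for v in group if _is_substring(v.alt, longest.alt, contiguous)]
            if len(members) >= 2:
                do_merge(members, "R1")
                changed = True
                break

    if tree is not None and data is not None:
        if log:  # structure changed; the provided tree references merged-away ids
            tree = _reinfer(data, err, seed)

        # R2: all remaining ITDs are leaves under one common parent
        remaining = [v for v in current if v.variant_id in tree.parent]
        if len(remaining) >= 2:
            kids = tree.children_map()
            leaves = all(not kids[v.variant_id] for v in remaining)
            parents = {tree.parent[v.variant_id] for v in remaining}
            if leaves and len(parents) == 1:
                do_merge(remaining, "R2")
                tree = _reinfer(data, err, seed)

        # R3: merging removes ITD-involving low-support pairs
        remaining = [v for v in current if v.variant_id in tree.parent]
        if len(remaining) >= 2:
            before = _itd_low_support_pairs(tree, data, {v.variant_id for v in remaining})
            if before >= 1:
                rep = max(remaining, key=lambda v: (len(v.alt), v.variant_id))
                member_ids = [v.variant_id for v in remaining]
                trial_data = _merge_columns(data, member_ids, rep.variant_id)
                trial_tree = _reinfer(trial_data, err, seed)
                after = _itd_low_support_pairs(trial_tree, trial_data, {rep.variant_id})
                if after == 0:
                    do_merge(remaining, "R3")
                    tree = _reinfer(data, err, seed)

    return ItdMergeResult(variants=current, tree=tree, data=data, log=log)
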