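"""Core domain types for single-cell mutation-tree analysis.

Genotype calls use the SCITE convention: 0 = wildtype, 1 = heterozygous
mutant, 2 = homozygous mutant (hom-or-LOH; upstream callers do not
distinguish), 3 = missing. Genomic coordinates are 1-based; strand is
ignored (targeted amplicon panels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np

from .pathways import Pathway, pathway_of

#: Genotype / binary codes
WILDTYPE, HET, HOM, MISSING = 0, 1, 2, 3

#: Sentinel label for the wildtype root of a mutation tree.
ROOT = "ROOT"


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    ITD = "ITD"


class VariantStatus(str, Enum):
    DRIVER = "DRIVER"
    VUS = "VUS"
    EXCLUDED = "EXCLUDED"


class Timepoint(str, Enum):
    DIAGNOSIS = "DIAGNOSIS"
    REMISSION = "REMISSION"
    RELAPSE = "RELAPSE"
    OTHER = "OTHER"


class FormatError(ValueError):
    """Raised when an on-disk file violates the documented format."""


@dataclass
class Variant:
    """A single mutation event on the targeted panel.

    ``alt`` carries the full insertion sequence for ITD variants; ``pathway``
    is derived from ``gene`` via the configured mapping when not given.
    """

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass = VariantClass.SNV
    protein_change: str | None = None
    status: VariantStatus = VariantStatus.DRIVER
    pathway: Pathway | None = None

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        self.status = VariantStatus(self.status)
        if int(self.pos) < 1:
            raise ValueError(f"{self.variant_id}: pos must be 1-based positive")
        self.pos = int(self.pos)
        if self.variant_class is VariantClass.ITD and not self.alt:
            raise ValueError(f"{self.variant_id}: ITD requires a non-empty insertion sequence")
        if self.pathway is None:
            self.pathway = pathway_of(self.gene)
        else:
            self.pathway = Pathway(self.pathway)


@dataclass
class ErrorModel:
    """Global per-patient genotyping error rates.

    alpha: false-positive rate P(observed mutant | true wildtype).
    beta:  false-negative (allele-dropout) rate P(observed wildtype | true mutant).
    """

    alpha: float = 0.01
    beta: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0) or not (0.0 <= self.beta < 1.0):
            raise ValueError("alpha and beta must lie in [0, 1)")
        if self.alpha + self.beta >= 1.0:
            raise ValueError("alpha + beta must be < 1")


def _validate_calls(calls: np.ndarray, n_cells: int, n_variants: int, allowed: set[int]) -> np.ndarray:
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape != (n_cells, n_variants):
        raise ValueError(f"calls shape {calls.shape} != ({n_cells}, {n_variants})")
    bad = set(np.unique(calls).tolist()) - allowed
    if bad:
        raise ValueError(f"invalid genotype codes {sorted(bad)}; allowed {sorted(allowed)}")
    return calls


@dataclass
class GenotypeMatrix:
    """cells x variants coded genotype calls for one sample."""

    cell_ids: list[str]
    variants: list[Variant]
    calls: np.ndarray
    sample_id: str = "sample"
    timepoint: Timepoint = Timepoint.DIAGNOSIS
    timepoint_index: int = 0
    n_coerced: int = 0  # unparseable entries coerced to MISSING at read time

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant_ids")
        self.calls = _validate_calls(self.calls, len(self.cell_ids), len(self.variants), {0, 1, 2, 3})

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant_id {variant_id!r} in sample {self.sample_id!r}") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.calls[:, self.variant_index(variant_id)]


@dataclass
class BinaryMatrix:
    """Binarized mutation matrix: 0 = absent, 1 = present, 3 = missing.

    ``vus_mask[j]`` marks variants used only to inform tree architecture
    (variants of unknown significance); they are dropped from downstream
    order inference.
    """

    cell_ids: list[str]
    variants: list[Variant]
    calls: np.ndarray
    vus_mask: np.ndarray

    def __post_init__(self) -> None:
        self.calls = _validate_calls(self.calls, len(self.cell_ids), len(self.variants), {0, 1, 3})
        self.vus_mask = np.asarray(self.vus_mask, dtype=bool)
        if self.vus_mask.shape != (len(self.variants),):
            raise ValueError("vus_mask length must equal number of variants")

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant_id {variant_id!r}") from None

    def column(self, variant_id: str) -> np.ndarray:
        return self.calls[:, self.variant_index(variant_id)]

    def variant_map(self) -> dict[str, Variant]:
        return {v.variant_id: v for v in self.variants}


@dataclass
class PatientDataset:
    """All samples for one patient, plus optional paired bulk VAFs.

    ``bulk_vafs`` maps ``(sample_id, variant_id) -> VAF in [0, 1]``.
    """

    patient_id: str
    samples: list[GenotypeMatrix]
    bulk_vafs: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        meta: dict[str, tuple] = {}
        for sample in self.samples:
            for v in sample.variants:
                key = (v.gene, v.chrom, v.pos, v.ref, v.alt)
                if meta.setdefault(v.variant_id, key) != key:
                    raise ValueError(
                        f"conflicting metadata for variant_id {v.variant_id!r} across samples"
                    )
        if self.bulk_vafs:
            for (sid, vid), vaf in self.bulk_vafs.items():
                if not (0.0 <= vaf <= 1.0):
                    raise ValueError(f"VAF out of range for ({sid}, {vid}): {vaf}")


class MutationTree:
    """Rooted tree of mutation events; the root is the wildtype state.

    Under the infinite-sites assumption each mutation event appears exactly
    once and never reverts, so the tree's parent map fully encodes mutation
    order: the mutations on the path root -> node define that node's clone.
    """

    def __init__(
        self,
        parent: Mapping[str, str],
        variants: Mapping[str, Variant] | None = None,
        log_likelihood: float | None = None,
        attachment: Mapping[str, str] | None = None,
    ) -> None:
        self.parent: dict[str, str] = dict(parent)
        self.variants: dict[str, Variant] = dict(variants or {})
        self.log_likelihood = log_likelihood
        self.attachment: dict[str, str] | None = dict(attachment) if attachment is not None else None
        self._validate()

    # -- construction / validation -------------------------------------------------
    def _validate(self) -> None:
        if ROOT in self.parent:
            raise ValueError("the root has no parent entry")
        for node, par in self.parent.items():
            if par != ROOT and par not in self.parent:
                raise ValueError(f"parent {par!r} of {node!r} is not a node")
        # acyclicity: walk each node to the root
        for node in self.parent:
            seen = {node}
            cur = node
            while cur != ROOT:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError(f"cycle involving node {node!r}")
                seen.add(cur)

    # -- basic structure -----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        """Mutation nodes (excluding the root), in insertion order."""
        return list(self.parent)

    def __contains__(self, node: str) -> bool:
        return node in self.parent

    def children(self, node: str) -> list[str]:
        return [n for n, p in self.parent.items() if p == node]

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {ROOT: []}
        for n in self.parent:
            out[n] = []
        for n, p in self.parent.items():
            out[p].append(n)
        return out

    def root_path(self, node: str) -> list[str]:
        """Mutations on the path root -> node, root-most first (node included)."""
        path = []
        cur = node
        while cur != ROOT:
            path.append(cur)
            cur = self.parent[cur]
        return path[::-1]

    def depth(self, node: str) -> int:
        return 0 if node == ROOT else len(self.root_path(node))

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict ancestor of ``b`` (root is ancestor of all)."""
        if a == b:
            return False
        if a == ROOT:
            return True
        cur = b
        while cur != ROOT:
            cur = self.parent[cur]
            if cur == a:
                return True
        return False

    def on_same_path(self, a: str, b: str) -> bool:
        return self.is_ancestor(a, b) or self.is_ancestor(b, a)

    def subtree(self, node: str) -> set[str]:
        """``node`` and all of its descendants."""
        kids = self.children_map()
        out: set[str] = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(kids.get(cur, []))
        return out

    def edges(self) -> list[tuple[str, str]]:
        return [(p, n) for n, p in self.parent.items()]

    def leaves(self) -> list[str]:
        kids = self.children_map()
        return [n for n in self.parent if not kids[n]]

    # -- editing -------------------------------------------------------------------
    def copy(self) -> "MutationTree":
        return MutationTree(self.parent, self.variants, self.log_likelihood, self.attachment)

    def contract(self, node: str) -> "MutationTree":
        """Remove ``node``, reattaching its children to its parent."""
        if node not in self.parent:
            raise KeyError(node)
        par = self.parent[node]
        new_parent = {}
        for n, p in self.parent.items():
            if n == node:
                continue
            new_parent[n] = par if p == node else p
        new_variants = {k: v for k, v in self.variants.items() if k != node}
        return MutationTree(new_parent, new_variants)

    def restrict(self, keep: Iterable[str]) -> "MutationTree":
        """Contract away every node not in ``keep``."""
        keep = set(keep)
        tree = self
        for node in [n for n in self.parent if n not in keep]:
            tree = tree.contract(node)
        return tree

    # -- canonical form ------------------------------------------------------------
    def canonical_parent_vector(self) -> tuple[str, ...]:
        """Parents listed in sorted-node order, with the root encoded as ''."""
        return tuple("" if self.parent[n] == ROOT else self.parent[n] for n in sorted(self.parent))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MutationTree) and self.parent == other.parent

    def __repr__(self) -> str:
        return f"MutationTree({len(self.parent)} mutations, ll={self.log_likelihood})"

    # -- labels --------------------------------------------------------------------
    def label(self, node: str, level: str = "GENE") -> str:
        """Gene or pathway label of a node (used for cohort summaries)."""
        v = self.variants.get(node)
        if v is None:
            raise KeyError(f"no Variant metadata for node {node!r}")
        if level.upper() == "GENE":
            return v.gene
        if level.upper() == "PATHWAY":
            return v.pathway.value
        raise ValueError(f"unknown level {level!r}")


def linear_tree(variant_ids: Iterable[str], variants: Mapping[str, Variant] | None = None) -> MutationTree:
    """Chain root -> v1 -> v2 -> ... (convenience constructor)."""
    parent = {}
    prev = ROOT
    for vid in variant_ids:
        parent[vid] = prev
        prev = vid
    return MutationTree(parent, variants)
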