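"""Readers and writers for genotype matrices, variant metadata and trees.

On-disk formats (all plain text):

* genotype matrix — TSV/CSV; header row of variant_ids with a leading
  ``cell_id`` column; body cells are integer codes 0/1/2/3. Unparseable
  codes are coerced to 3 (missing) and counted in a logged warning.
* variant metadata — TSV with columns variant_id, gene, chrom, pos, ref,
  alt, class, status and optional protein_change, pathway.
* trees — GraphML (round-trippable) and DOT (write-only).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    ROOT,
    FormatError,
    GenotypeMatrix,
    MutationTree,
    Timepoint,
    Variant,
    VariantClass,
    VariantStatus,
)

logger = logging.getLogger(__name__)

_VALID_CODES = {"0", "1", "2", "3"}


def read_genotype_matrix(
    path: str | Path,
    sep: str | None = None,
    sample_id: str | None = None,
    variants: list[Variant] | None = None,
    timepoint: Timepoint | str = Timepoint.DIAGNOSIS,
    timepoint_index: int = 0,
) -> GenotypeMatrix:
    """Read a cells x variants genotype matrix from TSV/CSV.

    ``sep=None`` infers the delimiter from the extension (.csv -> comma,
    otherwise tab). When ``variants`` is omitted, minimal placeholder
    metadata is attached (gene/locus unknown); pass the variant table for
    full annotations. Unparseable codes become 3 (missing) and the total is
    logged and stored on the returned matrix as ``n_coerced``.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a cell_id column plus >=1 variant column")
    header = list(df.columns)
    if header[0].lower() not in {"cell_id", "cell", "barcode"}:
        raise FormatError(f"{path}: first header field must be 'cell_id', got {header[0]!r}")
    variant_ids = header[1:]
    dup_cols = {c for c in variant_ids if variant_ids.count(c) > 1}
    if dup_cols:
        raise FormatError(f"{path}: duplicate variant column(s) {sorted(dup_cols)}")
    cell_ids = df.iloc[:, 0].tolist()
    dup = pd.Series(cell_ids)[pd.Series(cell_ids).duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate cell_id(s) {sorted(set(dup))}")

    raw = df.iloc[:, 1:].to_numpy(dtype=str)
    ok = np.isin(raw, sorted(_VALID_CODES))
    n_coerced = int((~ok).sum())
    if n_coerced:
        logger.warning("%s: coerced %d unparseable genotype code(s) to missing", path, n_coerced)
    calls = np.where(ok, raw, "3").astype(np.int8)

    if variants is None:
        variants = [
            Variant(vid, gene=vid.split("_")[0], chrom="NA", pos=1, ref="N", alt="N")
            for vid in variant_ids
        ]
    else:
        by_id = {v.variant_id: v for v in variants}
        missing = [vid for vid in variant_ids if vid not in by_id]
        if missing:
            raise FormatError(f"{path}: variant metadata missing for column(s) {missing}")
        variants = [by_id[vid] for vid in variant_ids]

    return GenotypeMatrix(
        cell_ids=cell_ids,
        variants=variants,
        calls=calls,
        sample_id=sample_id or path.stem,
        timepoint=Timepoint(timepoint),
        timepoint_index=timepoint_index,
        n_coerced=n_coerced,
    )


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(matrix.calls, index=matrix.cell_ids, columns=matrix.variant_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def read_variant_table(path: str | Path, sep: str = "\t") -> list[Variant]:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"variant_id", "gene", "chrom", "pos", "ref", "alt", "class", "status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Variant(
                variant_id=row["variant_id"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_class=VariantClass(row["class"]),
                protein_change=(row.get("protein_change") or None),
                status=VariantStatus(row["status"]),
                pathway=(row["pathway"] if "pathway" in df.columns and row["pathway"] else None),
            )
        )
    return out


def write_variant_table(variants: list[Variant], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "class": v.variant_class.value,
            "status": v.status.value,
            "protein_change": v.protein_change or "",
            "pathway": v.pathway.value,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def tree_to_digraph(tree: MutationTree) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_node(ROOT, variant_id=ROOT, gene="", pathway="")
    for node in tree.nodes:
        v = tree.variants.get(node)
        g.add_node(
            node,
            variant_id=node,
            gene=v.gene if v else "",
            pathway=v.pathway.value if v else "",
        )
    for parent, child in tree.edges():
        g.add_edge(parent, child)
    return g


def write_tree(tree: MutationTree, path: str | Path, format: str = "GRAPHML") -> None:
    """Write a tree as GraphML or DOT with variant_id/gene/pathway attributes."""
    fmt = format.upper()
    path = Path(path)
    g = tree_to_digraph(tree)
    if fmt == "GRAPHML":
        nx.write_graphml(g, path)
    elif fmt == "DOT":
        lines = ["digraph mutation_tree {"]
        for node, attrs in g.nodes(data=True):
            label = node if node == ROOT else f"{attrs['gene']}\\n{node}"
            lines.append(f'  "{node}" [label="{label}" gene="{attrs["gene"]}" pathway="{attrs["pathway"]}"];')
        for a, b in g.edges():
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown tree format {format!r} (use GRAPHML or DOT)")


def read_tree(path: str | Path, variants: list[Variant] | None = None) -> MutationTree:
    """Read a GraphML mutation tree written by :func:`write_tree`."""
    g = nx.read_graphml(Path(path))
    parent: dict[str, str] = {}
    for a, b in g.edges():
        parent[str(b)] = str(a)
    if ROOT not in g.nodes:
        raise FormatError(f"{path}: tree has no {ROOT} node")
    vmap = {v.variant_id: v for v in variants} if variants else {}
    tree_variants = {}
    for node, attrs in g.nodes(data=True):
        node = str(node)
        if node == ROOT:
            continue
        if node in vmap:
            tree_variants[node] = vmap[node]
        elif attrs.get("gene"):
            tree_variants[node] = Variant(
                node, gene=attrs["gene"], chrom="NA", pos=1, ref="N", alt="N",
                pathway=attrs.get("pathway") or None,
            )
    return MutationTree(parent, tree_variants)
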