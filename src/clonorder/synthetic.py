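"""Synthetic single-cell AML cohorts with known ground truth.

Emulates Tapestri-style targeted-panel scDNAseq: per patient, a ground-truth
mutation tree over panel genes, clone frequencies (symmetric Dirichlet over
all tree nodes including the wildtype root, so samples contain non-leukemic
cells), per-cell genotypes corrupted by false positives (alpha), allele
dropout (beta), hom-or-LOH upgrades and missing calls, paired bulk VAFs, and
artifactual fragmentation of FLT3-ITD insertions. Doublets, amplicon bias
and copy number are not simulated.

Seeding: a single cohort-level seed is split per patient by counter
(``SeedSequence(seed).spawn``-style keys), so per-patient output is stable
under cohort-size changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model import (
    ROOT,
    ErrorModel,
    GenotypeMatrix,
    MutationTree,
    PatientDataset,
    Timepoint,
    Variant,
    VariantClass,
)
from .pathways import Pathway, default_pathway_map

__all__ = [
    "SimConfig",
    "sample_random_tree",
    "simulate_genotype_matrix",
    "simulate_bulk_vaf",
    "simulate_serial_pair",
    "fragment_itd",
    "simulate_cohort",
]

#: canonical FLT3-ITD locus (chr13, exon 14) used for simulated ITDs
ITD_CHROM, ITD_POS = "13", 28608251

#: pathway classes biased to occur before signaling events
EARLY_CLASSES = frozenset({Pathway.DNA_METHYLATION, Pathway.NPM1})


def _default_gene_pool() -> dict[Pathway, list[str]]:
    pool: dict[Pathway, list[str]] = {}
    for gene, pw in default_pathway_map().items():
        pool.setdefault(pw, []).append(gene)
    return pool


@dataclass
class SimConfig:
    """Cohort-level simulation parameters (the study conditions).

    Defaults describe a desk-scale analogue of a multi-site targeted-panel
    AML cohort: 2-6 driver events per patient, mostly-linear trees with
    occasional branching, a few hundred cells per sample, and error rates in
    the range reported for single-cell DNA panels.
    """

    n_patients: int = 50
    n_mutations_range: tuple[int, int] = (2, 6)
    branching_prob: float = 0.2
    clone_freq_concentration: float = 1.0
    n_cells: int = 300
    alpha: float = 0.01
    beta: float = 0.2
    missing_rate: float = 0.1
    hom_rate: float = 0.05
    gene_pool: dict[Pathway, list[str]] = field(default_factory=_default_gene_pool)
    order_bias: float = 0.85
    itd_fragmentation: tuple[float, int] = (0.2, 3)
    bulk_depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("branching_prob", "alpha", "beta", "missing_rate", "hom_rate", "order_bias"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.clone_freq_concentration <= 0:
            raise ValueError("clone_freq_concentration must be positive")
        lo, hi = self.n_mutations_range
        if not (1 <= lo <= hi):
            raise ValueError("n_mutations_range must satisfy 1 <= min <= max")
        frag_p, frag_max = self.itd_fragmentation
        if not (0.0 <= frag_p <= 1.0) or frag_max < 1:
            raise ValueError("itd_fragmentation must be (probability, max_fragments >= 1)")
        self.gene_pool = {Pathway(k): list(v) for k, v in self.gene_pool.items()}
        for pw, genes in self.gene_pool.items():
            if not genes:
                raise ValueError(f"empty gene pool for pathway {pw.value}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "gene_pool" in raw:
            raw["gene_pool"] = {Pathway(k): list(v) for k, v in raw["gene_pool"].items()}
        for key in ("n_mutations_range", "itd_fragmentation"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# tree sampling
# ---------------------------------------------------------------------------

def _random_insertion(rng: np.random.Generator, lo: int = 12, hi: int = 45) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=length))


def _make_variant(gene: str, pathway: Pathway, index: int, rng: np.random.Generator) -> Variant:
    vid = f"{gene}_{index}"
    if gene == "FLT3" and rng.random() < 0.5:
        return Variant(vid, gene, ITD_CHROM, ITD_POS, ref="N",
                       alt=_random_insertion(rng), variant_class=VariantClass.ITD, pathway=pathway)
    pos = int(rng.integers(1_000_000, 250_000_000))
    bases = list("ACGT")
    ref = str(rng.choice(bases))
    alt = str(rng.choice([b for b in bases if b != ref]))
    return Variant(vid, gene, str(int(rng.integers(1, 23))), pos, ref, alt,
                   variant_class=VariantClass.SNV, pathway=pathway)


def _biased_gene_order(genes: list[tuple[str, Pathway]], order_bias: float,
                       rng: np.random.Generator) -> list[tuple[str, Pathway]]:
    """Permute events so the early-class-before-signaling pairwise marginal is ``order_bias``.

    A uniform permutation makes a comparable mixed pair early-first with
    probability 1/2; fully sorting makes it 1. Mixing the two with weight
    q = 2b - 1 (for b >= 1/2) yields marginal b; the b < 1/2 case mirrors.
    """
    perm = list(genes)
    rng.shuffle(perm)
    b = order_bias
    q = abs(2.0 * b - 1.0)
    if rng.random() >= q:
        return perm
    early_first = b >= 0.5
    early = [g for g in perm if g[1] in EARLY_CLASSES]
    signaling = [g for g in perm if g[1] is Pathway.SIGNALING]
    other = [g for g in perm if g[1] not in EARLY_CLASSES and g[1] is not Pathway.SIGNALING]
    ordered = early + signaling if early_first else signaling + early
    # re-insert unconstrained events at random positions
    for g in other:
        ordered.insert(int(rng.integers(len(ordered) + 1)), g)
    return ordered


def sample_random_tree(
    n_mutations: int,
    branching_prob: float,
    gene_pool: Mapping[Pathway, Sequence[str]],
    order_bias: float,
    rng: np.random.Generator,
) -> MutationTree:
    """Sample a ground-truth mutation tree with gene/pathway labels.

    Topology grows by sequential attachment: each new event extends the
    previous one (linear growth) with probability ``1 - branching_prob``,
    otherwise attaches to a uniformly chosen existing node (possibly
    branching). With ``order_bias = 1`` no SIGNALING event is ever ancestral
    to a DNA_METHYLATION or NPM1 event.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    pool = {Pathway(k): list(v) for k, v in gene_pool.items()}
    if not pool or any(not genes for genes in pool.values()):
        raise ValueError("gene pool must be non-empty for each pathway")
    flat = [(g, pw) for pw, genes in pool.items() for g in genes]
    picks = [flat[int(rng.integers(len(flat)))] for _ in range(n_mutations)]
    picks = _biased_gene_order(picks, order_bias, rng)

    variants = {}
    parent: dict[str, str] = {}
    nodes: list[str] = []
    used: dict[str, int] = {}
    prev = ROOT
    for gene, pw in picks:
        used[gene] = used.get(gene, 0) + 1
        var = _make_variant(gene, pw, used[gene], rng)
        vid = var.variant_id
        variants[vid] = var
        if not nodes or rng.random() >= branching_prob:
            parent[vid] = prev
        else:
            parent[vid] = str(rng.choice([ROOT] + nodes))
        nodes.append(vid)
        prev = vid
    return MutationTree(parent, variants)


# ---------------------------------------------------------------------------
# genotype / VAF simulation
# ---------------------------------------------------------------------------

def _freq_array(tree: MutationTree, clone_freqs) -> np.ndarray:
    """Clone frequencies as an array over [ROOT] + tree.nodes order."""
    nodes = [ROOT] + tree.nodes
    if isinstance(clone_freqs, Mapping):
        missing = [n for n in nodes if n not in clone_freqs]
        if missing:
            raise ValueError(f"clone_freqs missing node(s) {missing}")
        freqs = np.array([float(clone_freqs[n]) for n in nodes])
    else:
        freqs = np.asarray(clone_freqs, dtype=float)
        if freqs.shape != (len(nodes),):
            raise ValueError(f"clone_freqs must have length {len(nodes)} ([root] + nodes)")
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("clone frequencies must be nonnegative and sum to 1 (+/- 1e-9)")
    return freqs


def simulate_genotype_matrix(
    tree: MutationTree,
    clone_freqs,
    n_cells: int,
    error_model: ErrorModel,
    missing_rate: float,
    hom_rate: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
    timepoint: Timepoint = Timepoint.DIAGNOSIS,
    beta_per_variant: Mapping[str, float] | None = None,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Draw cells from clones and corrupt their genotypes.

    Each cell attaches to a node drawn from ``clone_freqs`` (over
    [root] + nodes); its true genotype is the indicator of the node's
    root-path mutations. Observation noise: 0 flips to 1 w.p. alpha; 1 flips
    to 0 w.p. beta (optionally overridden per variant); surviving mutant
    calls are upgraded to hom (2) w.p. hom_rate; any call becomes missing
    (3) w.p. missing_rate. Returns the matrix and the ground-truth
    cell -> node attachment.
    """
    nodes = [ROOT] + tree.nodes
    freqs = _freq_array(tree, clone_freqs)
    variant_ids = tree.nodes
    n_var = len(variant_ids)
    truth = np.zeros((len(nodes), n_var), dtype=np.int8)
    col = {vid: j for j, vid in enumerate(variant_ids)}
    for i, node in enumerate(nodes[1:], start=1):
        for vid in tree.root_path(node):
            truth[i, col[vid]] = 1

    assign = rng.choice(len(nodes), size=n_cells, p=freqs)
    true_geno = truth[assign]

    beta_vec = np.full(n_var, error_model.beta)
    if beta_per_variant:
        for vid, b in beta_per_variant.items():
            beta_vec[col[vid]] = b
    u = rng.random((n_cells, n_var))
    obs = true_geno.copy()
    obs[(true_geno == 0) & (u < error_model.alpha)] = 1
    obs[(true_geno == 1) & (u < beta_vec[None, :])] = 0
    hom = (obs == 1) & (rng.random((n_cells, n_var)) < hom_rate)
    obs[hom] = 2
    obs[rng.random((n_cells, n_var)) < missing_rate] = 3

    cell_ids = [f"{sample_id}_c{i}" for i in range(n_cells)]
    matrix = GenotypeMatrix(
        cell_ids=cell_ids,
        variants=[tree.variants[vid] for vid in variant_ids],
        calls=obs,
        sample_id=sample_id,
        timepoint=timepoint,
    )
    attachment = {cell_ids[i]: nodes[assign[i]] for i in range(n_cells)}
    return matrix, attachment


def simulate_bulk_vaf(
    tree: MutationTree,
    clone_freqs,
    hom_fraction: float,
    depth: int,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Paired bulk VAFs: binomial read sampling around the clonal expectation.

    Expected VAF = 0.5 * (mutant cell fraction that is het) + 1.0 * (hom
    fraction); the observed VAF is Binomial(depth, expected) / depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    freqs = _freq_array(tree, clone_freqs)
    nodes = [ROOT] + tree.nodes
    out = {}
    for vid in tree.nodes:
        carrier = sum(
            freqs[i] for i, node in enumerate(nodes)
            if node != ROOT and vid in tree.root_path(node)
        )
        expected = 0.5 * carrier * (1.0 - hom_fraction) + 1.0 * carrier * hom_fraction
        out[vid] = rng.binomial(depth, min(expected, 1.0)) / depth
    return out


# ---------------------------------------------------------------------------
# serial samples
# ---------------------------------------------------------------------------

def simulate_serial_pair(
    tree: MutationTree,
    n_new_events: int,
    parent_policy: Mapping[str, float],
    rng: np.random.Generator,
    *,
    n_cells: int = 300,
    error_model: ErrorModel = None,
    missing_rate: float = 0.1,
    hom_rate: float = 0.05,
    concentration: float = 1.0,
    gene_pool: Mapping[Pathway, Sequence[str]] | None = None,
    patient_id: str = "serial",
) -> tuple[PatientDataset, dict[str, str]]:
    """An earlier/later sample pair where the later tree gains new events.

    ``parent_policy`` maps parent classes ("ROOT", "NPM1",
    "DNA_METHYLATION", ..., or "OTHER") to selection weights; each new event
    (a SIGNALING gene, mirroring relapse biology) is grafted as a leaf under
    a node of the drawn class in the earlier tree. Variants absent at the
    earlier timepoint have no column in the earlier matrix. Returns the
    two-sample dataset and the ground-truth new-event -> parent map.
    """
    if n_new_events < 0:
        raise ValueError("n_new_events must be >= 0")
    error_model = error_model or ErrorModel()
    pool = dict(gene_pool or _default_gene_pool())
    sig_genes = list(pool.get(Pathway.SIGNALING, ["NRAS"]))

    def node_class(node: str) -> str:
        if node == ROOT:
            return "ROOT"
        pw = tree.variants[node].pathway
        return pw.value

    classes = list(parent_policy)
    weights = np.array([float(parent_policy[c]) for c in classes])
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("parent_policy weights must be nonnegative and sum > 0")
    weights = weights / weights.sum()

    by_class: dict[str, list[str]] = {}
    for node in [ROOT] + tree.nodes:
        by_class.setdefault(node_class(node), []).append(node)

    later_parent = dict(tree.parent)
    later_variants = dict(tree.variants)
    truth_parents: dict[str, str] = {}
    used = {}
    def candidates_for(cls_name: str) -> list[str]:
        if cls_name == "OTHER":
            others = [n for n in [ROOT] + tree.nodes
                      if node_class(n) not in classes or node_class(n) == "OTHER"]
            return others or [ROOT]
        return by_class.get(cls_name, [])

    if not any(candidates_for(c) for c in classes):
        raise ValueError("parent_policy names no class present in the earlier tree")
    for k in range(n_new_events):
        # draw classes until one is represented in the earlier tree
        while True:
            cls_name = str(rng.choice(classes, p=weights))
            candidates = candidates_for(cls_name)
            if candidates:
                break
        parent_node = str(rng.choice(candidates))
        gene = str(rng.choice(sig_genes))
        used[gene] = used.get(gene, 0) + 1
        var = _make_variant(gene, Pathway.SIGNALING, 100 + used[gene], rng)
        later_parent[var.variant_id] = parent_node
        later_variants[var.variant_id] = var
        truth_parents[var.variant_id] = parent_node

    later_tree = MutationTree(later_parent, later_variants)

    f_early = rng.dirichlet([concentration] * (len(tree.nodes) + 1))
    f_late = rng.dirichlet([concentration] * (len(later_tree.nodes) + 1))
    early_mat, _ = simulate_genotype_matrix(
        tree, f_early, n_cells, error_model, missing_rate, hom_rate, rng,
        sample_id=f"{patient_id}_t0", timepoint=Timepoint.DIAGNOSIS,
    )
    late_mat, _ = simulate_genotype_matrix(
        later_tree, f_late, n_cells, error_model, missing_rate, hom_rate, rng,
        sample_id=f"{patient_id}_t1", timepoint=Timepoint.RELAPSE,
    )
    late_mat.timepoint_index = 1
    dataset = PatientDataset(patient_id=patient_id, samples=[early_mat, late_mat])
    return dataset, truth_parents


# ---------------------------------------------------------------------------
# ITD fragmentation
# ---------------------------------------------------------------------------

def fragment_itd(itd_variant: Variant, n_fragments: int, rng: np.random.Generator) -> list[Variant]:
    """Split one ITD event into artifactual fragment variants.

    All fragments share the original chrom/pos; each fragment's insertion is
    a contiguous substring of the original sequence, and the original
    sequence itself is always among the fragments (so the set merges back to
    one event under the same-locus substring rule).
    """
    if itd_variant.variant_class is not VariantClass.ITD:
        raise ValueError(f"{itd_variant.variant_id} is not an ITD variant")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    seq = itd_variant.alt
    out = [itd_variant]
    for k in range(1, n_fragments):
        length = int(rng.integers(1, len(seq) + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        out.append(
            Variant(
                f"{itd_variant.variant_id}_frag{k}",
                itd_variant.gene,
                itd_variant.chrom,
                itd_variant.pos,
                itd_variant.ref,
                seq[start : start + length],
                variant_class=VariantClass.ITD,
                status=itd_variant.status,
                pathway=itd_variant.pathway,
            )
        )
    return out


def _apply_itd_fragmentation(
    matrix: GenotypeMatrix, tree: MutationTree, prob: float, max_fragments: int,
    rng: np.random.Generator, detect_rate: float = 0.6,
) -> GenotypeMatrix:
    """Replace ITD columns with several fragment columns (batch-effect artifact).

    Each fragment observes the same underlying event but detects each mutant
    call independently with probability ``detect_rate`` (missing stays
    missing), mimicking unstable insertion-sequence calling.
    """
    itds = [v for v in matrix.variants if v.variant_class is VariantClass.ITD]
    if not itds or prob <= 0:
        return matrix
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for j, v in enumerate(matrix.variants):
        colv = matrix.calls[:, j]
        if v.variant_class is VariantClass.ITD and rng.random() < prob and max_fragments > 1:
            k = int(rng.integers(2, max_fragments + 1))
            frags = fragment_itd(v, k, rng)
            for frag in frags:
                fcol = colv.copy()
                mutant = (colv == 1) | (colv == 2)
                drop = mutant & (rng.random(colv.shape[0]) >= detect_rate)
                fcol[drop] = 0
                variants.append(frag)
                columns.append(fcol)
        else:
            variants.append(v)
            columns.append(colv)
    return GenotypeMatrix(
        cell_ids=list(matrix.cell_ids),
        variants=variants,
        calls=np.column_stack(columns),
        sample_id=matrix.sample_id,
        timepoint=matrix.timepoint,
        timepoint_index=matrix.timepoint_index,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    tree: MutationTree
    clone_freqs: np.ndarray            # over [root] + tree.nodes
    attachment: dict[str, str]
    fragmented_from: dict[str, str] = field(default_factory=dict)  # fragment id -> original id


def patient_rng(seed: int, index: int) -> np.random.Generator:
    """Per-patient stream split from the cohort seed by counter."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(index,)))


def simulate_cohort(config: SimConfig) -> tuple[list[PatientDataset], list[PatientTruth]]:
    """Simulate a full cohort; deterministic given ``config.seed``."""
    cohort: list[PatientDataset] = []
    truths: list[PatientTruth] = []
    frag_p, frag_max = config.itd_fragmentation
    err = ErrorModel(config.alpha, config.beta)
    for i in range(config.n_patients):
        rng = patient_rng(config.seed, i)
        pid = f"P{i:03d}"
        lo, hi = config.n_mutations_range
        n_mut = int(rng.integers(lo, hi + 1))
        tree = sample_random_tree(n_mut, config.branching_prob, config.gene_pool, config.order_bias, rng)
        freqs = rng.dirichlet([config.clone_freq_concentration] * (n_mut + 1))
        matrix, attachment = simulate_genotype_matrix(
            tree, freqs, config.n_cells, err, config.missing_rate, config.hom_rate, rng,
            sample_id=f"{pid}_dx",
        )
        vafs = simulate_bulk_vaf(tree, freqs, config.hom_rate, config.bulk_depth, rng)
        observed = _apply_itd_fragmentation(matrix, tree, frag_p, frag_max, rng)
        fragmented_from = {
            v.variant_id: v.variant_id.split("_frag")[0]
            for v in observed.variants
            if "_frag" in v.variant_id
        }
        dataset = PatientDataset(
            patient_id=pid,
            samples=[observed],
            bulk_vafs={(observed.sample_id, vid): vaf for vid, vaf in vafs.items()},
        )
        cohort.append(dataset)
        truths.append(PatientTruth(pid, tree, freqs, attachment, fragmented_from))
    return cohort, truths
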