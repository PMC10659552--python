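"""End-to-end per-patient pipeline: filter -> infer -> postprocess.

Glue over the library modules so the CLI, tests and cohort analyses can run
the whole procedure with one call per patient: inclusion filtering,
cohort-level artifact exclusion, sample merging and binarization, MCMC tree
search, ITD merging, and low-support pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .filtering import build_filter_report, flag_recurrent_artifacts
from .inference import attach_cells, infer_tree_mcmc, merge_samples
from .model import BinaryMatrix, ErrorModel, GenotypeMatrix, MutationTree, PatientDataset, VariantClass
from .pathways import default_pathway_map
from .postprocess import (
    compute_cell_support,
    flag_low_support,
    merge_itds,
    prune_low_support_variants,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    alpha: float = 0.01
    beta: float = 0.2
    min_fraction: float = 0.01
    min_lower_count: float = 10.0
    ci_level: float = 0.95
    support_threshold: float = 0.5
    n_iter: int | None = None
    n_chains: int = 2
    seed: int = 0

    @property
    def error_model(self) -> ErrorModel:
        return ErrorModel(self.alpha, self.beta)


@dataclass
class PatientResult:
    patient_id: str
    tree: MutationTree
    data: BinaryMatrix
    attachment: dict[str, str]
    filter_report: pd.DataFrame
    pruned_variants: list[str] = field(default_factory=list)
    itd_log: list[dict] = field(default_factory=list)


def _filter_sample(matrix: GenotypeMatrix, cfg: PipelineConfig,
                   excluded_keys: set) -> tuple[GenotypeMatrix, pd.DataFrame]:
    report = build_filter_report(matrix, cfg.min_fraction, cfg.min_lower_count, cfg.ci_level)
    included = set(report.loc[report["decision"] == "INCLUDED", "variant_id"])
    keep = [
        j for j, v in enumerate(matrix.variants)
        if v.variant_id in included and (v.gene, v.chrom, v.pos, v.ref, v.alt) not in excluded_keys
    ]
    filtered = GenotypeMatrix(
        cell_ids=list(matrix.cell_ids),
        variants=[matrix.variants[j] for j in keep],
        calls=matrix.calls[:, keep],
        sample_id=matrix.sample_id,
        timepoint=matrix.timepoint,
        timepoint_index=matrix.timepoint_index,
    )
    return filtered, report


def process_patient(
    dataset: PatientDataset,
    cfg: PipelineConfig | None = None,
    excluded_keys: set | None = None,
) -> PatientResult | None:
    """Run filter -> infer -> postprocess for one patient.

    Returns None when no variant survives filtering (no tree can be built).
    """
    cfg = cfg or PipelineConfig()
    excluded_keys = excluded_keys or set()
    filtered_samples, reports = [], []
    for sample in dataset.samples:
        filtered, report = _filter_sample(sample, cfg, excluded_keys)
        filtered_samples.append(filtered)
        reports.append(report.assign(sample_id=sample.sample_id))
    report = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
    union_variants = {v.variant_id for s in filtered_samples for v in s.variants}
    if not union_variants:
        logger.info("patient %s: no variants pass inclusion; skipping", dataset.patient_id)
        return None

    filtered_dataset = PatientDataset(dataset.patient_id, filtered_samples, dataset.bulk_vafs)
    data = merge_samples(filtered_dataset)
    err = cfg.error_model
    tree = infer_tree_mcmc(data, err, n_iter=cfg.n_iter, n_chains=cfg.n_chains, seed=cfg.seed)

    itd_log: list[dict] = []
    itds = [v for v in data.variants if v.variant_class is VariantClass.ITD and v.variant_id in tree.parent]
    if len(itds) >= 2:
        merged = merge_itds(itds, tree, data, err=err, seed=cfg.seed)
        tree, data, itd_log = merged.tree, merged.data, merged.log

    table = flag_low_support(compute_cell_support(data, tree), cfg.support_threshold)
    tree, pruned = prune_low_support_variants(tree, table, data, cfg.support_threshold)
    attachment = attach_cells(tree, data, err)
    tree.attachment = attachment
    return PatientResult(dataset.patient_id, tree, data, attachment, report, pruned, itd_log)


def run_cohort(
    cohort: list[PatientDataset],
    cfg: PipelineConfig | None = None,
    aml_gene_set: set[str] | None = None,
) -> list[PatientResult]:
    """Pipeline over a cohort, with cohort-level artifact exclusion first."""
    cfg = cfg or PipelineConfig()
    if aml_gene_set is None:
        aml_gene_set = set(default_pathway_map())
    excluded = flag_recurrent_artifacts(cohort, aml_gene_set)
    results = []
    for dataset in cohort:
        result = process_patient(dataset, cfg, excluded)
        if result is not None and result.tree.nodes:
            results.append(result)
    return results
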