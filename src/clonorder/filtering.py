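"""Variant inclusion thresholds, driver classification and artifact exclusion.

Inclusion requires both (i) at least 1% of called cells mutated and (ii) a
95% Clopper-Pearson lower bound on the mutant-cell count above 10. The
denominator throughout is the number of cells with a non-missing call for
the variant. Cohort-level artifact rules exclude non-AML-gene variants that
are either near-ubiquitous across patients or recurrently mutated at a low
cell fraction.
"""

from __future__ import annotations

import logging
import re

import pandas as pd
from scipy import stats

from .model import GenotypeMatrix, PatientDataset, Variant, VariantStatus

logger = logging.getLogger(__name__)

__all__ = [
    "compute_mutated_fraction",
    "clopper_pearson_lower",
    "passes_inclusion",
    "build_filter_report",
    "flag_recurrent_artifacts",
    "classify_driver",
]

DECISION_INCLUDED = "INCLUDED"
DECISION_FAIL_FRACTION = "FAIL_FRACTION"
DECISION_FAIL_CI = "FAIL_CI"
DECISION_ARTIFACT_PREVALENCE = "ARTIFACT_PREVALENCE"
DECISION_ARTIFACT_RECURRENT_LOW = "ARTIFACT_RECURRENT_LOW"


def compute_mutated_fraction(matrix: GenotypeMatrix, variant_id: str) -> tuple[float, int, int]:
    """(fraction, n_mutant, n_called) for one variant.

    n_called counts cells with a non-missing call; n_mutant counts het or
    hom calls. A zero denominator yields fraction 0 (callers should treat
    n_called == 0 as a flag).
    """
    col = matrix.column(variant_id)
    n_called = int((col != 3).sum())
    n_mutant = int(((col == 1) | (col == 2)).sum())
    fraction = n_mutant / n_called if n_called else 0.0
    return fraction, n_mutant, n_called


def clopper_pearson_lower(k: int, n: int, ci_level: float = 0.95) -> float:
    """Lower bound of the two-sided Clopper-Pearson interval on a proportion."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0 or k == 0:
        return 0.0
    return float(stats.beta.ppf((1.0 - ci_level) / 2.0, k, n - k + 1))


def passes_inclusion(
    matrix: GenotypeMatrix,
    variant_id: str,
    min_fraction: float = 0.01,
    min_lower_count: float = 10.0,
    ci_level: float = 0.95,
) -> tuple[bool, dict]:
    """Apply the inclusion thresholds to one variant.

    Passes iff mutated fraction >= min_fraction AND the Clopper-Pearson
    lower bound on the mutant proportion, scaled to a cell count, exceeds
    min_lower_count (strict >). Returns (decision, report row).
    """
    fraction, n_mutant, n_called = compute_mutated_fraction(matrix, variant_id)
    lower = clopper_pearson_lower(n_mutant, n_called, ci_level) * n_called if n_called else 0.0
    if n_called == 0 or fraction < min_fraction:
        decision = DECISION_FAIL_FRACTION
    elif not lower > min_lower_count:
        decision = DECISION_FAIL_CI
    else:
        decision = DECISION_INCLUDED
    row = {
        "variant_id": variant_id,
        "mutated_fraction": fraction,
        "n_mutant_cells": n_mutant,
        "n_called_cells": n_called,
        "ci_lower_count": lower,
        "decision": decision,
    }
    return decision == DECISION_INCLUDED, row


def build_filter_report(
    matrix: GenotypeMatrix,
    min_fraction: float = 0.01,
    min_lower_count: float = 10.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-variant inclusion report for one sample."""
    rows = [
        passes_inclusion(matrix, vid, min_fraction, min_lower_count, ci_level)[1]
        for vid in matrix.variant_ids
    ]
    return pd.DataFrame(rows)


def flag_recurrent_artifacts(
    cohort: list[PatientDataset],
    aml_gene_set: set[str],
    prevalence_cutoff: float = 0.5,
    low_fraction_cutoff: float = 0.1,
    min_recurrence: int = 3,
) -> set[tuple[str, str, int, str, str]]:
    """Cohort-level artifact exclusion.

    Variants are keyed by (gene, chrom, pos, ref, alt) across patients. A
    key is excluded iff its gene is NOT in ``aml_gene_set`` AND either it
    appears in more than ``prevalence_cutoff`` of patients, or it recurs in
    at least ``min_recurrence`` patients always below
    ``low_fraction_cutoff`` mutated fraction. AML-panel genes are never
    excluded.
    """
    if not cohort:
        return set()
    fractions: dict[tuple, list[float]] = {}
    for patient in cohort:
        per_patient: dict[tuple, float] = {}
        for sample in patient.samples:
            for v in sample.variants:
                key = (v.gene, v.chrom, v.pos, v.ref, v.alt)
                frac, _, _ = compute_mutated_fraction(sample, v.variant_id)
                per_patient[key] = max(per_patient.get(key, 0.0), frac)
        for key, frac in per_patient.items():
            fractions.setdefault(key, []).append(frac)
    n_patients = len(cohort)
    excluded = set()
    for key, fracs in fractions.items():
        gene = key[0]
        if gene in aml_gene_set:
            continue
        prevalence = len(fracs) / n_patients
        recurrent_low = len(fracs) >= min_recurrence and all(f < low_fraction_cutoff for f in fracs)
        if prevalence > prevalence_cutoff or recurrent_low:
            excluded.add(key)
    return excluded


_SYNONYMOUS_RE = re.compile(r"^p\.(?:([A-Z][a-z]{2}|[A-Z])(\d+)\1|.*=)$")


def classify_driver(variant: Variant, rules: dict) -> VariantStatus:
    """Classify a variant as DRIVER or VUS from a pluggable rule table.

    ``rules`` maps gene -> {"hotspots": [positions], "classes": [variant
    classes]}. A variant is a driver if its position hits a listed hotspot
    or its class is whitelisted for the gene; synonymous protein changes are
    always VUS; genes absent from the rules yield VUS with a warning.
    """
    if variant.protein_change and _SYNONYMOUS_RE.match(variant.protein_change):
        return VariantStatus.VUS
    gene_rules = rules.get(variant.gene)
    if gene_rules is None:
        logger.warning("no driver rules for gene %s; classifying %s as VUS",
                       variant.gene, variant.variant_id)
        return VariantStatus.VUS
    if variant.pos in set(gene_rules.get("hotspots", [])):
        return VariantStatus.DRIVER
    if variant.variant_class.value in set(gene_rules.get("classes", [])):
        return VariantStatus.DRIVER
    return VariantStatus.VUS
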