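# clonorder

Clonal-evolution and mutation-order analysis for targeted single-cell DNA
sequencing of acute myeloid leukemia (AML).

AML evolves by sequential acquisition of driver mutations, and the *order*
of those events — not just their presence — carries biological and clinical
signal: DNA-methylation mutations (DNMT3A, IDH1/2, TET2) typically precede
cell-signaling mutations (FLT3, NRAS, KRAS, ...), and deviations from that
order mark distinct disease biology. Tapestri-style targeted panels
genotype thousands of single cells at a few dozen loci, which makes the
order recoverable per patient. `clonorder` is for computational biologists
and AML researchers who want to go from per-sample genotype matrices to
per-patient mutation trees and cohort-level ordering statistics.

## What it does

* **Mutation-tree inference.** Per patient, a rooted mutation tree under
  the infinite-sites assumption (each event occurs once, never reverts) is
  fit by maximum likelihood with an explicit error model — false-positive
  rate α and allele-dropout false-negative rate β — marginalizing every
  cell's attachment over all tree nodes:

      log L(T) = Σ_cells log[ (1/N) Σ_nodes Π_variants P(obs | expected, α, β) ]

  Search is Metropolis MCMC (prune-and-reattach and label-swap moves) with
  an exhaustive enumeration oracle for small instances. Zygosity is
  collapsed for tree building; serial samples merge into one matrix.
* **Variant filtering.** Inclusion requires ≥ 1% mutated cells *and* a 95%
  Clopper–Pearson lower bound above 10 mutant cells; cohort-level rules
  exclude recurrent artifacts in non-AML genes; driver/VUS classification
  is a pluggable rule table. VUS inform tree architecture but are excluded
  from order inference.
* **Tree cleaning.** "Cell support" (the fraction of later-mutant cells
  carrying the earlier mutation) validates every same-clone pair; paths
  under 50% support are pruned greedily. FLT3-ITD records that describe one
  insertion event (same-locus substring fragments, terminal siblings,
  support-degrading splits) are merged.
* **Cohort analyses.** Early/late calls, pairwise and trio ordering with
  exact binomial/multinomial tests, merged cohort graphs (prefix tries over
  root sequences), distinct-ordering counts, branching composition,
  single-mutant clone sizes, bulk-VAF concordance and VAF-based early/late
  proxies (cutoff 0.3), serial-sample new-event parent enrichment (Fisher
  exact), and homozygosity summaries.
* **Synthetic cohorts.** A seeded generator produces ground-truth trees,
  clone frequencies, noisy genotypes, paired bulk VAFs, serial samples, and
  fragmented ITD artifacts, so the full pipeline is testable without access
  to protected patient data.

See `docs/methods.md` for the model, defaults, and design decisions.

## Worked example

```python
import numpy as np
from clonorder import (
    PipelineConfig, SimConfig, count_distinct_orderings,
    pairwise_order_summary, run_cohort, simulate_cohort,
)
from clonorder.analysis import ordered_pair_fraction

# a 20-patient synthetic cohort in which DNA-methylation/NPM1 events
# precede signaling events 85% of the time
cfg = SimConfig(n_patients=20, n_cells=300, order_bias=0.85, seed=7)
cohort, truths = simulate_cohort(cfg)

# filter -> infer -> merge ITDs -> prune, per patient
results = run_cohort(cohort, PipelineConfig(seed=0))
trees = [r.tree for r in results]

frac, n_pairs = ordered_pair_fraction(trees)
print(f"patients with trees : {len(trees)}")
print(f"distinct orderings  : {count_distinct_orderings(trees)}")
print(f"DNAme/NPM1 -> signaling fraction: {frac:.2f} over {n_pairs} ordered pairs")

summary = pairwise_order_summary(trees, level="PATHWAY")
row = summary[(summary.g1 == "DNA_METHYLATION") & (summary.g2 == "SIGNALING")].iloc[0]
print(f"DNA_METHYLATION vs SIGNALING: {row.n_g1_first} vs {row.n_g2_first} first, "
      f"binomial p = {row.binomial_p:.4f}")
```

Output:

```
patients with trees : 20
distinct orderings  : 26
DNAme/NPM1 -> signaling fraction: 0.87 over 15 ordered pairs
DNA_METHYLATION vs SIGNALING: 4 vs 1 first, binomial p = 0.3750
```

All 20 patients yield a tree; the cohort shows 26 distinct maximal
root-to-leaf gene orderings; and the inferred trees recover the generated
ordering bias (0.87 measured vs 0.85 simulated). The pathway-level pairwise
test counts each patient once per direction — here 4 methylation-first vs 1
signaling-first, which at n = 5 is not yet a significant asymmetry
(two-sided exact binomial p = 0.375).

## Command line

```bash
clonorder simulate --config sim.yaml --out cohort/ --seed 1
clonorder filter --matrix cohort/P000_genotypes.tsv --variants cohort/P000_variants.tsv --report report.tsv
clonorder postprocess --matrix cohort/P000_genotypes.tsv --variants cohort/P000_variants.tsv \
    --seed 1 --out trees/P000.graphml
clonorder analyze --trees trees/ --level gene --out analysis/
clonorder report --analysis analysis/
```

Genotype matrices are TSV/CSV (header of variant ids, leading `cell_id`
column, codes 0 = wildtype, 1 = het, 2 = hom-or-LOH, 3 = missing); trees
are GraphML/DOT; variant metadata and summaries are TSV.

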