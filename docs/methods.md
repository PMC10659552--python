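# Methods

## Problem and model

`clonorder` reconstructs the order in which driver mutations were acquired
in acute myeloid leukemia (AML) from targeted-panel single-cell DNA
sequencing (Mission Bio Tapestri-style), and summarizes ordering patterns
across a cohort. The central object is the **mutation tree**: a rooted tree
whose root is the wildtype state and whose non-root nodes are mutation
events. Under the **infinite-sites assumption** each event occurs at most
once and never reverts, so a cell attached to a node carries exactly the
mutations on the node's root path, and mutant cell populations are
perfectly nested in the absence of noise.

Observed genotypes are corrupted by a global false-positive rate α
(wildtype read as mutant) and a false-negative allele-dropout rate β
(mutant read as wildtype); missing calls carry no information. The
likelihood of a tree T marginalizes every cell's attachment uniformly over
the N nodes (root included):

    log L(T) = Σ_cells log[ (1/N) Σ_nodes Π_variants P(obs | expected, α, β) ]

with P(1|0)=α, P(0|0)=1−α, P(0|1)=β, P(1|1)=1−β and P(missing|·)=1. This is
the standard single-cell mutation-tree (SCITE-family) marginal likelihood.
Zygosity is collapsed before tree building (het and hom/LOH both count as
mutant): amplicon panels cannot separate homozygosity from loss of
heterozygosity, and zygosity carries little extra ordering signal.

## Search

Maximum-likelihood search uses Metropolis MCMC over labeled rooted trees
with two symmetric proposals chosen with equal probability: prune a subtree
and reattach it to a uniformly chosen node outside the subtree, or swap the
labels of two nodes. The best tree visited across chains is returned. Exact
likelihood ties are broken toward the lexicographically smallest canonical
parent-vector, making results reproducible for a given seed.

Defaults are 2 independent chains of `1500 + 250·n²` iterations for n
variants. The panel setting keeps n small (typically 2–10), where this
schedule reaches the global optimum of the exhaustive search
(`enumerate_trees_exact`, feasible for n ≤ 6 since there are (n+1)^(n−1)
labeled rooted trees) on every instance we test; the chain count and length
are configurable for larger problems.

Error rates are fixed per run (α = 0.01 and β = 0.2 by default, β ideally
set from the platform's per-sample dropout estimate). β is deliberately not
learned during search: a β-move would make runs sensitive to move ordering,
and at panel scale the inferred topology is robust to moderate
misspecification of β.

Variants of unknown significance (VUS) join the likelihood and the search —
they carry real signal about architecture — but are contracted out of the
returned tree (children reattached to the VUS node's parent), so all
downstream ordering statistics see driver events only.

### Cell attachment

Cells are assigned to their maximum-likelihood attachment node; ties go to
the node closest to the root (an all-missing cell therefore sits at the
root). This convention is conservative — a cell is never claimed to carry
more mutations than its reads support — but it biases attachments shallow
under dropout: a cell whose terminal path mutation reads 0 (probability
β(1−missing)) or missing (an exact tie) is placed at the parent node. With
β = 0.2 and 10% missing calls roughly a quarter of non-root cells attach
one node above their true clone; tree topology and ordering statistics are
unaffected (they use the marginal likelihood, not hard attachments), but
per-cell attachment accuracy saturates around 70–75% in that regime.

## Filtering

Per sample, a variant is included when both:

1. at least 1% of called cells are mutant (the denominator is always the
   number of cells with a non-missing call for that variant), and
2. the 95% two-sided Clopper–Pearson lower bound on the mutant proportion,
   scaled to a cell count, exceeds 10 cells (strict).

The Clopper–Pearson interval was chosen because it is exact and
conservative at the low fractions that matter here; the level and bound are
configurable. Cohort-level artifact screening excludes a variant key
(gene, locus, ref, alt) only when its gene is *not* an AML panel gene and
it either appears in more than half the patients or recurs in ≥ 3 patients
always below 10% mutated cells; the thresholds reproduce the shape of the
rule and are exposed in configuration for calibration. Driver/VUS calls
come from a pluggable rule table (per-gene hotspot positions and variant
classes; synonymous changes are always VUS) rather than a hard-coded
knowledge base.

## Post-processing

**Cell support.** For an ordered same-path pair (a earlier, b later),
support = #{cells: b mutant ∧ a mutant} / #{cells: b mutant ∧ a called}.
Under the infinite-sites model this is 1 in expectation up to ancestor
dropout (≈ 1−β_a). Pairs below 50% support (strict) are low-support;
undefined supports (no informative cells) are treated as low.

**Pruning.** Low-support paths are cleaned greedily: repeatedly remove the
variant participating in the most low-support pairs, breaking ties toward
the more distal node and then the lexicographically smallest id, contract
its node, and recompute supports. The loop terminates in at most n
iterations and never touches the root. The score combines the two factors
(pair count, distal position) lexicographically; the combination is a
design choice of this package.

**FLT3-ITD merging.** Multiple ITD records in one patient often describe a
single biological insertion (unstable ITD sequences, caller batch
effects). Three rules are applied in order: (R1) records at the same start
locus whose insertions are contiguous substrings of the group's longest
merge (tandem-duplication fragments are contiguous; a configuration switch
allows non-contiguous subsequence matching); (R2) remaining ITDs that are
all terminal children of one common parent node merge; (R3) if the tree has
at least one low-support pair involving an ITD and re-inferring on the
merged matrix removes all of them, the merge is accepted — a measurable,
conservative operationalization of "fewer poorly supported connections".
Merged genotype columns take the union of member calls (mutant if any
member mutant, missing only if all missing), and the tree is re-inferred on
the merged matrix. The operation is idempotent.

## Cohort analyses

* **Early/late**: an event is early iff its parent is the root.
* **Pairwise ordering**: per label pair (gene or pathway), counts of
  same-patient co-occurrence, same-clone co-occurrence (both events on one
  root path), and precedence in each direction; a two-sided exact binomial
  test against p = ½ scores directional asymmetry. Default counting scores
  each patient once per pair and direction; event-level counting is
  available. Self-pairs (two events of one gene) are reported separately
  and carry no direction.
* **Trio ordering**: exact multinomial goodness-of-fit over the 6 orderings
  of a trio under a uniform null, computed in integer arithmetic (an
  outcome's null probability is proportional to its multinomial
  coefficient); enumeration is limited to n ≤ 30 observations per trio.
* **Merged graphs**: a prefix trie over root label sequences; a key's
  weight is the number of patients whose tree contains that root sequence,
  and keys below a minimum count are dropped (the trie stays prefix-closed
  because a prefix is at least as frequent as its extensions).
* **Distinct orderings**: the number of maximal root-to-leaf label
  sequences after removing strict prefixes — a sequence that merely extends
  another is not a new ordering.
* **Branching**: branch points are nodes (including the root) with two or
  more children; the pathway composition of their children and per-gene
  branch rates are reported.
* **Clone sizes and VAF concordance**: the single-mutant clone size of an
  ancestor–descendant pair is the difference of their mutated-cell
  fractions (each with its own called-cell denominator; negative values
  under noise are reported as-is). Paired bulk VAF differences are compared
  with cell-fraction differences by Pearson correlation over same-path
  pairs (≥ 3 pairs required; zero-variance inputs are flagged undefined).
  A bulk VAF of 0.3 is the proxy cutoff between early (≥ 0.3) and late
  mutations when single-cell data are unavailable; the boundary itself is
  assigned early.
* **Serial samples**: events present in a later sample but absent from the
  earlier variant set are "new"; each new signaling event contributes its
  parent node in the merged tree (root = no prior mutation). A 2×2 table
  crosses parent class (NPM1-or-DNA-methylation vs other including root)
  with role (parent of a new signaling event vs other available node, where
  available = earlier-tree nodes plus root), tested by two-sided Fisher
  exact test. Pooling across patients is the caller's choice; tables add.
* **Homozygosity**: fraction of mutant cells called hom-or-LOH; undefined
  (NaN) without mutant cells.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
the sequencing process. Per patient: a mutation tree over panel genes
(sequential attachment; linear growth with probability 1−branching_prob,
otherwise a uniformly chosen existing node), clone frequencies from a
symmetric Dirichlet over all nodes *including the root* (samples contain
non-leukemic cells), per-cell genotypes with α/β flips, hom upgrades and
missing calls, paired bulk VAFs with binomial read sampling at a configured
depth, and optional fragmentation of FLT3-ITD insertions into same-locus
contiguous substrings (each fragment re-detects mutant calls independently,
mimicking unstable insertion calling).

Mutation-order structure is controlled by `order_bias` b: gene assignments
are a per-tree mixture of a fully sorted order (all DNA-methylation/NPM1
events before all signaling events, weight |2b−1|) and a uniform
permutation, which makes a comparable mixed pair methylation-first with
probability exactly b in the linear case and empirically within ±0.01 for
the default branching rate. At b = 1 no signaling event is ever ancestral
to a methylation or NPM1 event.

Defaults describe a desk-scale analogue of a multi-site AML cohort: 2–6
driver events per patient, branching probability 0.2, 300 cells per sample,
α = 0.01, β = 0.2, 10% missing, 5% hom upgrades, bulk depth 10 000, ITD
fragmentation probability 0.2 with up to 3 fragments, order bias 0.85.
α/β/missing sit in the range reported for single-cell DNA panels and are
exposed in configuration. One cohort seed is split per patient by counter,
so patient i's data do not change when the cohort grows.

What the generator does **not** model — doublets, amplicon bias, copy-number
events, per-site error heterogeneity, read-level errors — bounds what
passing tests show: they demonstrate correctness of the inference and
statistics under the stated error model, not robustness to artifacts
outside it.

## Numerical and design notes

* Likelihoods are computed on unique observation rows with multiplicities
  (cells collapse heavily at panel scale) via log-sum-exp; a slower exact
  path handles degenerate error rates of exactly 0, where log-probabilities
  are −∞.
* Exhaustive enumeration refuses n > 6 variants.
* Genotype codes are fixed at 0/1/2/3 (wildtype/het/hom/missing);
  coordinates are 1-based; strand is ignored.
* Merging a patient's serial samples concatenates cells over the variant
  union; a variant with no column at some timepoint is scored wildtype
  (not missing) for those cells. This is a strong assumption — a variant
  absent from a panel revision would be wrongly treated as absent from the
  cells — and callers merging across heterogeneous panels should restrict
  to the shared target set first.
* The gene→pathway map ships as an editable YAML covering the 19-gene AML
  panel; unmapped genes fall to OTHER.
* Problem sizes in the test-suite and in `scripts/acceptance.py`
  (10–20 seeds, 50–5000 cells, 150–200 patients) were chosen as the
  smallest scales at which the Monte-Carlo bands in use are stable.

## Known limitations

* Per-cell attachment accuracy is capped by dropout as described above;
  use attachments for visualization and coarse clone assignment, not as
  per-cell genotype truth.
* A single global (α, β) per patient ignores per-amplicon variation.
* The artifact-exclusion thresholds and driver rules are calibration
  points, not validated clinical criteria.
* Survival and clinical-covariate modeling are out of scope; the ordering
  statistics are designed to be joined against external clinical tables.
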