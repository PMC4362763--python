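# Methods

## The analysis

`phenoconverge` implements a pathway-convergence analysis for cohorts of
patients with developmental disorders who carry de novo copy-number
variants (CNVs) and have been phenotyped *systematically* with a
hierarchical phenotype ontology (every patient considered for every
term, so absence of a term is informative). The analysis asks two
questions:

1. **Which molecular pathways are recurrently perturbed** in patients
   who share a phenotype? Patients are grouped by every propagated
   ontology term carried by at least `min_group_size` (default 3)
   patients, and each group's pooled CNV gene set is interrogated with
   four engines: GO-like and KEGG-like gene-set enrichment,
   model-organism knockout-phenotype enrichment, and clustering in a
   gene co-expression network. Candidate genes are those identified by
   at least two engines, and candidate sets are validated by clustering
   in a protein-protein interaction (PPI) network.
2. **Do patients who share a perturbed pathway converge
   phenotypically?** For each significant enrichment, group members are
   split into "contributing" patients (their CNV genes intersect the
   enrichment's gene overlap) and "non-contributing" patients, and the
   phenotypic similarity among contributing pairs is compared with the
   similarity between contributing and non-contributing patients.

## Cohort construction

CNV calls are 0-based half-open intervals with dosage (gain/loss) and
inheritance annotations. A patient enters the analysis cohort when they
carry at least one de novo CNV and **every** de novo CNV is strictly
shorter than 5 Mb (larger events disrupt too many genes to resolve a
pathway); patients with no de novo CNV but other CNV records form the
replication pool. A CNV affects a gene iff the whole gene lies inside
the CNV, or the CNV intersects at least one exon in *every* transcript
— the exon-aware rule prevents counting genes where only a fraction of
very long transcripts is touched. Genes observed copy-changed in the
same dosage direction in control individuals are removed before any
enrichment. Overlapping (≥ 1 bp) or bookended CNVs merge into CNV
regions (CNVRs), ignoring dosage.

## Enrichment engines

Enrichment of a group's pooled genes in an annotation term uses the
exact upper tail of the hypergeometric distribution against the
resource's gene universe, corrected by Benjamini–Hochberg within one
(group × resource) family at FDR < 0.05. The model-organism engine maps
human genes through a strict 1:1 ortholog table (ambiguous orthologies
are simply absent from the table), restricts candidate terms to the
overarching category configured for the group's phenotype (the
human-term → category assignment is an input, not inferred), and drops
terms annotating < 1% of the category's gene pool before correction.

The co-expression engine thresholds pairwise Pearson correlation of a
genes × samples expression matrix: genes below 1 RPKM in > 95% of
samples are removed, and edges keep signed r ≥ 0.7 (configurable; the
0.6/0.7/0.8 sweep produces nested edge sets by construction). A group
clusters in a network when its induced weight sum (co-expression) or
edge count (PPI) exceeds that of random gene sets matched in size and
per-gene degree: for each test gene, a gene of identical degree is
drawn, without replacement within a set, up to `n_samples` sets
(≤ 10,000). The empirical p-value uses the +1/+1 estimator
p = (1 + #{null ≥ observed}) / (1 + n), so p is never exactly zero.

The bait-extension test takes a fixed phenotype-associated PPI
subnetwork ("bait") and an independent cohort's CNVRs, drops CNVRs that
contain bait genes or hit no in-network gene, and compares the number of
bait↔CNVR-gene edges against `n_rand` (default 500) randomisations in
which each CNVR is replaced by a random run of consecutive genes (in
genomic order) containing the same number of in-network genes and no
bait gene. Runs are anchored on in-network genes; the chromosome is
chosen with probability proportional to its count of feasible anchors.
Only bait↔CNVR edges are counted, not CNVR↔CNVR edges.

## Phenotypic similarity

Similarity between two patients is the Goodall3 index over the
phenotype universe (every term annotated to any patient under
comparison), with per-term weight

    G_i = 1 − f_i²        i present in both patients
    G_i = 1 − (1 − f_i)²  i present in neither patient
    G_i = 0               i present in only one,

where f_i is the term's frequency in the comparison cohort. Sharing a
rare phenotype or jointly lacking a common one both score highly — this
uses the evidence-of-absence that systematic phenotyping provides.
Frequencies are computed over the full retained cohort by default, and
over the comparison pool in the replication analysis.

For each significant enrichment, intra (contributing-pair) and inter
(contributing × non-contributing) similarity sets are compared with a
two-sided Wilcoxon rank-sum test — exact enumeration for tiny tie-free
inputs, otherwise the normal approximation with tie and continuity
correction. Comparisons need ≥ 10 patients on each side.

**Caveat: these pair sets are not independent** (pairs share patients),
so the raw rank-sum p-value is anticonservative at the patient level —
in null simulations the rejection rate at α = 0.05 is roughly 6–13%
depending on group composition. The p-values are therefore descriptive
indices, as in the analysis style this package follows. The calibrated
summary is the one-sided binomial excess test, which only counts the
*direction* of each comparison (median intra vs median inter, ties
dropped) against a fair coin; direction is symmetric under the
patient-level null.

Two follow-ups characterise a significant convergence: the
subterm-restricted test recomputes frequencies over the group members
using only proper descendants of the group term, distinguishing "more
specific subtype" signals (subterm test fires) from pleiotropic
co-morbidity outside the branch (subterm test null); and the
pooled-by-annotation test combines contributing patients across all
groups sharing a significant annotation term, which increases power
when one pathway drives several phenotype groups.

The replication analysis partitions patients without de novo CNVs into
mutually exclusive candidate / extended / none groups by whether their
inherited CNVs hit a candidate-pathway gene, a gene functionally linked
to one (same annotation term, or a direct network edge), or neither —
candidate membership wins on overlap — and runs candidate vs rest and
extended vs none comparisons.

## Synthetic study generator

Because the motivating data are private clinical records, the package
ships a seeded generator that emulates the study design and is the
basis of every calibration and power test:

- **Ontology**: a rooted DAG of 500 terms, depth ≤ 6, ~10% of terms
  with two parents; written to OBO and re-parsed in round-trip tests.
- **Genome**: 2,000 non-overlapping genes on 10 chromosomes, 1–3
  transcripts of 2–8 exons each, gene lengths 10–200 kb with 10–100 kb
  gaps (≈ one gene per 160 kb, the density of a gene-rich human
  region).
- **Cohort**: 200 de novo patients and a 200-patient replication pool;
  CNV lengths log-uniform on [50 kb, 5 Mb); each patient draws
  ~1 + Poisson(6) background terms which are then propagated.
- **Planted pathway**: 10 genes, 20 carriers whose de novo CNV covers a
  pathway gene, target phenotype expressed with penetrance 0.9, and 5
  co-morbid phenotype terms at frequency 0.8 in carriers (pleiotropy
  mode; an alternative subtype mode elevates child terms of the target
  instead). Annotation resources carry one planted term per engine that
  exactly covers the pathway genes, plus random decoy terms.
- **Networks**: expression from a latent-factor model (module loading
  √r gives pairwise correlation ≈ r; planted module r = 0.9) plus ~150
  background modules of 6–14 genes at r ≈ 0.78 so the thresholded
  network has realistic size and a smooth degree distribution; the PPI
  is a Chung–Lu expected-degree graph over half the genome, plus
  planted edges among pathway genes and between pathway (bait) and
  extension genes.

What the generator does **not** emulate: recurrent CNV hotspots, LD
structure, realistic human coordinates, annotation-term overlap
hierarchy (terms are flat sets), and the breadth of real co-expression
structure. In particular, the per-group co-expression engine on the
bundled fixture is diluted by large pooled gene sets in a 2,000-gene
genome, so on the fixture most groups are detected by the annotation
engines; the co-expression machinery itself is tested directly on
planted modules. Passing tests therefore demonstrate correctness and
calibration of the machinery at desk scale, not performance on real
cohort data.

## Numerical and design choices

- Exactly 5 Mb is excluded ("shorter than" is strict).
- Empirical p-values use the +1/+1 estimator; permutation statistics are
  compared with a 1e-9 float tolerance on weight sums.
- Degree-matched sampling is exact per degree class (every seed gene's
  class contains at least itself); a log2-binned nearest-degree
  fallback exists for restricted sampling pools. Within a class,
  without-replacement draws use rejection when the draw is sparse
  relative to the class (collision-rare by the birthday bound) and
  row-wise permutations otherwise.
- Null statistics for cluster tests are computed sparsely as
  x'Ax/2 over membership indicators, so 10,000 samples are cheap.
- FDR families are (group × resource); the pipeline never corrects
  across the several hundred groups, and this is deliberate — users can
  re-pool from the per-test output.
- The fold-change is (k/n)/(K/N), reported as 0 when k = 0.
- Simulation sizes in tests: 200 null enrichment cohorts × 3 engines,
  500–600 null replicates for the permutation-p uniformity checks (with
  199-sample inner nulls), 100 replicates for each power analysis.
  These sizes keep every Monte-Carlo standard error well inside the
  asserted bands.

## Known limitations

- Rank-sum p-values on similarity pairs are descriptive (see above);
  only the binomial excess meta-test carries calibrated inference.
- Hypergeometric p-values are discrete, so BH is mildly conservative in
  small universes; the null per-family discovery rate sits slightly
  below the nominal 5%.
- The bait-extension randomisation conditions on in-network gene counts
  but not on gene length or local gene density beyond genomic
  contiguity.
- Enrichment treats annotation terms as flat sets; no parent-term
  propagation inside GO-like resources.
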