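# adenoconserv

Cross-genus conservation analysis of colonic-adenoma transcriptomes.

Mouse and rat strains carrying heterozygous nonsense alleles of the *Apc*
gatekeeper gene develop colonic adenomas, the precursor lesion of human
colorectal cancer. Comparing the tumor-vs-normal transcriptome of such
models with the human adenoma asks a sharp question: which expression
changes are *conserved* across three mammalian genera — and is that
conservation carried by individual orthologous genes, or by shared
functional categories whose member genes differ between genera?
`adenoconserv` implements that comparison end to end for anyone analysing
paired tumor/normal expression studies across species: differential
expression, ortholog linking, overlap permutation tests, gene-set
enrichment with dominant-category summaries, and the accompanying tumor
phenotype statistics. A synthetic-data generator with known ground truth
replaces the original microarray accessions, so every stage is testable
offline.

## The statistics at its core

**Paired differential expression.** Per gene, log2 intensity is modelled
additively in animal and tissue; on a balanced paired design the
tissue-factor F equals the squared paired t on within-animal differences
d_i = tumor_i − normal_i. Calls require both |d̄| ≥ log2(2) ("at least a
factor of 2, up or down") and Benjamini–Hochberg FDR ≤ 0.05.

**Mean-overlap fraction.** For gene (or enriched-category) lists
L_1 … L_k on a linked universe of N 1:1:1 orthologs, the statistic is the
average over ordered pairs of |L_i ∩ L_j| / |L_i|. Two permutation nulls
give its significance:

- *gene level*: each genus's list is redrawn uniformly from the universe
  with its size preserved, independently per genus; p = (r + 1)/(B + 1).
- *category level*: gene lists are held fixed (so gene-level agreement is
  held fixed) and the annotation is relabelled by one random bijection of
  the universe per replicate; the per-genus enriched-category lists are
  recomputed and compared.

**Standardized-hypergeometric enrichment.** A category with G universe
members, against a list of size m, has observed count X standardized as

    z = (X − mG/N) / sqrt( m (G/N)(1 − G/N)(N − m)/(N − 1) )

with a one-sided normal p. Enriched terms pass gates on z (or p), G, and
X; a greedy cover then orders them by decreasing numbers of list genes not
contained in a prior category — the "dominant category" view.

**Empirical-Bayes two-group model.** For normal epithelium of
tumor-bearing vs tumor-free colons, a log-normal/normal mixture with
gene-specific plug-in variances is fit by EM, yielding a DE mixing
proportion p̂ and per-gene posterior DE probabilities; calling uses the
soft posterior-FDR rule (largest prefix with mean posterior null mass
≤ 20%) plus the fold gate.

**Phenotype statistics.** Kruskal–Wallis and exact/asymptotic two-sided
Wilcoxon rank-sum tests for tumor multiplicities, Kaplan–Meier
product-limit curves and surviving fractions for 100-day survival, pooled
genotype means, and 2^ΔCT qPCR fold changes.

## Worked example

`examples/` holds one narrative script per capability. The central one,
`examples/04_category_enrichment_cover.py`, plants conservation *only* at
the category level — different member genes of the same categories are
differentially expressed in different genera — and prints:

```
gene-level overlap of TRUE up sets: 0.000
category-level observed overlap: 0.745, permutation p = 0.0050

dominant categories of the any-genus up list:
category_id  newly_covered  cumulative_covered
      C0001             26                  26
      C0007             25                  51
      C0006             19                  70
...
planted categories among dominant: 10 of 10
```

The true DE gene sets share nothing across genera (overlap 0.000), yet the
enriched-category lists agree at 0.745 — far beyond the annotation-shuffle
null (p = 1/(B+1) at B = 199) — and the greedy cover surfaces exactly the
ten planted categories. That is the package's core claim in miniature:
agreement between genera can be accentuated at the functional-category
level even when it is invisible gene by gene.

`examples/03_cross_genus_overlap.py` shows the complementary gene-level
planting (observed overlap 0.350 vs null mean 0.074, p = 0.001), and
`examples/05_tumor_counts_survival.py` the phenotype statistics, including
the pooled genotype means (3.3, 4.3), the 100-day survival fractions
(16.7%, 93.3%) and the 2^1.722 ≈ 3.30-fold qPCR enhancement.

A thin CLI wraps the same calls (`adenoconserv simulate / de / link /
conserve / enrich / phenostats / run-all`); `run-all` executes the whole
pipeline from a YAML config and writes TSV/JSON outputs plus a manifest
with checksums and per-stage seeds.

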