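# Methods

This note documents the statistical model behind `spindex`, the choices
made where the workflow left room for interpretation, what the synthetic
data generator does and does not emulate, and the package's known limits.

## The analysis model

The pipeline operates on exon-level integer read counts for a two-group
design (group A, the mutant/perturbed genotype, is always the fold-change
numerator; group B the control). Gene counts are defined as the sum of
the gene's exon counts, which keeps the two levels internally consistent
and makes the splicing-index identity below exact. Per-sample library
size is the column sum of gene-level counts over all annotated genes; the
same per-sample basis normalises both gene- and exon-level RPKM, so an
exon's RPKM and its gene's RPKM are directly comparable.

RPKM is `count * 1e9 / (length_bases * library_size)`. Gene length is
the length of the union of exon intervals (GTF convention: 1-based,
inclusive; exon length = end − start + 1); overlap resolution lives only
in the annotation layer — the simulator always emits disjoint exons.

### Threshold rules

Three count-denominated thresholds shape everything downstream. All are
configurable in `PipelineConfig`; the defaults are the analysis's
published operating point.

| rule | default | comparison |
|---|---|---|
| Reliable Quantification Threshold `k_quant` | 50 reads/gene | retained iff count ≥ 50 in ≥ 1 sample |
| gene replacement floor `k_floor_gene` | 10 reads | floored iff count ≤ 10 |
| exon replacement floor `k_floor_exon` | 1 read | floored iff count ≤ 1 |
| Venn detection threshold `k_det` | 10 reads | detected iff count > 10 |

"A minimum of ~50 reads" is implemented as an inclusive `count >= 50`;
the replacement rule as an inclusive `count <= k_floor`. The floor value
for an entity is the across-sample mean of the RPKM equivalent of
`k_floor` reads for that entity, so all floored cells of an entity carry
the same value and the operation is idempotent.

The gene-level detection threshold used by the Venn classification is not
pinned by the workflow this package descends from; the default here is
`k_det = 10` — a cell is "detected" exactly when it escaped the
replacement floor, on the reasoning that a floored cell carries no
quantitative evidence of expression. It is a plain parameter for users
who prefer another operating point. Relatedly, the published Venn class
counts that motivated this stage do not sum to the published detectable
total; the partition here is exact and exhaustive by construction
(`unique_A` / `unique_B` / `common` / `excluded`), and we make no attempt
to reproduce that bookkeeping discrepancy.

### Differential expression

Per gene, a one-way fixed-effects ANOVA with df (1, n_A + n_B − 2). The
analysis scale is log2 of post-replacement RPKM (the floor guarantees
positivity); the log scale stabilises the strong mean–variance coupling
of count-derived abundances and matches the clustering stage. A switch
(`de_log_scale=False`) runs the ANOVA on linear RPKM instead. The F
statistic is computed in closed form, vectorised over genes; with two
groups it equals the squared pooled-variance t, which the tests verify
against an independent implementation to 1e-10 relative tolerance.
Degenerate genes with zero within- and between-group variance get
F = 0, p = 1.

Fold change is the ratio of group-mean post-replacement RPKM (A/B),
always finite because the floor bounds both means away from zero, and
reported NA when the *raw-count* means of both groups are below
`k_quant` — a ratio of two unreliable abundances is not interpretable.
The DE call is strict: p < 0.05; the fold-change filter is two-sided
(FC ≥ 1.5 or ≤ 1/1.5) and NA never passes it. Up/down sets split the
fold-change-filtered list by direction, so
`|up| + |down| = |fc_filtered|` exactly. No gene-level multiple-testing
correction is applied to the call (the workflow's published criterion is
the raw p); a Benjamini–Hochberg column `p_adj_info` is emitted for
information only.

### Clustering

Differentially expressed genes (p < 0.05) are log2-transformed, each row
centred at its median, and clustered with centred (Pearson) correlation
similarity and average linkage (UPGMA), genes and samples both.
Distance = 1 − similarity. The linkage is implemented directly with the
Lance–Williams average update so two conventions are pinned down
deterministically: among equal-distance candidates the lexicographically
smallest pair of current cluster ids merges first, and the displayed leaf
order is a depth-first traversal placing the child that contains the
lower original row index first. Zero-variance rows (possible when every
cell was floored) are given similarity 0 to all others, with a warning,
rather than raising — mirroring Cluster 3.0's tolerance. Tests check the
merge heights against both a brute-force O(n³) re-scan and
`scipy.cluster.hierarchy.linkage`. Output follows the Java TreeView
`.cdt`/`.gtr`/`.atr` dialect.

### Splicing index

SI(e, s) = exon RPKM / gene RPKM on post-replacement abundances. Two
pre-filters: the exon's gene must be reliable, and the exon must have ≥ 1
read in ≥ 1 sample. SI is NA wherever the gene count is < 50 reads in
that sample. The per-exon test is a one-way ANOVA across genotypes on
the raw SI ratio (the statistic is defined as a plain quotient, so no log
is taken), plus a Tukey HSD contrast; with exactly two groups the Tukey
adjusted p equals the ANOVA p (q = √2·|t|, k = 2), and the code uses that
identity rather than evaluating the studentized-range distribution per
exon — tests confirm agreement with `scipy.stats.tukey_hsd` numerically.
Every statistic for an exon is NA as soon as any sample's SI is NA.

For a gene with disjoint exons and no floored or NA cells,
`sum_e SI(e,s) * len_e / gene_len = 1` holds exactly per sample, because
gene counts are exon sums over the same normalisation basis; the test
suite asserts it to 1e-10. The "top spliced genes" report ranks genes
with ≥ 10 analysed exons by their minimum exon p-value.

### Over-representation

Focus list: p < 0.05 and two-sided FC beyond 1.5×, intersected with the
universe. Universe: all genes passing the reliability threshold — the
detectable-gene background, not the whole annotation — because a gene
that could never have been called DE should not dilute the reference.
Per set: hypergeometric upper tail P(X ≥ k), i.e. the one-sided Fisher
exact test (a two-sided variant is exposed); BH adjustment across tested
sets (Bonferroni available); enriched ⇔ adjusted p < 0.05.

## The synthetic-data generator

`SimParams` defaults describe the emulated study: 2 genotype groups × 3
replicates, 19,000 genes, 4–12 exons per gene (mean 8), exon lengths
80–300 bp, gene baseline means log2-normal with mean 5 and SD 2 (median
32 expected reads — placing roughly half the genes above the 50-read
reliability rule, matching the detectable fraction of a typical
annotation), NB dispersion 0.05 (variance = μ + 0.05 μ², a typical
within-genotype biological variability for inbred mouse tissue),
library-size factors drawn U(0.8, 1.2), 5% DE genes with |log2 FC| in
(0.585, 3) (1.5× to 8×), 2% differential-exon-usage genes with one
affected exon at multiplier 3, and 2% boundary genes rescaled so their
expected maximum per-sample count lands in [30, 70], exercising both
sides of the 50-read rule.

Counts are NB draws with mean = exon baseline × group effect × exon
multiplier × library factor, where the exon baseline splits the gene mean
proportionally to exon length (so all exons of an undisturbed gene share
one SI expectation of 1). A gene is planted as DE *or* DEU *or*
boundary, never two of these, keeping the truth table unambiguous. The
same seed yields bit-identical output.

What the generator does **not** emulate: batch effects, GC/length bias,
positional read bias, correlated genes, isoform-level structure,
overlapping exons, outlier samples, or more than two groups. Passing
tests therefore demonstrate that the statistics behave as designed under
the model's own assumptions, not that the pipeline is robust to every
artefact of real sequencing data.

## Verification design and problem sizes

The verification suite runs at sizes chosen to make each property crisp:
oracle equivalences at 1,000 random ANOVA inputs, all ORA configurations
with universe ≤ 12 (against exhaustive enumeration), 50 random 8-leaf
linkage instances; null calibration at 5,000 genes with no planted
effects, where the fraction of gene-level p < 0.05 must sit within 3
binomial standard errors of 0.05 and exon-level p-values must pass a KS
uniformity check; planted-effect recovery at 2,000 genes with 10%
four-fold DE genes (sensitivity ≥ 0.9 among genes with expected baseline
≥ 200 reads, observed false-discovery proportion reported against truth)
and 5% DEU genes at multiplier 3 (Fisher enrichment of planted exons
among significant exons); and one full-scale 19,000-gene end-to-end run.
The null-calibration simulation draws expression high (log2 mean 8,
SD 1.5) so the replacement floors — which deliberately bias low-count
cells toward the floor value and are exercised separately by the
boundary-rule tests — rarely bind, isolating the ANOVA stage's
calibration.

## Numerical and degenerate-input choices

- Zero-length features and zero library sizes are errors, not NaNs.
- `anova_rows` with zero within-group variance and distinct means returns
  F = inf, p = 0 (a real, maximally confident difference).
- Correlations are clipped to [−1, 1] against floating-point drift.
- Empty inputs (no genes passing filters) flow through every stage and
  produce header-only outputs and a zeroed manifest rather than raising.
- All tables are UTF-8 TSV with a header row; NA is spelled `NA`.

## Limitations

- RPKM with a counted-reads denominator: the original total-mapped-reads
  library size is unavailable when starting from count matrices; column
  sums stand in. Fold changes and SI are insensitive to this choice;
  absolute RPKM values shift by a constant per-sample factor.
- The raw p < 0.05 DE criterion is intentionally uncorrected (matching
  the workflow this package packages); users wanting FDR control should
  filter on the provided `p_adj_info` column instead.
- n = 3 per group gives the ANOVA only 4 denominator df; power for
  subtle effects is limited, which the parameter-recovery tests quantify
  at their stated effect sizes.
- No moderated variance estimation (as in limma/DESeq2-style shrinkage);
  the package reproduces a classical per-gene ANOVA workflow faithfully
  rather than improving on it.
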