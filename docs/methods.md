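# Methods

## The classification problem

Pathogenic non-coding SNVs reported for monogenic Mendelian disease genes
cluster in proximal *cis*-regulatory regions: introns, 5'/3' UTRs and the
1 kb flanks around the transcription start and end sites of the affected
gene, with small minorities in downstream and intergenic space. The model
treats pathogenicity prediction as binary classification of a variant
against common human variants without clinical assertions, using purifying
selection signals at three sequence scales — the position itself, a window
around it, and the associated gene.

The classifier is gradient tree boosting: an ensemble of regression trees
built stepwise, each successive tree fit to the residuals of the current
ensemble, with a logistic objective so the score is a probability of class
membership (higher = more pathogenic-like). All features enter untransformed
(no normalisation or standardisation) — trees are invariant to monotone
feature rescaling.

## Annotation model

Coordinates are 1-based fully closed (VCF convention). Candidate labels are
computed per (variant, gene) against every transcript: exonic positions
inside the CDS, UTR5/UTR3 in exon parts 5'/3' of the CDS (strand-aware),
intronic between exons, splicing within 10 bp of an internal exon boundary
on either side (transcript termini are not splice junctions), and
upstream/downstream within 1 kb of the gene-extremal TSS/TSE. Positions
inside the transcript-hull of a gene but covered by no transcript are
intronic at the gene level. Non-coding RNA genes map onto ncRNA_exonic /
ncRNA_intronic / ncRNA_splicing, with their flanks collapsed to ncRNA_flank
(which ranks with the flanking tier, not the ncRNA tier — only
exon/intron/splice occupy that tier).

Resolution across genes: highest precedence tier wins; within the winning
tier, protein-coding candidates are preferred over ncRNA candidates, then
the gene with the shortest unsigned distance to its TSS or TSE (0 for
intragenic positions) is assigned; an exact distance tie across two or more
genes is `conflicting` and excluded. Variants beyond 1 kb of every gene are
intergenic and attached to the nearest protein-coding gene. Variants on a
chromosome with no annotated genes are dropped with a warning rather than
labeled: every downstream feature requires an associated gene.

Only the six region classes of protein-coding genes (intronic, UTR5, UTR3,
upstream, downstream, intergenic) are retained for scoring; everything else
is tallied per exclusion class.

## Features

- **Windowed allele-frequency statistics** use a 1 kb window, implemented as
  pos ± 500 bp inclusive, and always exclude any panel record at the query's
  own position, so the variant's own frequency never leaks into its feature
  vector. Expected heterozygosity is 2p(1−p) from the site's folded MAF.
  An empty window is *missing* (later imputed with training medians), never
  0 — zero would conflate "no data" with "extreme constraint".
- **GC/CpG** are computed over pos ± 75 bp (151 bases), truncated at
  chromosome edges; N bases are excluded from numerator and denominator,
  and the CpG denominator is the number of possible dinucleotide starts
  (L − 1). The window is stated as ±75 bp in one place and "150 bp" in
  another in the source material; the inclusive 151-base reading is used.
- **Position tracks** (conservation scores, B statistic, CDTS, neutrality-
  test percentiles, epigenetic signals) are consumed as sorted
  non-overlapping interval tracks; a position in a gap looks up as missing.
  Their computation from alignments or genotypes is out of scope.
- **Gene-level features** are joined by gene id; absent genes or missing
  values receive the column median computed once over the whole
  protein-coding gene universe (not per query batch).
- **Imputation of position/window features** uses medians of the *training
  rows only* — at scoring time each model imputes with the medians of its
  own training rows, so test statistics never inform training-time values.
- Both 1000G-style and GnomAD-style mean-MAF columns are computed from the
  single population panel the pipeline carries; at fixture scale they are
  identical columns, which gradient boosting tolerates (redundant features
  share splits).

## Cohort design

Common variants are those flagged COMMON with MAF > 0.05; rare variants are
unflagged with MAF < 0.01; everything else (including variants with no MAF)
is excluded. Positive curation applies four fail-closed filters in fixed
order — source/annotation gene agreement, monogenic Mendelian gene class,
phenotype consistency, zero homozygous carriers — with a per-step audit.
One positive per gene is kept (seeded random choice).

Protein-coding genes are split into k = 10 partitions, stratified by
chromosome and by positive-gene status, remainders dealt greedily to the
least-loaded partitions so per-stratum counts differ by at most one both
per chromosome and globally. Each positive draws 10 negatives without
replacement from common variants of the **same region class** whose genes
lie in the **same partition**, with at most one negative per gene cohort-
wide and no negative reused between positives. When a (region, partition)
cell lacks depth the sampler fails loudly naming the cell — borrowing from
other partitions would reopen the leakage path the design exists to close.

**Why stratify the partition on positive genes:** testing the permuted-label
null exposed a pooled-cross-validation artifact — if the positive counts
per partition are unbalanced, each model's positive base rate anti-
correlates with the positive count of the partition it scores, and pooling
the ten models' held-out scores yields AUROC well below 0.5 on pure noise
(≈0.30 in our tests). Equalising positive genes across partitions removes
the artifact; the null then sits at 0.5.

## Training and scoring

Ten XGBoost models (eta = 0.01, max_depth = 25, gamma = 10; exact tree
method, single thread for bitwise determinism), model i trained on all
cohort rows whose gene is outside partition i. The boosting-round budget is
not part of the published configuration; the default is 1000 rounds with
early stopping after 50 stagnant rounds on a 10% stratified internal
validation split of each model's training rows, both recorded in the bundle
provenance. No class weights (the 1:10 imbalance is by design) and no
row/column subsampling.

A variant is scored by the single model excluding its gene's partition; the
score is the model's probability output. Genes absent from the partition
map fall back to the mean of all ten models and are flagged. Each training
run stores per-model gene manifests; a leakage audit re-checks every scored
row against them. Feature importance is gain-based (total split-loss
reduction per feature), normalised per model, averaged across models and
summed per category; a model that grew no splits contributes a flat
profile.

The consistency diagnostic builds 11 partitions, reserves one, trains the
ten-model bundle on the rest and reports the pairwise Spearman correlation
of the ten models' scores on the reserved rows — the one context where a
variant receives ten scores.

## Evaluation

AUROC is the probability a random positive outranks a random negative with
ties counted 1/2; AUPRC is the step integral of the precision-recall curve
(not an interpolated grid average), so a constant score scores at the
positive prevalence. Region-bias tests reduce each (class, region) group to
its median score per gene, then compare groups with a two-sided Wilcoxon
rank-sum test — exact null distribution for tie-free groups up to size 25,
normal approximation with continuity correction otherwise. Spike-in
percentiles use standard competition ("1224") ranking:
rank = 1 + #(strictly greater), percentile = 100·(N − rank + 1)/N; the
paired pathogenic-vs-control comparison is a one-sided Wilcoxon signed-rank
test on per-variant median percentiles, returning p = 1 for the degenerate
all-zero-difference case. Fisher enrichment is one-sided ("greater") for
enrichment claims, with the sample odds ratio and a degenerate-margin flag.
Cross-source designs drop test rows whose genes overlap the training genes
(counted in the output) and then hard-fail on any residual overlap.

## The synthetic fixture

The generator emulates the study inputs, not their biology: random
nucleotide sequences at a set GC fraction; sequentially packed three-exon
protein-coding genes with UTR5/CDS/UTR3 structure on random strands;
non-coding RNAs half embedded inside coding introns (to exercise the ncRNA
precedence tier) and half standing alone between genes; one engineered
exactly-equidistant gene pair whose gap midpoint realises `conflicting`;
a Poisson-density allele-frequency panel with a Beta(0.5, 0.5) folded
spectrum, per-population log-normal jitter, derived-allele frequencies and
COMMON flags consistent with the MAF thresholds; interval tracks per
feature (per-100 bp bins for conservation, 10 bp for CDTS, coarse bins for
the 30 kb-scale neutrality tests, with ~1% gaps in conservation tracks to
exercise imputation); and a gene-level table with 5% missing holes outside
positive genes.

Positives are placed per the curated set's region mixture (intronic 23%,
UTR5 36%, UTR3 12%, upstream 26%, downstream and intergenic the remaining
~2%, largest-remainder rounding) in non-coding regions of distinct genes,
each placement verified by re-annotation. Planted signal is an additive
location shift in SD units of each track's baseline, oriented so that
pathogenic means more constrained (conservation up, B statistic and CDTS
down, neutrality percentiles up), clipped at natural bounds. Defaults:
category A = 2 SD, all others 0 — the conditions under which signal
recovery and bundle consistency are asserted. Setting every effect to zero
yields an exchangeable null (windowed allele-frequency features are never
planted; they act as realistic nuisance dimensions in both conditions).

**Scale.** Default: 2 chromosomes × 1 Mb, 360 protein-coding genes (+10%
ncRNAs), panel density 20/kb, 30 positives, 1:10 negatives. The driving
constraint is the cohort design itself: with at most one negative per gene,
n_pos × ratio distinct genes must exist with a common variant of the right
region class inside the right partition, which bounds n_pos ≤ n_genes/10
and requires the panel dense enough that ≥96% of genes carry a common UTR
variant. Thirty positives spread ≥2 per partition, enough for every model
to train on ≥27 positives, and the full pipeline (including the ten-seed
null) runs in minutes on one CPU.

What passing tests show — and do not show: the fixture has no linkage,
no coalescent history, no covariance between features (an optional
covariance hook exists in concept but the default is independence), and no
realistic relationship between allele frequency and conservation. Green
tests demonstrate that the machinery (annotation geometry, matching
constraints, leakage freedom, metric implementations) is correct and that
the learner recovers a planted signal of stated size; they say nothing
about real-data performance, which depends on licensed variant resources
the package deliberately does not ship.

## Known limitations

- Single-transcript fixture genes under-exercise multi-isoform UTR/CDS
  conflicts (the annotator supports them; tests cover them only via the
  hand-built gene set).
- The spike-in "individual genomes" are Bernoulli carrier draws over the
  common pool (carrier probability 1 − (1 − MAF)²), not phased genomes.
- `meanMAF1000G` duplicates `meanMAFGnomAD` at fixture scale (one panel).
- Enrichment thresholds use linear-interpolation quantiles of the reference
  positive scores; with small reference sets the threshold is sensitive to
  the quantile convention.
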