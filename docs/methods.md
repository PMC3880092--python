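# Methods

This note records the exact statistical and genomic conventions the package
implements, in the order of the pipeline.

## Expression ingest and variation filters

Datasets are genes × samples matrices of log2-scale intensities with at least
six samples. Probe-level platforms are collapsed to gene symbols by averaging
probes of the requested annotation grade (default "A"); probes mapping to
multiple symbols (`A /// B`) are dropped.

The coefficient of variation of a vector is the sample standard deviation
(n−1 denominator) divided by the mean; it is undefined at mean zero. Two
filters select informative datasets:

* **reference-set filter** — keep a dataset when the mean CV over the
  reference (module) genes present in it is ≥ `min_cv` (default 0.30);
  genes with constant values are excluded from the mean rather than counted
  as zero.
* **single-gene filter** — keep a dataset when one gene's CV is ≥ `min_cv`
  (default 0.05); datasets not measuring the gene are excluded.

## Correlation meta-analysis

For a candidate gene and a reference module, each retained dataset
contributes the mean Pearson correlation of the candidate with the module
genes measured in that dataset (the candidate's self-correlation is dropped
when it belongs to the module; constant vectors are excluded, not
zero-filled). The candidate's aggregate score is the **unweighted mean of the
per-dataset means** — genes first, then datasets — so one large study cannot
dominate the aggregate. Candidates are ranked by score, ties broken
lexicographically. The same machinery produces averaged gene–gene correlation
matrices (unit diagonal, NaN where no dataset measures a pair) and
genome-wide profiles of a single reference gene.

## Clustering

Gene–gene correlation matrices are clustered with agglomerative hierarchical
clustering (complete linkage by default) and cut into *k* clusters, mirroring
R's `hclust`/`cutree`. Two row distances are supported: Euclidean distance
between correlation-matrix rows (default) and `1 − r` directly. Missing
cells are imputed as 0 with a warning. Cluster summaries report the mean
within-cluster correlation (NaN for singletons) and, for each cluster pair,
the fraction of one cluster's genes whose mean correlation to the other
cluster is negative.

## Hypergeometric over-representation

For a study list of *n* genes drawn from a universe of *N*, a term with *K*
members and *k* study hits is scored by the upper-tail probability
P(X ≥ k) of the hypergeometric distribution, computed in log space
(`logsf`) for numerical stability; *k* = 0 returns 1. Term tables report
`term, ExpCount = nK/N, Count, Size, p`, sorted by p then term name. The
regulator screen tests each candidate's top-500 correlated genes and retains
candidates with a keyword-matching term at p ≤ 0.001; cross-species
confirmation intersects screen hits case-insensitively (or through an
explicit symbol map).

## Pre-ranked GSEA

Given a gene list ranked by descending score, the running sum steps up by
|score|^w (normalized over the set's hits; equal weights when all hit scores
are zero) at set members and down by 1/(N − N_h) at non-members. The
enrichment score is the signed value at the maximum absolute deviation; the
peak is reported 1-based, and the leading edge contains the set members at or
before a positive peak (at or after a negative one). Significance uses a
gene-set permutation null: random same-size sets are drawn from the list and
the nominal p is the fraction of **same-signed** null scores whose magnitude
reaches the observed one, among same-signed nulls (the standard pre-ranked
convention; conditioning on sign keeps the statistic one-sided on each side).

## Four-condition differential expression

The design is a 2×2 factorial (WT, WT+stimulus, KO, KO+stimulus, ≥ 2
replicates each) on log2 values. Preprocessing computes one global standard
deviation over the whole matrix (`sd_unit`), masks genes whose replicate
means are below `sd_unit` in all four conditions, and floors remaining
values at `sd_unit`.

Each two-group contrast reports the log2 fold change (difference of means)
and a p value from a t test gated by a **two-sided variance-ratio F test**
(larger variance on top, two-sided by doubling the tail, α = 0.05): pooled
Student when the variances are compatible, Welch otherwise. Degenerate cases:
two zero-variance groups give p = 1 for equal means and p = 0 otherwise; one
zero-variance group forces Welch. P values are adjusted by
Benjamini–Hochberg; fold changes with adjusted p strictly greater than α are
set to zero.

Regulation categories come from the sign pattern of the two zeroed stimulus
contrasts (WT+stim vs WT; KO+stim vs KO):

| category  | WT contrast | KO contrast |
|-----------|-------------|-------------|
| I         | > 0         | = 0         |
| II        | ≥ 0         | < 0         |
| III       | < 0         | < 0         |
| unchanged | all other patterns        |

### Expected error floor of the category classifier

With BH control at FDR 0.05 and two contrasts of ~270 genes each, a handful
of null contrasts are expected to pass in every run; each false positive can
flip one gene's sign pattern into a neighbouring category. Measured over 20
generator seeds at the default effect size 2.0 and noise 0.05, accuracy
averages ≈ 0.985 (minimum ≈ 0.963, occasionally 1.000). This is a property
of FDR-controlled inference, not an implementation defect: the classifier is
exactly as accurate as its contrasts. Acceptance reporting therefore
documents accuracy as a distribution (98–100 %) rather than a constant.

## ChIP-seq peak integration

Peaks are 0-based, half-open intervals (BED convention); touching endpoints
do not overlap. **Consistent peaks** across replicate time points are regions
where one peak from *every* input set covers a common base (mutual overlap,
not pairwise chaining); each such region is reported as the union span of all
contributing peaks, with overlapping spans merged. Peaks are assigned to
genes whose strand-aware TSS lies within an inclusive window (default
±5,000 bp) of the peak center `floor((start+end)/2)`; distances are signed
5′→3′ on the gene's strand. Bound-gene sets are tested for target-annotation
enrichment against a fixed universe (default 23,563 unique symbols).

Enhancer states are called per region from histone-mark/pioneer-factor
overlap flags, in precedence order: pre-existing H3K27ac → **active**;
otherwise pre-existing H3K4me1 → **poised** (**poised_activated** when
H3K27ac appears post-stimulus); otherwise a region devoid of all three marks
pre-stimulus that gains H3K4me1 → **latent**; anything else → **other**.
A mark gain is *factor-dependent* when it appears post-stimulus in wild-type
but not in knockout cells.

## Motif scanning

IUPAC consensus matching is positional: each pattern symbol's IUPAC class
must contain the sequence base (pattern `N` accepts anything including the
unknown base `N`; a sequence `N` matches only pattern `N`), with an optional
mismatch allowance (0 by default). Reverse-strand matches — the pattern's
reverse complement read on the forward strand — are reported at their
forward-strand offsets; positions matching on both strands (every hit of a
palindromic consensus such as `TTCNNNNGAA`) are reported once, on "+".
Promoter windows are ±2 kb of the strand-aware TSS, pulled from an indexed
FASTA, clipped to chromosome bounds (logged) and reverse-complemented for
minus-strand genes.

## Synthetic-data conventions

All generators use `numpy.random.default_rng(seed)` and are pure functions of
their config. The regulator generator plants a latent per-sample activity
added to the regulator's measured row and, in a configurable fraction of
"active" datasets, scaled into the module rows — reproducing the
context-dependence that motivates the meta-analysis. The genome generator
plants one motif instance per promoter (strand-aware placement), reproducible
TF peaks with small per-timepoint jitter near bound-gene TSSs, per-timepoint
decoy peaks at mutually disjoint positions (so the consistency merge must
remove them), and mark peaks directly on the TF-peak intervals so that the
planted active / poised / latent configurations are recoverable end-to-end.
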