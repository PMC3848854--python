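# Methods

This note documents the models, conventions, parameters and design
choices behind `paseq`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and conventions

All internal coordinates are 0-based half-open (BED native); SAM and
wiggle are converted at the I/O boundary. A *cleavage position* is the
last transcribed base before the poly(A) tail. The downstream window of
a site on the sense strand is therefore `[mode+1, mode+21)` on '+' and
the reverse complement of `[mode-20, mode)` on '−'. Motif windows of
width 100 cover sense offsets −50..+49 with the mode at offset 0.

When deriving cleavage sites from paired-end alignments, the strand of
read 1 is taken as the transcript strand (library-level strand
correction is assumed to have happened before alignment); a '+' fragment
spanning `[s, e)` cleaves at `e−1`, a '−' fragment at `s`. Optional
deduplication collapses identical fragment endpoints to one tag,
mirroring the all-fragments versus non-redundant analysis pair.

## Cluster calling

The caller is a deterministic Gaussian-kernel density estimator (an
F-seq-style feature-density approach with all parameters exposed):

- tags on each (contig, strand) are smoothed with a Gaussian kernel,
  bandwidth σ = 10 nt by default;
- the threshold is the uniform-background null: spreading the strand's
  *N* tags evenly over a contig of length *L* gives rate λ = *N/L* per
  nt, and under Poisson sampling the smoothed density has variance
  λ·∫k² = λ/(2σ√π); the threshold is λ + 4·√(λ/(2σ√π));
- maximal runs above threshold become candidates, resized to the 95%
  core: the *shortest* genomic window holding ≥ 95% of the candidate's
  tags (ties: smaller width, then leftmost start; verified against
  exhaustive window enumeration). The mode is the maximal-count
  position inside the core, ties broken 5′-most on the cluster strand;
- filter order is resize → minimum 50 tags (on the core) → internal
  priming (≥ 15 A in the 20 sense-strand nt downstream of the mode; 'N'
  never counts; a window running off the contig keeps the cluster with
  a warning) → shape classification. Applying the tag threshold to the
  reported core keeps the filter and the reported counts consistent;
- shape: f = fraction of core tags within ±2 nt of the mode; NP if
  f ≥ 0.5 and span < 10, BP if f ≥ 0.5 and span ≥ 10, else WP. The ±2
  window and the span cut are parameters (a ±5 variant is sometimes
  used for positional motif contrasts).

Per-tissue counts are tallied inside the final core bounds, so the
cluster total always equals the sum over tissues.

## Annotation

Assignment is anchored at the cluster mode (the cluster's defining
position), strand-matched only, and takes the highest-priority region
over all transcripts: PA (annotated transcript 3′ end ±10 nt) > 3′ UTR >
extended 3′ UTR (1 kb downstream of the transcript 3′ end) > exon >
intron > 5′ UTR > TSS (5′ end ±10 nt) > promoter (250 nt upstream);
otherwise intergenic, with a `distant` flag for modes > 500 nt from
every transcript span. For coding transcripts the exon category means
the *coding* portion of exon blocks: UTR bases always lie inside exon
blocks, so a literal any-exon region would make the lower-priority
5′ UTR category unreachable; for non-coding transcripts full exon
blocks count.

## Tissue specificity

Counts are scaled per tissue to tags per million of the tissue's
library, then quantile normalized. Quantile normalization replaces each
column's sorted values with the across-column mean order statistics;
tied input values receive the mean of their run of reference values.
Note a structural consequence: on tie-free data the defining property
(identical sorted column multisets) and idempotency hold exactly, while
tied runs (e.g. zeros in count data) are averaged, perturbing the
multisets slightly — the same behavior as the standard R implementation
with tie handling enabled.

For each cluster with positive total, relative usages p_t give
H = −Σ_{p_t>0} p_t log2 p_t (bits) and Q_t = H − log2 p_t where
p_t > 0 (undefined otherwise; no pseudocount is added, so zero-usage
tissues simply drop out — this avoids inventing a smoothing constant).
Q_t is minimal for the most-used tissue, so the specific call names
argmin Q. Thresholds are computed from the dataset itself: specific
iff H < median(H) − 2·sd(H) and min_t Q_t < median(Q) − 2·sd(Q) (Q
pooled over all defined values); constitutive iff H > mean(H) + 2·sd(H)
and min_t Q_t > mean(Q) + 2·sd(Q) with Q defined in every tissue. All
four cutoffs are overridable parameters. Tissue *usage* is a separate,
cruder call: a cluster is utilized in a tissue iff its normalized count
strictly exceeds that tissue's column median.

Two-way clustering of the specific set uses 1 − Pearson distance with
average (UPGMA) linkage on log2(x+1) values; zero-variance rows are
excluded (their correlation is undefined). Dendrograms are serialized
as Newick with branch length = parent merge height − child merge
height.

## 3′ UTR shortening

Genes are consolidated before any UTR statistic: same-strand
overlapping genes are removed (both parties), as are genes whose
transcripts disagree on the stop codon; non-coding genes are skipped.
The annotated UTR length runs from the shared stop-codon boundary to
the most distal transcript 3′ end (the distal choice keeps USI ≥ 0 for
intra-UTR clusters). A cluster's implied UTR length L_i runs from the
stop-codon boundary to the cluster mode (L = 1 for a mode at the first
UTR base). C_i are per-million library-scaled counts: the per-million
layer is monotone-linear within each tissue, so within-gene usage
ratios — the quantity the effective length averages — are exactly
preserved, while cross-tissue expression comparisons remain normalized.
(Quantile-normalized counts would distort low-count within-gene ratios.)

Effective length and USI per gene per tissue follow the weighted-mean
definition above; a tissue with zero counts on a gene's clusters is
undefined and excludes the gene from that tissue's ranking. For the
grid, only genes defined in every tissue enter; expression and
effective length are each ranked 1..T low-to-high with ties broken by
the fixed tissue order (deterministic), genes are counted per tissue in
B × B rank boxes (B = T by default; coarser binning maps rank bins by
floor((rank−1)·B/T)), and the null permutes each gene's tissue labels
independently with the (expression, length) pair travelling together —
the minimal exchangeability null, preserving each gene's rank multiset
exactly. Z = (observed − permutation mean)/permutation SD; boxes with
zero SD report 0 where observed equals the mean and are otherwise
missing. P = 1000 permutations by default, seeded.

## Motifs and information content

Enrichment counts k-mer occurrences at every valid start position
(window width − k + 1 per window; starts covering an 'N' are skipped;
overlapping occurrences all count) in foreground windows versus a
background of random intergenic windows (4000 × 100 nt by default,
sampled outside gene spans ± 1 kb). Each k-mer gets a one-sided
binomial p-value for the foreground occurrence count at the background
rate; k-mers absent from the background use a conservative rate of one
occurrence over the background start count so p stays in (0, 1].
Positional profiles report occurrences per bin divided by the number of
windows (so a motif present once in every window peaks at frequency 1).
Information content per column is 2 + Σ_b f_b log2 f_b over observed
A/C/G/T frequencies, Ns excluded; no small-sample correction is applied
by default.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the pipeline
assumes, not raw sequencing: it starts at cleavage coordinates (no
reads, errors or alignment).

- **Genome and genes:** 2 contigs × 2 Mb at GC 0.41; 300 genes, each
  with a 200-nt 5′ UTR, a CDS (1.0–1.8 kb genomic) interrupted by one
  500-nt intron, and a 3′ UTR of 300–3000 nt; roughly half carry a
  second transcript with a shorter 3′ end (same stop codon; 5% of genes
  get a discordant stop to exercise consolidation), and four same-strand
  overlapping gene pairs are planted for the overlap filter.
- **PA sites:** 1–3 per gene (spacing ≥ 200 nt within the UTR, the
  distal site 50 nt from the annotated end). Shape mix
  0.45/0.43/0.12 narrow/broad/dispersed. Emission offsets from the
  planted mode: narrow = round N(0, 1); broad = 0.6·round N(0, 1) +
  0.4·U[−15, 15]; dispersed = 0.3·round N(0, 2) + 0.7·U[−15, 15].
  The mixtures are chosen so the three classes match the NP/BP/WP
  definitions in expectation (within-±2 fractions ≈ 0.95/0.64/0.35)
  while every shape retains a single most-frequent position — a pure
  uniform emission would have no recoverable mode at all.
- **Counts:** per gene and tissue, the total is negative-binomial with
  dispersion 0.3 around the sum of the gene's site means (40 tags per
  site per tissue, times a per-tissue library multiplier drawn from
  [0.5, 2.0]); the split among the gene's sites is multinomial given
  the total. Overdispersion therefore acts at the gene × tissue level
  (expression noise) while within-gene site usage is sampling noise —
  the hierarchical structure real tag counts show, and the only reading
  under which planted within-gene usage signals are recoverable at the
  stated dispersion.
- **Tissue specificity:** 10% of sites give one dominant tissue a 0.9
  usage share (rest uniform).
- **Shortening coupling:** ~10% of genes (multi-site, non-specific
  ones) designate a shortening-prone tissue — drawn from two
  tissues by default, mirroring the tissue-preferential shortening the
  generator emulates — in which 80% of the gene's tags move to the
  proximal site and expression rises 4-fold.
- **Artifacts:** 30 narrow sites on planted A-rich tracts (18 A in the
  downstream 20-mer), half intergenic and half intronic, so their
  removal must come from the A filter, not from annotation. Genuine
  sites get a downstream 20-mer capped at ≤ 8 A and an AATAAA hexamer
  planted 21 nt upstream of the mode on the sense strand.

Identical seeds give byte-identical output files. What passing tests on
this generator do **not** show: robustness to mis-stranded fragments,
overlapping/merged clusters closer than 200 nt, chimeric or antisense
transcription, UTR annotations that disagree with the data, or
heavy-tailed library artifacts beyond NB noise — real-data behavior on
those axes is untested.

## Numerical and degenerate-input choices

- Core resizing accepts singleton inputs; the empty profile returns an
  empty cluster list with a log line.
- All-zero matrix rows are excluded from entropy analysis; all-zero
  library columns are dropped with a warning; fewer than 10 usable rows
  triggers a threshold-reliability warning, fewer than 20 eligible
  genes a grid warning.
- Grid Z-scores use population SD over permutations; sub-seeds derived
  in the acceptance script stay below 2³¹.
- Problem sizes throughout (300 genes, 13 tissues, 1000 permutations,
  1000 oracle maps, 4000 background windows) are chosen so the full
  validation runs in seconds on one core while every planted structure
  is estimated from ≥ 20–500 instances.

## Known limitations

- The density caller is not F-seq; it reproduces well-separated sites
  under any reasonable bandwidth but has no fragment-length model.
- Quantile normalization with tie averaging perturbs tied runs (see
  above); analyses that depend on within-gene count ratios use the
  per-million layer instead.
- The entropy thresholds are distribution-derived; datasets whose H/Q
  distributions are not unimodal-with-outliers may need the exposed
  threshold overrides.
- The annotation scheme is transcript-based and strand-matched;
  antisense overlap is deliberately ignored.
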