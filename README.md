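# paseq

Cluster calling and downstream analysis for 3′-end polyadenylation
sequencing (PA-seq style) data: from per-base cleavage-site counts to
polyadenylation (PA) clusters, genomic annotation, tissue-specificity
calls, 3′ UTR shortening statistics and sequence-motif profiles — with a
synthetic multi-tissue data generator whose planted ground truth
validates every stage.

## The problem

3′-end sequencing protocols read the exact base at which a transcript is
cleaved and polyadenylated. Most genes use several such sites
(alternative polyadenylation, APA), changing 3′ UTR length and thereby
transcript stability, localization and translation. Turning raw
per-base cleavage counts into biology requires a chain of specific
computations, each with sharp conventions:

- **PA clusters.** Cleavage positions are pooled across tissues,
  kernel-density peaks become candidate clusters, each cluster is
  resized to the shortest window holding 95% of its tags, clusters with
  fewer than 50 tags are dropped, and clusters whose sense-strand 20 nt
  downstream of the mode (the most frequent position) contain ≥ 15
  adenosines are removed as oligo(dT) internal-priming artifacts.
  Surviving clusters are classified by shape: **NP** (narrow peak,
  ≥ 50% of tags within ±2 nt of the mode, span < 10 nt), **BP** (broad
  with peak, ≥ 50% within ±2 nt, span ≥ 10 nt) and **WP** (weak peak,
  everything else).
- **Annotation.** Each cluster mode gets the highest-priority genomic
  category: PA (annotated 3′ end ±10) > 3′ UTR > extended 3′ UTR (1 kb
  downstream) > exon > intron > 5′ UTR > TSS (±10) > promoter (250 nt
  upstream), else intergenic.
- **Tissue specificity.** The clusters × tissues count matrix is
  library-size scaled to tags per million and quantile normalized. Per
  cluster, relative usages *p*ₜ give the Shannon entropy
  *H* = −Σ *p*ₜ log₂ *p*ₜ and per-tissue scores *Q*ₜ = *H* − log₂ *p*ₜ;
  clusters with *H* and min *Q*ₜ below (median − 2 SD) are called
  tissue-specific, those with both above (mean + 2 SD) constitutive.
- **3′ UTR shortening.** For consolidated genes (same-strand overlaps
  removed, one shared stop codon) with UTR clusters at distances *Lᵢ*
  from the stop codon carrying counts *Cᵢ*:
  Effective_UTR_Length = Σ(*Cᵢ* · *Lᵢ*)/Σ*Cᵢ* and
  USI = Annotated_UTR_Length − Effective_UTR_Length.
  Per gene, expression and effective length are ranked across tissues;
  per tissue, genes are counted in rank × rank boxes and scored against
  a per-gene label-permutation null (Z-scores).
- **Motifs.** 6-mer occurrence enrichment in 100-nt windows around
  cluster modes versus random intergenic background (one-sided binomial,
  p < 10⁻⁵), positional frequency profiles (100 or 20 bins), and
  per-position information content (2 + Σ *f*ᵦ log₂ *f*ᵦ bits).

Real tissue panels at sequencing scale are not required: the
`simulate` module generates a toy genome with planted PA sites of all
three shapes, tissue-biased usage, negative-binomial count noise,
library-size variation, A-rich internal-priming artifacts and a planted
shortening coupling, so every stage can be scored against known truth.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_call_clusters.py
```

prints (seed 1):

```
simulated 574 genuine PA sites ({'narrow': 244, 'broad': 264, 'dispersed': 66})
  across 300 genes and 13 tissues, plus 30 A-rich priming artifacts
called 574 clusters: NP 244 (42.5%), BP 264 (46.0%), WP 66 (11.5%)
recovery vs truth: sensitivity 1.000, mean |mode error| 0.06 nt, 0 false clusters
internal-priming filter removed 30/30 planted A-rich artifacts
```

Every planted site is recovered with its mode within a base or two, the
shape classes match the planted emission shapes, and the A-content
filter removes exactly the planted artifacts. Continuing with
`03_annotate.py` … `06_motifs.py` reproduces the downstream analyses:
95% of planted tissue-specific sites are called specific to the correct
tissue, the two shortening-prone tissues show corner-box Z-scores of
+5.2 and +6.3 in the rank-enrichment grid, and AATAAA is the
top-enriched 6-mer, peaking 21 nt upstream of the cleavage mode.

The same stages are available as a CLI (`paseq simulate`, `paseq call`,
`paseq all …`) for running on external data in the documented formats
(FASTA genome, BED12 + gene-map models, BED6 cleavage dialect or SAM).

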