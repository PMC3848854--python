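"""Genomic category assignment for PA clusters and distance statistics.

A cluster is anchored at its mode and receives the highest-priority
category whose region contains the mode over all same-strand
transcripts:

    PA > UTR3 > Extended_UTR3 > Exon > Intron > UTR5 > TSS > Promoter

with PA = annotated transcript 3' end +/- 10 nt, Extended_UTR3 = 1 kb
downstream of the transcript 3' end, TSS = transcript 5' end +/- 10 nt
and Promoter = 250 nt upstream of the TSS.  Anything else is
Intergenic; modes more than 500 nt from every annotated transcript span
are additionally flagged distant.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .formats import GeneModel, TranscriptModel

CATEGORIES = ("PA", "UTR3", "Extended_UTR3", "Exon", "Intron", "UTR5",
              "TSS", "Promoter", "Intergenic")
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

#: categories counted as "clusters of a gene" in per-gene summaries
GENIC_CATEGORIES = ("PA", "UTR3", "Extended_UTR3", "Exon", "Intron", "UTR5")


@dataclass
class AnnotationParams:
    pa_flank: int = 10          # nt either side of the annotated 3' end
    extended_utr3: int = 1000   # nt downstream of the transcript 3' end
    tss_flank: int = 10
    promoter: int = 250
    distant_cutoff: int = 500


@dataclass
class CategoryAssignment:
    cluster_id: str
    category: str
    gene_id: str | None
    distant_flag: bool


def _transcript_regions(t: TranscriptModel, p: AnnotationParams):
    """Yield (category, start, end) half-open mode-containment regions."""
    three = t.three_prime_end
    five = t.five_prime_end
    yield ("PA", three - p.pa_flank, three + p.pa_flank + 1)
    utr3 = t.utr3_interval()
    if utr3:
        yield ("UTR3", *utr3)
    if t.strand == "+":
        yield ("Extended_UTR3", t.tx_end, t.tx_end + p.extended_utr3)
    else:
        yield ("Extended_UTR3", t.tx_start - p.extended_utr3, t.tx_start)
    # for coding transcripts the Exon category means the coding portion:
    # UTR bases also sit in exon blocks, and with Exon ranked above UTR5
    # a literal any-exon region would make the UTR5 category unreachable
    for s, e in t.exons:
        if t.is_coding:
            s, e = max(s, t.cds_start), min(e, t.cds_end)
            if s >= e:
                continue
        yield ("Exon", s, e)
    yield ("Intron", t.tx_start, t.tx_end)  # span minus exons, checked below
    utr5 = t.utr5_interval()
    if utr5:
        yield ("UTR5", *utr5)
    yield ("TSS", five - p.tss_flank, five + p.tss_flank + 1)
    if t.strand == "+":
        yield ("Promoter", t.tx_start - p.promoter, t.tx_start)
    else:
        yield ("Promoter", t.tx_end, t.tx_end + p.promoter)


def assign_category(cluster, genes: list[GeneModel],
                    params: AnnotationParams | None = None) -> CategoryAssignment:
    """Assign one cluster; ``cluster`` needs contig/strand/mode/cluster_id."""
    params = params or AnnotationParams()
    mode = cluster.mode
    best_cat, best_gene = "Intergenic", None
    min_dist = None
    for gene in genes:
        if gene.contig != cluster.contig or gene.strand != cluster.strand:
            continue
        for t in gene.transcripts:
            d = max(t.tx_start - mode, mode - (t.tx_end - 1), 0)
            min_dist = d if min_dist is None else min(min_dist, d)
            for cat, s, e in _transcript_regions(t, params):
                if not s <= mode < e:
                    continue
                if cat == "Intron" and any(es <= mode < ee for es, ee in t.exons):
                    continue
                if _PRIORITY[cat] < _PRIORITY[best_cat]:
                    best_cat, best_gene = cat, gene.gene_id
    distant = min_dist is None or min_dist > params.distant_cutoff
    return CategoryAssignment(cluster_id=cluster.cluster_id, category=best_cat,
                              gene_id=best_gene, distant_flag=distant)


def assign_categories(clusters, genes: list[GeneModel],
                      params: AnnotationParams | None = None) -> list[CategoryAssignment]:
    by_key: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_key[(g.contig, g.strand)].append(g)
    return [assign_category(c, by_key.get((c.contig, c.strand), []), params)
            for c in clusters]


@dataclass
class PerGeneSummary:
    counts: dict[str, int]              # gene_id -> number of clusters
    mean_clusters_coding: float
    mean_clusters_ncrna: float
    frac_multi_coding: float
    frac_multi_ncrna: float


def clusters_per_gene(assignments: list[CategoryAssignment],
                      genes: list[GeneModel]) -> PerGeneSummary:
    """Cluster counts per gene over the genic categories, summarised
    separately for coding genes and ncRNAs (genes with no assigned
    cluster do not enter the means)."""
    coding = {g.gene_id: g.coding_flag for g in genes}
    counts: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.gene_id is not None and a.category in GENIC_CATEGORIES:
            counts[a.gene_id] += 1

    def summarise(ids):
        vals = [counts[g] for g in ids]
        if not vals:
            return float("nan"), float("nan")
        return (float(np.mean(vals)),
                float(np.mean([v >= 2 for v in vals])))

    coding_ids = [g for g in counts if coding.get(g, False)]
    nc_ids = [g for g in counts if not coding.get(g, True)]
    mc, fc = summarise(coding_ids)
    mn, fn = summarise(nc_ids)
    return PerGeneSummary(counts=dict(counts), mean_clusters_coding=mc,
                          mean_clusters_ncrna=mn, frac_multi_coding=fc,
                          frac_multi_ncrna=fn)


@dataclass
class DistanceResult:
    distances: np.ndarray        # one per query site; NaN where no target
    n_missing: int
    frac_zero: float
    frac_within_5: float

    def histogram(self, bins) -> tuple[np.ndarray, np.ndarray]:
        d = self.distances[~np.isnan(self.distances)]
        return np.histogram(d, bins=bins)


def distance_to_reference(query_sites, target_sites) -> DistanceResult:
    """Minimum absolute distance from each query site to the nearest
    target on the same contig and strand.

    Sites are (contig, strand, position) triples.  With queries =
    reference and targets = observed this measures coverage of the
    reference; swapped, it measures precision of the observed calls.
    """
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for contig, strand, pos in target_sites:
        by_key[(contig, strand)].append(pos)
    sorted_targets = {k: np.sort(np.array(v, dtype=np.int64))
                      for k, v in by_key.items()}
    out = []
    for contig, strand, pos in query_sites:
        targets = sorted_targets.get((contig, strand))
        if targets is None or targets.size == 0:
            out.append(np.nan)
            continue
        i = int(np.searchsorted(targets, pos))
        cands = []
        if i < targets.size:
            cands.append(abs(int(targets[i]) - pos))
        if i > 0:
            cands.append(abs(pos - int(targets[i - 1])))
        out.append(min(cands))
    arr = np.array(out, dtype=float)
    defined = arr[~np.isnan(arr)]
    n_missing = int(np.isnan(arr).sum())
    return DistanceResult(
        distances=arr, n_missing=n_missing,
        frac_zero=float(np.mean(defined == 0)) if defined.size else float("nan"),
        frac_within_5=float(np.mean(defined <= 5)) if defined.size else float("nan"))


def write_assignment_table(assignments: list[CategoryAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcategory\tgene_id\tdistant_flag\n")
        for a in assignments:
            fh.write(f"{a.cluster_id}\t{a.category}\t{a.gene_id or '.'}\t"
                     f"{int(a.distant_flag)}\n")
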