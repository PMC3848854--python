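"""3' UTR shortening index (USI) and the tissue rank-enrichment grid.

Genes are consolidated (same-strand overlapping genes removed, all
transcripts must share one stop codon), their 3'-UTR PA clusters are
collected with UTR-implied lengths L_i (stop-codon boundary to cluster
mode) and per-tissue counts C_i, and per tissue:

    Effective_UTR_Length = sum(C_i * L_i) / sum(C_i)
    USI                  = Annotated_UTR_Length - Effective_UTR_Length

For the grid, each gene's expression (sum of C_i) and effective length
are ranked low-to-high across tissues; per tissue, genes are counted in
(expression rank, length rank) boxes, and a permutation null (each
gene's tissue labels independently shuffled, the (expression, length)
pair travelling together) yields a Z-score per box.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import CategoryAssignment
from .formats import GeneModel

UTR_CATEGORIES = ("PA", "UTR3", "Extended_UTR3")


@dataclass
class UTRCluster:
    cluster_id: str
    length: int                       # L_i, nt from stop codon boundary to mode
    counts: dict[str, float]          # per-tissue normalized C_i


@dataclass
class ConsolidatedGene:
    gene_id: str
    strand: str
    stop_boundary: int
    annotated_utr_length: int
    utr_clusters: list[UTRCluster] = field(default_factory=list)


def consolidate_genes(genes: list[GeneModel]) -> tuple[list[ConsolidatedGene], dict]:
    """Keep coding genes that neither overlap another same-strand gene
    nor carry transcripts with discordant stop codons.

    Annotated UTR length runs from the shared stop-codon boundary to the
    most distal transcript 3' end.
    """
    log = {"overlap_removed": 0, "stop_mismatch_removed": 0, "noncoding_skipped": 0}

    overlapping: set[str] = set()
    by_key: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_key[(g.contig, g.strand)].append(g)
    for group in by_key.values():
        # sweep left to right; any gene starting before the running max
        # end overlaps the gene holding that end (both parties removed)
        max_end, holder = -1, None
        for g in sorted(group, key=lambda g: g.span):
            if g.span[0] < max_end:
                overlapping.update((g.gene_id, holder))
            if g.span[1] > max_end:
                max_end, holder = g.span[1], g.gene_id

    out = []
    for g in genes:
        if not g.coding_flag:
            log["noncoding_skipped"] += 1
            continue
        if g.gene_id in overlapping:
            log["overlap_removed"] += 1
            continue
        stops = {t.stop_boundary for t in g.transcripts if t.is_coding}
        if len(stops) != 1:
            log["stop_mismatch_removed"] += 1
            continue
        stop = stops.pop()
        if g.strand == "+":
            distal = max(t.tx_end for t in g.transcripts)
            ann_len = distal - stop
        else:
            distal = min(t.tx_start for t in g.transcripts)
            ann_len = stop - distal
        out.append(ConsolidatedGene(gene_id=g.gene_id, strand=g.strand,
                                    stop_boundary=stop,
                                    annotated_utr_length=ann_len))
    return out, log


def attach_utr_clusters(consolidated: list[ConsolidatedGene],
                        assignments: list[CategoryAssignment],
                        clusters, counts: pd.DataFrame) -> list[ConsolidatedGene]:
    """Populate each consolidated gene with its 3'-UTR clusters
    (categories PA/UTR3/Extended_UTR3 assigned to that gene), computing
    L_i from the stop-codon boundary to the cluster mode.  ``counts``
    supplies per-tissue (normalized) C_i keyed by cluster_id.  Genes that
    end up with no UTR clusters are dropped."""
    by_gene: dict[str, list[str]] = defaultdict(list)
    for a in assignments:
        if a.category in UTR_CATEGORIES and a.gene_id is not None:
            by_gene[a.gene_id].append(a.cluster_id)
    mode_of = {c.cluster_id: c.mode for c in clusters}

    out = []
    for gene in consolidated:
        for cid in by_gene.get(gene.gene_id, []):
            mode = mode_of[cid]
            if gene.strand == "+":
                L = mode - gene.stop_boundary + 1
            else:
                L = gene.stop_boundary - mode
            if L < 0 or cid not in counts.index:
                continue
            gene.utr_clusters.append(UTRCluster(
                cluster_id=cid, length=L,
                counts=counts.loc[cid].to_dict()))
        if gene.utr_clusters:
            gene.utr_clusters.sort(key=lambda c: c.length)
            out.append(gene)
    return out


def effective_utr_metrics(gene: ConsolidatedGene,
                          tissue: str) -> tuple[float, float, float]:
    """(effective UTR length, USI, expression) for one gene in one
    tissue; all NaN when the tissue has no tags on the gene's clusters."""
    c = np.array([cl.counts.get(tissue, 0.0) for cl in gene.utr_clusters])
    L = np.array([cl.length for cl in gene.utr_clusters], dtype=float)
    total = c.sum()
    if total <= 0:
        return float("nan"), float("nan"), float("nan")
    eff = float((c * L).sum() / total)
    return eff, gene.annotated_utr_length - eff, float(total)


def usi_table(consolidated: list[ConsolidatedGene],
              tissues: list[str]) -> pd.DataFrame:
    """Long-format table: gene, tissue, annotated/effective UTR length,
    USI and expression."""
    rows = []
    for gene in consolidated:
        for t in tissues:
            eff, usi, expr = effective_utr_metrics(gene, t)
            rows.append((gene.gene_id, t, gene.annotated_utr_length,
                         eff, usi, expr))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "annotated_length",
                                       "effective_length", "usi", "expression"])


# ---------------------------------------------------------------------------
# rank-enrichment grid
# ---------------------------------------------------------------------------

@dataclass
class RankGrid:
    tissue: str
    observed: np.ndarray          # B x B gene counts (expr bin, length bin)
    perm_mean: np.ndarray
    perm_sd: np.ndarray
    z: np.ndarray                 # NaN where sd == 0 and observed != mean


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Rank each row 1..T low-to-high; ties broken by the fixed tissue
    (column) order so ranks are always a permutation of 1..T."""
    G, T = values.shape
    cols = np.broadcast_to(np.arange(T), (G, T))
    order = np.lexsort((cols, values), axis=1)
    ranks = np.empty((G, T), dtype=np.int64)
    rows = np.arange(G)[:, None]
    ranks[rows, order] = np.arange(1, T + 1)
    return ranks


def enrichment_grid(usi: pd.DataFrame, n_tissues: int | None = None,
                    bins: int | None = None, permutations: int = 1000,
                    seed: int = 0) -> dict[str, RankGrid]:
    """Per-tissue B x B grids of gene counts by (expression rank,
    effective-length rank) with permutation Z-scores.

    Only genes with defined metrics in every tissue are used.  The null
    permutes each gene's tissue labels independently, keeping its
    (expression, length) pairs together, so each gene's rank multiset is
    preserved exactly.
    """
    wide_expr = usi.pivot(index="gene_id", columns="tissue", values="expression")
    wide_len = usi.pivot(index="gene_id", columns="tissue", values="effective_length")
    tissues = list(wide_expr.columns)
    T = n_tissues or len(tissues)
    if T != len(tissues):
        raise ValueError("n_tissues disagrees with the table's tissue set")
    B = bins or T
    ok = wide_expr.notna().all(axis=1) & wide_len.notna().all(axis=1)
    expr = wide_expr.loc[ok].to_numpy()
    length = wide_len.loc[ok].to_numpy()
    G = expr.shape[0]
    if G < 20:
        warnings.warn(f"only {G} genes eligible for the rank grid; "
                      "Z-scores will be noisy")

    er = _rank_rows(expr)        # G x T, ranks 1..T
    lr = _rank_rows(length)
    ebin = (er - 1) * B // T     # rank -> bin index 0..B-1
    lbin = (lr - 1) * B // T
    codes = ebin * B + lbin      # G x T box code per (gene, tissue)

    observed = np.zeros((T, B * B), dtype=np.int64)
    for t in range(T):
        observed[t] = np.bincount(codes[:, t], minlength=B * B)

    rng = np.random.default_rng(seed)
    acc = np.zeros((T, B * B))
    acc2 = np.zeros((T, B * B))
    for _ in range(permutations):
        perm = rng.random((G, T)).argsort(axis=1)   # per-gene label shuffle
        permuted = np.take_along_axis(codes, perm, axis=1)
        for t in range(T):
            cnt = np.bincount(permuted[:, t], minlength=B * B)
            acc[t] += cnt
            acc2[t] += cnt.astype(float) ** 2
    mean = acc / permutations
    var = np.maximum(acc2 / permutations - mean ** 2, 0.0)
    sd = np.sqrt(var)

    grids = {}
    for t, tissue in enumerate(tissues):
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (observed[t] - mean[t]) / sd[t]
        zero_sd = sd[t] == 0
        z[zero_sd & (observed[t] == mean[t])] = 0.0
        z[zero_sd & (observed[t] != mean[t])] = np.nan
        grids[tissue] = RankGrid(
            tissue=tissue,
            observed=observed[t].reshape(B, B),
            perm_mean=mean[t].reshape(B, B),
            perm_sd=sd[t].reshape(B, B),
            z=z.reshape(B, B))
    return grids


def write_grid_tables(grids: dict[str, RankGrid], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue, grid in grids.items():
        B = grid.observed.shape[0]
        with open(out / f"grid_{tissue}.tsv", "w") as fh:
            fh.write("expr_bin\tlength_bin\tobserved\tperm_mean\tperm_sd\tz\n")
            for i in range(B):
                for j in range(B):
                    fh.write(f"{i + 1}\t{j + 1}\t{grid.observed[i, j]}\t"
                             f"{grid.perm_mean[i, j]:.4f}\t"
                             f"{grid.perm_sd[i, j]:.4f}\t{grid.z[i, j]:.4f}\n")
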