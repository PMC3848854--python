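"""Readers/writers and coordinate conventions for PA-seq style data.

All internal coordinates are 0-based half-open (BED native).  SAM and
wiggle are converted at the boundary.  A *cleavage position* is the last
transcribed base before the poly(A) tail, never the first adenosine of
the tail; every downstream window (internal-priming filter, motif
windows) is defined relative to that base.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STRANDS = ("+", "-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome: contig name -> uppercase base string.

    Lookups outside contig bounds raise; they are never clipped.
    """

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        for name, seq in contigs.items():
            if len(seq) == 0:
                raise ValueError(f"contig {name!r} has zero length")
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def extract_window(self, contig: str, strand: str, start: int, end: int) -> str:
        """Strand-aware sequence of [start, end); '-' returns the reverse
        complement so the string reads 5'->3' on the requested strand."""
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        seq = self.contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"window [{start},{end}) out of bounds for {contig} "
                f"(length {len(seq)})"
            )
        fwd = seq[start:end]
        return fwd if strand == "+" else reverse_complement(fwd)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def extract_window(genome: GenomeSequence, contig: str, strand: str,
                   start: int, end: int) -> str:
    return genome.extract_window(contig, strand, start, end)


@dataclass
class TranscriptModel:
    """One transcript; coordinates 0-based half-open, CDS bounds equal for
    non-coding transcripts."""

    tx_id: str
    gene_id: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.tx_id}: empty transcript span")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(f"{self.tx_id}: malformed exon blocks")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.tx_id}: CDS outside transcript span")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the transcript's last (3'-most) base."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def five_prime_end(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def stop_boundary(self) -> int | None:
        """Genomic boundary between CDS and 3' UTR ('+': cds_end; '-':
        cds_start); None for non-coding transcripts."""
        if not self.is_coding:
            return None
        return self.cds_end if self.strand == "+" else self.cds_start

    def utr3_interval(self) -> tuple[int, int] | None:
        if not self.is_coding:
            return None
        if self.strand == "+":
            iv = (self.cds_end, self.tx_end)
        else:
            iv = (self.tx_start, self.cds_start)
        return iv if iv[1] > iv[0] else None

    def utr5_interval(self) -> tuple[int, int] | None:
        if not self.is_coding:
            return None
        if self.strand == "+":
            iv = (self.tx_start, self.cds_start)
        else:
            iv = (self.cds_end, self.tx_end)
        return iv if iv[1] > iv[0] else None


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        contigs = {t.contig for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(contigs) != 1 or len(strands) != 1:
            raise ValueError(f"{self.gene_id}: transcripts span contigs/strands")

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def coding_flag(self) -> bool:
        return any(t.is_coding for t in self.transcripts)

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.tx_start for t in self.transcripts),
                max(t.tx_end for t in self.transcripts))


@dataclass(frozen=True)
class CleavageRecord:
    contig: str
    strand: str
    position: int
    tissue: str
    count: int


class CleavageProfile:
    """Per-(contig, strand) sparse map of cleavage position -> tag count,
    with a layer per tissue.  The pooled layer is derived on demand."""

    def __init__(self) -> None:
        # (contig, strand) -> tissue -> Counter{position: count}
        self._data: dict[tuple[str, str], dict[str, Counter]] = defaultdict(dict)

    def add(self, contig: str, strand: str, position: int, tissue: str,
            count: int = 1) -> None:
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count}")
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        layer = self._data[(contig, strand)].setdefault(tissue, Counter())
        layer[position] += count

    @classmethod
    def from_records(cls, records: Iterable[CleavageRecord]) -> "CleavageProfile":
        prof = cls()
        for r in records:
            prof.add(r.contig, r.strand, r.position, r.tissue, r.count)
        return prof

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data.keys())

    @property
    def tissues(self) -> list[str]:
        seen: set[str] = set()
        for layers in self._data.values():
            seen.update(layers.keys())
        return sorted(seen)

    def is_empty(self) -> bool:
        return not any(any(c for c in layers.values())
                       for layers in self._data.values())

    def pooled(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted positions and pooled (all-tissue) counts for one strand of
        one contig; empty arrays when nothing is recorded there."""
        layers = self._data.get((contig, strand))
        if not layers:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        pooled: Counter = Counter()
        for layer in layers.values():
            pooled.update(layer)
        pos = np.array(sorted(pooled), dtype=np.int64)
        cnt = np.array([pooled[p] for p in pos], dtype=np.int64)
        return pos, cnt

    def tissue_counts_in(self, contig: str, strand: str, start: int,
                         end: int) -> dict[str, int]:
        """Per-tissue tag totals inside [start, end)."""
        layers = self._data.get((contig, strand), {})
        out: dict[str, int] = {}
        for tissue, layer in layers.items():
            total = sum(c for p, c in layer.items() if start <= p < end)
            if total:
                out[tissue] = total
        return out

    def library_sizes(self) -> dict[str, int]:
        sizes: Counter = Counter()
        for layers in self._data.values():
            for tissue, layer in layers.items():
                sizes[tissue] += sum(layer.values())
        return dict(sizes)

    def iter_records(self) -> Iterator[CleavageRecord]:
        for (contig, strand) in self.keys():
            layers = self._data[(contig, strand)]
            for tissue in sorted(layers):
                for pos in sorted(layers[tissue]):
                    yield CleavageRecord(contig, strand, pos, tissue,
                                         layers[tissue][pos])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CleavageProfile):
            return NotImplemented
        return list(self.iter_records()) == list(other.iter_records())


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def read_gene_models(bed12_source: str | Path,
                     gene_map_source: str | Path) -> list[GeneModel]:
    """Load transcripts from BED12 (thickStart/thickEnd = CDS) and group
    them into genes via a two-column tx_id -> gene_id TSV.

    Transcripts missing from the gene map are skipped and counted in the
    log; malformed BED lines raise.
    """
    gene_map: dict[str, str] = {}
    with open(gene_map_source) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"gene map line {ln}: expected 2 columns")
            gene_map[parts[0]] = parts[1]

    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    n_skipped = 0
    with open(bed12_source) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line {ln}: expected 12 columns, got {len(f)}")
            contig, start, end, tx_id = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"BED12 line {ln}: blockCount inconsistent with blocks")
            exons = [(start + off, start + off + size)
                     for off, size in zip(starts, sizes)]
            if tx_id not in gene_map:
                n_skipped += 1
                logger.warning("transcript %s absent from gene map; skipped", tx_id)
                continue
            by_gene[gene_map[tx_id]].append(TranscriptModel(
                tx_id=tx_id, gene_id=gene_map[tx_id], contig=contig,
                strand=strand, tx_start=start, tx_end=end, exons=exons,
                cds_start=thick_start, cds_end=thick_end))
    if n_skipped:
        logger.info("%d transcripts skipped (absent from gene map)", n_skipped)
    return [GeneModel(gene_id=g, transcripts=txs)
            for g, txs in sorted(by_gene.items())]


def write_gene_models(genes: Iterable[GeneModel], bed12_path: str | Path,
                      gene_map_path: str | Path) -> None:
    with open(bed12_path, "w") as bed, open(gene_map_path, "w") as gm:
        for gene in genes:
            for t in gene.transcripts:
                sizes = ",".join(str(e - s) for s, e in t.exons)
                starts = ",".join(str(s - t.tx_start) for s, _ in t.exons)
                bed.write("\t".join(map(str, [
                    t.contig, t.tx_start, t.tx_end, t.tx_id, 0, t.strand,
                    t.cds_start, t.cds_end, 0, len(t.exons), sizes, starts,
                ])) + "\n")
                gm.write(f"{t.tx_id}\t{t.gene_id}\n")


# ---------------------------------------------------------------------------
# BED6 cleavage-site dialect: contig, pos, pos+1, tissue, count, strand
# ---------------------------------------------------------------------------

def read_cleavage_sites(bed6_source: str | Path) -> CleavageProfile:
    prof = CleavageProfile()
    with open(bed6_source) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"cleavage BED line {ln}: expected 6 columns")
            contig, start, end, tissue, count, strand = (
                f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5])
            if end != start + 1:
                raise ValueError(f"cleavage BED line {ln}: end must be start+1")
            if count < 1:
                raise ValueError(f"cleavage BED line {ln}: count must be >= 1")
            if strand not in STRANDS:
                raise ValueError(f"cleavage BED line {ln}: unknown strand {strand!r}")
            prof.add(contig, strand, start, tissue, count)
    return prof


def write_cleavage_sites(profile: CleavageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in profile.iter_records():
            fh.write(f"{r.contig}\t{r.position}\t{r.position + 1}\t"
                     f"{r.tissue}\t{r.count}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# SAM fragment -> cleavage position
# ---------------------------------------------------------------------------

def cleavage_from_alignments(sam_source: str | Path, tissue: str = "pooled",
                             dedup: bool = False) -> list[CleavageRecord]:
    """Derive cleavage positions from properly paired alignments.

    The fragment strand is taken from read 1 (strand correction is assumed
    to have happened upstream, before alignment).  A '+' fragment spanning
    [s, e) cleaves at e-1, a '-' fragment at s.  Secondary, supplementary
    and unpaired records are skipped and tallied.  With ``dedup`` identical
    fragment endpoints collapse to a single tag.
    """
    import pysam

    skipped = 0
    frags: Counter = Counter()
    with pysam.AlignmentFile(str(sam_source), "r") as sam:
        for read in sam:
            if (read.is_unmapped or read.is_secondary or
                    read.is_supplementary or not read.is_paired or
                    not read.is_proper_pair or read.mate_is_unmapped):
                skipped += 1
                continue
            if read.template_length <= 0:
                continue  # each pair processed once, via its leftmost record
            s = read.reference_start
            e = s + read.template_length
            leftmost_is_read1 = read.is_read1
            strand = "+" if leftmost_is_read1 else "-"
            frags[(read.reference_name, strand, s, e)] += 1
    if skipped:
        logger.info("%d alignments skipped (secondary/supplementary/unpaired)",
                    skipped)
    records = []
    for (contig, strand, s, e), n in sorted(frags.items()):
        pos = e - 1 if strand == "+" else s
        records.append(CleavageRecord(contig, strand, pos, tissue,
                                      1 if dedup else n))
    return records


# ---------------------------------------------------------------------------
# Wiggle output (variableStep, 1-based)
# ---------------------------------------------------------------------------

_STRAND_SUFFIX = {"+": "plus", "-": "minus"}


def write_wiggle(profile: CleavageProfile, out_prefix: str | Path) -> list[Path]:
    """One variableStep wiggle file per tissue per strand; positions are
    converted to 1-based at this boundary."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    # tissue -> strand -> contig -> Counter
    per_file: dict = defaultdict(lambda: defaultdict(dict))
    for (contig, strand) in profile.keys():
        layers = profile._data[(contig, strand)]
        for tissue, layer in layers.items():
            per_file[tissue][strand][contig] = layer
    paths = []
    for tissue in sorted(per_file):
        for strand in sorted(per_file[tissue]):
            path = Path(f"{out_prefix}.{tissue}.{_STRAND_SUFFIX[strand]}.wig")
            with open(path, "w") as fh:
                fh.write(f'track type=wiggle_0 name="PA-seq {tissue} '
                         f'({strand})"\n')
                for contig in sorted(per_file[tissue][strand]):
                    fh.write(f"variableStep chrom={contig}\n")
                    layer = per_file[tissue][strand][contig]
                    for pos in sorted(layer):
                        fh.write(f"{pos + 1} {layer[pos]}\n")
            paths.append(path)
    return paths
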