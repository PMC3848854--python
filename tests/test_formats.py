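"""I/O contracts: BED12 gene models, the BED6 cleavage dialect, SAM
fragment extraction, strand-aware windows and wiggle output."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paseq import (CleavageProfile, CleavageRecord, GenomeSequence,
                   cleavage_from_alignments, read_cleavage_sites,
                   read_gene_models, write_cleavage_sites, write_gene_models,
                   write_wiggle)
from paseq.formats import TranscriptModel, reverse_complement


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def test_bed12_two_blocks_cds_and_exons(tmp_path):
    bed = tmp_path / "m.bed"
    bed.write_text("chr1\t100\t1000\ttxA\t0\t+\t300\t800\t0\t2\t200,400\t0,500\n")
    gm = tmp_path / "map.tsv"
    gm.write_text("txA\tgeneA\n")
    genes = read_gene_models(bed, gm)
    assert len(genes) == 1
    t = genes[0].transcripts[0]
    assert t.exons == [(100, 300), (600, 1000)]
    assert (t.cds_start, t.cds_end) == (300, 800)
    assert t.strand == "+"


def test_utr_coordinate_conventions():
    plus = TranscriptModel("t", "g", "chr1", "+", 100, 1000,
                           [(100, 1000)], 300, 800)
    assert plus.utr3_interval() == (800, 1000)
    minus = TranscriptModel("t", "g", "chr1", "-", 100, 1000,
                            [(100, 1000)], 300, 800)
    # '-' strand: 3' UTR upstream of cds_start in genomic coordinates
    assert minus.utr3_interval() == (100, 300)
    assert minus.utr3_interval()[1] - minus.utr3_interval()[0] == 200
    assert minus.stop_boundary == 300


def test_bed12_missing_gene_map_entry_skipped(tmp_path, caplog):
    bed = tmp_path / "m.bed"
    bed.write_text(
        "chr1\t0\t100\ttxA\t0\t+\t0\t0\t0\t1\t100\t0\n"
        "chr1\t200\t300\ttxB\t0\t+\t200\t200\t0\t1\t100\t0\n")
    gm = tmp_path / "map.tsv"
    gm.write_text("txA\tgeneA\n")
    genes = read_gene_models(bed, gm)
    assert [g.gene_id for g in genes] == ["geneA"]


def test_bed12_inconsistent_blocks_rejected(tmp_path):
    bed = tmp_path / "m.bed"
    bed.write_text("chr1\t0\t100\ttxA\t0\t+\t0\t0\t0\t2\t100\t0\n")
    gm = tmp_path / "map.tsv"
    gm.write_text("txA\tgeneA\n")
    with pytest.raises(ValueError, match="blockCount"):
        read_gene_models(bed, gm)


def test_gene_models_round_trip(small_sim, tmp_path):
    write_gene_models(small_sim.genes, tmp_path / "m.bed", tmp_path / "g.tsv")
    back = read_gene_models(tmp_path / "m.bed", tmp_path / "g.tsv")
    orig = {t.tx_id: t for g in small_sim.genes for t in g.transcripts}
    redo = {t.tx_id: t for g in back for t in g.transcripts}
    assert orig == redo


# ---------------------------------------------------------------------------
# cleavage BED6 dialect
# ---------------------------------------------------------------------------

def test_cleavage_bed6_parsing(tmp_path):
    f = tmp_path / "c.bed"
    f.write_text("chr1\t999\t1000\tliver\t12\t+\n")
    prof = read_cleavage_sites(f)
    recs = list(prof.iter_records())
    assert recs == [CleavageRecord("chr1", "+", 999, "liver", 12)]


def test_cleavage_duplicate_rows_aggregate(tmp_path):
    f = tmp_path / "c.bed"
    f.write_text("chr1\t10\t11\tliver\t3\t+\nchr1\t10\t11\tliver\t4\t+\n")
    recs = list(read_cleavage_sites(f).iter_records())
    assert recs == [CleavageRecord("chr1", "+", 10, "liver", 7)]


@pytest.mark.parametrize("line,err", [
    ("chr1\t10\t11\tliver\t0\t+", "count"),
    ("chr1\t10\t12\tliver\t5\t+", "start"),
    ("chr1\t10\t11\tliver\t5\t*", "strand"),
])
def test_cleavage_bed6_validation(tmp_path, line, err):
    f = tmp_path / "c.bed"
    f.write_text(line + "\n")
    with pytest.raises(ValueError, match=err):
        read_cleavage_sites(f)


def test_cleavage_round_trip(small_sim, tmp_path):
    path = tmp_path / "c.bed"
    write_cleavage_sites(small_sim.profile, path)
    assert read_cleavage_sites(path) == small_sim.profile


# ---------------------------------------------------------------------------
# SAM fragments
# ---------------------------------------------------------------------------

_SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:100000\n"


def _sam_line(qname, flag, pos1, pnext1, tlen):
    seq = "A" * 50
    return (f"{qname}\t{flag}\tchr1\t{pos1}\t60\t50M\t=\t{pnext1}\t{tlen}\t"
            f"{seq}\t*\n")


def test_sam_fragment_cleavage_positions(tmp_path):
    sam = tmp_path / "a.sam"
    sam.write_text(
        _SAM_HEADER
        # '+' fragment [100, 250): leftmost is read1 (forward)
        + _sam_line("fragP", 99, 101, 201, 150)
        + _sam_line("fragP", 147, 201, 101, -150)
        # '-' fragment [100, 250): leftmost is read2
        + _sam_line("fragM", 163, 101, 201, 150)
        + _sam_line("fragM", 83, 201, 101, -150)
        # secondary alignment: skipped
        + _sam_line("fragS", 99 | 256, 301, 401, 150))
    recs = cleavage_from_alignments(sam, tissue="liver")
    assert (set((r.strand, r.position) for r in recs)
            == {("+", 249), ("-", 100)})
    assert all(r.count == 1 for r in recs)


def test_sam_dedup_collapses_identical_fragments(tmp_path):
    sam = tmp_path / "a.sam"
    lines = ""
    for q in ("d1", "d2", "d3"):
        lines += _sam_line(q, 99, 101, 201, 150)
        lines += _sam_line(q, 147, 201, 101, -150)
    sam.write_text(_SAM_HEADER + lines)
    assert cleavage_from_alignments(sam)[0].count == 3
    assert cleavage_from_alignments(sam, dedup=True)[0].count == 1


def test_sam_and_bed6_routes_agree(tmp_path):
    sam = tmp_path / "a.sam"
    sam.write_text(_SAM_HEADER
                   + _sam_line("f1", 99, 101, 201, 150)
                   + _sam_line("f1", 147, 201, 101, -150))
    recs = cleavage_from_alignments(sam, tissue="liver")
    bed = tmp_path / "c.bed"
    bed.write_text("".join(f"{r.contig}\t{r.position}\t{r.position + 1}\t"
                           f"{r.tissue}\t{r.count}\t{r.strand}\n" for r in recs))
    assert read_cleavage_sites(bed) == CleavageProfile.from_records(recs)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_extract_window_examples():
    g = GenomeSequence({"c": "TTTTTTTTTTACGTACTTTT"})
    assert g.extract_window("c", "+", 10, 16) == "ACGTAC"
    assert g.extract_window("c", "-", 10, 16) == "GTACGT"
    with pytest.raises(ValueError):
        g.extract_window("c", "+", 15, 25)
    with pytest.raises(ValueError):
        g.extract_window("c", "+", -1, 5)


@settings(derandomize=True, max_examples=50)
@given(st.data())
def test_extract_window_strand_symmetry(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    seq = "".join(rng.choice(list("ACGTN"), size=200))
    g = GenomeSequence({"c": seq})
    start = data.draw(st.integers(0, 190))
    end = data.draw(st.integers(start + 1, 200))
    fwd = g.extract_window("c", "+", start, end)
    rev = g.extract_window("c", "-", start, end)
    assert rev == reverse_complement(fwd)
    assert len(rev) == end - start


# ---------------------------------------------------------------------------
# wiggle
# ---------------------------------------------------------------------------

def test_wiggle_one_based_output(tmp_path):
    prof = CleavageProfile()
    prof.add("chr1", "+", 999, "liver", 12)
    paths = write_wiggle(prof, tmp_path / "w")
    assert len(paths) == 1 and paths[0].name == "w.liver.plus.wig"
    lines = paths[0].read_text().splitlines()
    assert "variableStep chrom=chr1" in lines
    assert "1000 12" in lines


def test_wiggle_both_strands_and_empty(tmp_path):
    prof = CleavageProfile()
    prof.add("chr1", "+", 5, "liver", 1)
    prof.add("chr1", "-", 9, "liver", 2)
    paths = write_wiggle(prof, tmp_path / "w")
    assert {p.name for p in paths} == {"w.liver.plus.wig", "w.liver.minus.wig"}
    empty = write_wiggle(CleavageProfile(), tmp_path / "e")
    assert empty == []
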