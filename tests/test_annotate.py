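"""Genomic category assignment: a hand-assigned fixture covering every
category and the priority conflicts, per-gene summaries and
distance-to-reference statistics."""

from dataclasses import dataclass

import numpy as np
import pytest

from paseq import (GeneModel, assign_categories, clusters_per_gene,
                   distance_to_reference)
from paseq.annotate import CategoryAssignment
from paseq.formats import TranscriptModel


@dataclass
class FakeCluster:
    cluster_id: str
    contig: str
    strand: str
    mode: int


def _gene(gene_id, contig, strand, tx_start, tx_end, exons, cds_start, cds_end,
          tx_id=None):
    return GeneModel(gene_id=gene_id, transcripts=[TranscriptModel(
        tx_id=tx_id or gene_id + ".t1", gene_id=gene_id, contig=contig,
        strand=strand, tx_start=tx_start, tx_end=tx_end, exons=exons,
        cds_start=cds_start, cds_end=cds_end)])


@pytest.fixture(scope="module")
def fixture_genes():
    # A: '+' coding, exons (1000-1800, 2100-3000), CDS 1200-2500
    #    promoter [750,1000) TSS 1000+/-10 UTR5 [1000,1200)
    #    coding exon [1200,1800)+[2100,2500) intron [1800,2100)
    #    UTR3 [2500,3000) PA 2999+/-10 extended [3000,4000)
    a = _gene("A", "chr1", "+", 1000, 3000, [(1000, 1800), (2100, 3000)],
              1200, 2500)
    # B: '+' coding, nested in A's intron, tx 1820-2090, CDS 1830-1990
    b = _gene("B", "chr1", "+", 1820, 2090, [(1820, 2090)], 1830, 1990)
    # C: '-' coding, tx 5000-7000, exons (5000-5900, 6200-7000), CDS 5500-6800
    c = _gene("C", "chr1", "-", 5000, 7000, [(5000, 5900), (6200, 7000)],
              5500, 6800)
    # D: '+' non-coding single exon
    d = _gene("D", "chr1", "+", 9000, 9500, [(9000, 9500)], 9000, 9000)
    return [a, b, c, d]


# (mode, strand, expected category, expected gene or None-for-any)
FIXTURE_CASES = [
    # every category on gene A, including in-gene priority conflicts
    (2991, "+", "PA", "A"),              # PA beats UTR3 and Exon
    (2600, "+", "UTR3", "A"),            # UTR3 beats Extended_UTR3(B)
    (3500, "+", "Extended_UTR3", None),  # downstream of A (and of B)
    (1500, "+", "Exon", "A"),            # coding exon
    (1810, "+", "Intron", "A"),          # intron, beats Promoter(B) and TSS(B)
    (1100, "+", "UTR5", "A"),            # UTR5 beats the exon block it sits in
    (995, "+", "TSS", "A"),              # TSS beats Promoter
    (1005, "+", "UTR5", "A"),            # UTR5 beats TSS
    (800, "+", "Promoter", "A"),
    (500, "+", "Intergenic", None),
    (200, "+", "Intergenic", None),
    # cross-gene priority conflicts with nested gene B
    (2000, "+", "UTR3", "B"),            # UTR3(B) beats Intron(A)
    (2085, "+", "PA", "B"),              # PA(B) beats Intron(A) and UTR3(B)
    (2200, "+", "Extended_UTR3", "B"),   # Extended(B) beats coding Exon(A)
    (1850, "+", "Exon", "B"),            # Exon(B) beats Intron(A)
    (1700, "+", "Exon", "A"),            # Exon(A) beats Promoter(B)
    (1820, "+", "Intron", "A"),          # Intron(A) beats TSS(B)
    # '-' strand gene C mirrors the coordinate conventions
    (5003, "-", "PA", "C"),
    (5300, "-", "UTR3", "C"),
    (4500, "-", "Extended_UTR3", "C"),
    (6900, "-", "UTR5", "C"),
    (5950, "-", "Intron", "C"),
    (7100, "-", "Promoter", "C"),
    # strand-matched assignment only
    (5003, "+", "Intergenic", None),
    # non-coding gene: full exon blocks count as Exon, PA at the 3' end
    (9499, "+", "PA", "D"),
    (9200, "+", "Exon", "D"),
]


def test_hand_assigned_category_fixture(fixture_genes):
    clusters = [FakeCluster(f"c{i}", "chr1", strand, mode)
                for i, (mode, strand, _, _) in enumerate(FIXTURE_CASES)]
    got = assign_categories(clusters, fixture_genes)
    for a, (mode, strand, category, gene) in zip(got, FIXTURE_CASES):
        assert a.category == category, (mode, strand, a.category, category)
        if gene is not None:
            assert a.gene_id == gene, (mode, strand, a.gene_id, gene)
        if category == "Intergenic":
            assert a.gene_id is None


def test_distant_flag(fixture_genes):
    near = FakeCluster("x", "chr1", "+", 500)    # 500 nt from A: not distant
    far = FakeCluster("y", "chr1", "+", 200)     # 800 nt away: distant
    got = assign_categories([near, far], fixture_genes)
    assert got[0].distant_flag is False
    assert got[1].distant_flag is True


def test_priority_unchanged_by_lower_priority_overlap(fixture_genes):
    """Adding an overlapping lower-priority annotation never changes an
    assignment: dropping nested gene B can only demote, never promote."""
    with_b = assign_categories(
        [FakeCluster("c", "chr1", "+", 2600)], fixture_genes)
    without_b = assign_categories(
        [FakeCluster("c", "chr1", "+", 2600)],
        [g for g in fixture_genes if g.gene_id != "B"])
    assert with_b[0].category == without_b[0].category == "UTR3"


def test_synthetic_utr_sites_assigned_to_true_gene(sim, called, assignments):
    """On synthetic data nearly all truth 3'-UTR sites get a UTR-class
    category of their true gene."""
    truth_by_mode = {(t.contig, t.strand, t.mode): t
                     for t in sim.truth if not t.is_artifact}
    by_id = {a.cluster_id: a for a in assignments}
    n_ok = n = 0
    for c in called:
        t = None
        for off in range(-5, 6):
            t = truth_by_mode.get((c.contig, c.strand, c.mode + off))
            if t is not None:
                break
        if t is None:
            continue
        n += 1
        a = by_id[c.cluster_id]
        if (a.category in ("PA", "UTR3", "Extended_UTR3")
                and a.gene_id == t.gene_id):
            n_ok += 1
    assert n > 0 and n_ok / n >= 0.95


def test_every_cluster_gets_exactly_one_category(assignments, called):
    assert len(assignments) == len(called)
    from collections import Counter
    cats = Counter(a.category for a in assignments)
    assert sum(cats.values()) == len(called)


def test_clusters_per_gene_summary():
    genes = [_gene("g1", "chr1", "+", 0, 1000, [(0, 1000)], 100, 900),
             _gene("g2", "chr1", "+", 2000, 3000, [(2000, 3000)], 2100, 2900),
             _gene("g3", "chr1", "+", 4000, 5000, [(4000, 5000)], 4100, 4900),
             _gene("nc", "chr1", "+", 6000, 7000, [(6000, 7000)], 6000, 6000)]
    assigns = (
        [CategoryAssignment("a", "UTR3", "g1", False)]
        + [CategoryAssignment(f"b{i}", "UTR3", "g2", False) for i in range(2)]
        + [CategoryAssignment(f"c{i}", "PA", "g3", False) for i in range(3)]
        + [CategoryAssignment("n", "Exon", "nc", False)]
        + [CategoryAssignment("p", "Promoter", "g1", False)]   # not counted
        + [CategoryAssignment("i", "Intergenic", None, True)])
    s = clusters_per_gene(assigns, genes)
    assert s.counts == {"g1": 1, "g2": 2, "g3": 3, "nc": 1}
    assert s.mean_clusters_coding == pytest.approx(2.0)
    assert s.mean_clusters_ncrna == pytest.approx(1.0)
    assert s.frac_multi_coding == pytest.approx(2 / 3)


def test_distance_to_reference_directions():
    observed = [("chr1", "+", 100), ("chr1", "+", 200)]
    reference = [("chr1", "+", 105)]
    ref_to_obs = distance_to_reference(reference, observed)
    assert ref_to_obs.distances.tolist() == [5.0]
    # gene with two reference sites: the shortest distance is used
    obs_to_ref = distance_to_reference([("chr1", "+", 102)],
                                       [("chr1", "+", 100), ("chr1", "+", 500)])
    assert obs_to_ref.distances.tolist() == [2.0]


def test_distance_missing_targets():
    res = distance_to_reference([("chr1", "+", 100), ("chr2", "+", 5)],
                                [("chr1", "+", 100)])
    assert res.n_missing == 1
    assert res.frac_zero == 1.0
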