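"""Synthetic multi-tissue PA-seq data with known ground truth.

The generator plants polyadenylation sites of three emission shapes in
the 3' UTRs of a toy genome, emits negative-binomial per-tissue tag
counts around each site, and adds genomic A-rich internal-priming
artifacts, so that every downstream stage (cluster calling, shape
classification, priming filter, tissue-specificity calls, UTR
shortening) can be validated against the planted truth.

Emission shapes (offsets relative to the planted mode):

* ``narrow``    — round N(0, sd) with sd 1 nt: a sharp, single-base-
  dominated site (expected within-±2 fraction ~0.95, span < 10).
* ``broad``     — 60% round N(0, 1) + 40% uniform on [-15, 15]: a
  dominant mode on a wide base (within-±2 ~0.64, span >= 10).
* ``dispersed`` — 30% round N(0, 2) + 70% uniform on [-15, 15]: no
  dominant mode in the shape-class sense (within-±2 ~0.35) but still a
  well-defined most-frequent position for mode recovery.

Every genuine site carries a canonical AATAAA hexamer planted on the
sense strand 21 nt upstream of the mode, and a downstream 20-mer capped
at <= 8 adenosines so the internal-priming filter can never remove it.
Artifact sites sit on planted A-rich tracts (18 A in the downstream
20-mer) both between genes and inside introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats import (CleavageProfile, GeneModel, GenomeSequence,
                      TranscriptModel, reverse_complement,
                      write_cleavage_sites, write_gene_models)

DEFAULT_TISSUES = (
    "adult_brain", "fetal_brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "pancreas", "prostate", "skeletal_muscle", "spleen",
    "testis",
)

SHAPES = ("narrow", "broad", "dispersed")


@dataclass
class SimulationConfig:
    seed: int = 1
    n_contigs: int = 2
    contig_length: int = 2_000_000
    gc_fraction: float = 0.41
    n_genes: int = 300
    n_tissues: int = 13
    utr_length_range: tuple[int, int] = (300, 3000)
    pa_sites_per_gene: tuple[int, int] = (1, 3)
    shape_mix: tuple[float, float, float] = (0.45, 0.43, 0.12)
    narrow_sd: float = 1.0
    broad_half_width: int = 15
    dispersed_width: int = 30
    mean_tags_per_site_per_tissue: float = 40.0
    nb_dispersion: float = 0.3
    library_size_range: tuple[float, float] = (0.5, 2.0)
    frac_tissue_specific: float = 0.1
    dominant_tissue_share: float = 0.9
    frac_usi_coupled: float = 0.1
    usi_proximal_share: float = 0.8
    usi_expression_fold: float = 4.0
    #: tissue indices eligible as the designated shortening tissue; the
    #: default concentrates the planted coupling in two tissues, mirroring
    #: the tissue-preferential shortening the generator emulates
    usi_designated_tissues: tuple[int, ...] = (0, 1)
    n_artifact_sites: int = 30
    n_overlapping_gene_pairs: int = 4
    frac_stop_codon_mismatch: float = 0.05
    min_site_spacing: int = 200

    def __post_init__(self) -> None:
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise ValueError("shape_mix proportions must sum to 1")
        for lo, hi in (self.utr_length_range, self.pa_sites_per_gene,
                       self.library_size_range):
            if not lo < hi:
                raise ValueError("config ranges must be non-degenerate")

    def tissue_names(self) -> list[str]:
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES[: self.n_tissues])
        return [f"tissue_{i:02d}" for i in range(1, self.n_tissues + 1)]


@dataclass
class TruthPASite:
    site_id: str
    gene_id: str | None
    contig: str
    strand: str
    mode: int
    shape: str
    expected_counts: dict[str, float]
    is_artifact: bool = False
    is_tissue_specific: bool = False
    dominant_tissue: str | None = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: list[TruthPASite]
    profile: CleavageProfile
    tissues: list[str]
    library_multipliers: dict[str, float]
    files: dict[str, Path] = field(default_factory=dict)
    usi_coupled: dict[str, str] = field(default_factory=dict)
    """gene_id -> designated tissue for the planted shortening coupling."""


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_genome(rng: np.random.Generator, cfg: SimulationConfig) -> dict[str, np.ndarray]:
    gc = cfg.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {f"chr{i + 1}": rng.choice(4, size=cfg.contig_length, p=p).astype(np.int8)
            for i in range(cfg.n_contigs)}


def _sense_to_fwd(mode: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Forward-strand interval of the sense-strand offsets [a, b) around
    ``mode`` (offset 0 = the mode base itself)."""
    if strand == "+":
        return mode + a, mode + b
    return mode - b + 1, mode - a + 1


def _plant(arr: np.ndarray, strand: str, fwd_start: int, fwd_end: int,
           sense_seq: str) -> None:
    seq = sense_seq if strand == "+" else reverse_complement(sense_seq)
    codes = np.array(["ACGT".index(c) for c in seq], dtype=np.int8)
    arr[fwd_start:fwd_end] = codes


def _downstream_20mer(rng: np.random.Generator, max_a: int = 8) -> str:
    """Random 20-mer with at most ``max_a`` adenosines (sense strand)."""
    while True:
        s = rng.choice(4, size=20, p=[0.25, 0.25, 0.25, 0.25])
        if int(np.sum(s == 0)) <= max_a:
            return "".join(_BASES[s])


def _artifact_20mer(rng: np.random.Generator, n_a: int = 18) -> str:
    others = rng.choice([1, 2, 3], size=20 - n_a)
    codes = np.concatenate([np.zeros(n_a, dtype=np.int64), others])
    rng.shuffle(codes)
    return "".join(_BASES[codes])


def _draw_offsets(rng: np.random.Generator, shape: str, n: int,
                  cfg: SimulationConfig) -> np.ndarray:
    hw = cfg.broad_half_width
    if shape == "narrow":
        return np.rint(rng.normal(0.0, cfg.narrow_sd, n)).astype(np.int64)
    if shape == "broad":
        sharp = rng.random(n) < 0.6
        out = rng.integers(-hw, hw + 1, size=n)
        out[sharp] = np.rint(rng.normal(0.0, 1.0, int(sharp.sum())))
        return out
    if shape == "dispersed":
        central = rng.random(n) < 0.3
        out = rng.integers(-hw, hw + 1, size=n)
        out[central] = np.rint(rng.normal(0.0, 2.0, int(central.sum())))
        return out
    raise ValueError(f"unknown shape {shape!r}")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


# --------------------------------------------------------------------------
# gene construction
# --------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    contig: str
    strand: str
    start: int          # genomic span start
    length: int
    utr_len: int
    cds_len: int        # genomic CDS span (includes the intron)
    mismatch_stop: bool
    second_tx: bool

    UTR5 = 200
    EXON1 = 400
    INTRON = 500

    @property
    def end(self) -> int:
        return self.start + self.length

    def _genomic(self, local_start: int, local_end: int) -> tuple[int, int]:
        """Map a 5'->3' local interval to genomic coordinates."""
        if self.strand == "+":
            return self.start + local_start, self.start + local_end
        return self.end - local_end, self.end - local_start

    def transcripts(self) -> list[TranscriptModel]:
        L = self.length
        exon_locals = [(0, self.EXON1), (self.EXON1 + self.INTRON, L)]
        cds_local = (self.UTR5, self.UTR5 + self.cds_len)
        txs = [self._make_tx(f"{self.gene_id}.t1", L, exon_locals, cds_local)]
        if self.second_tx:
            # shorter 3' end, same stop codon unless mismatch_stop
            cut = cds_local[1] + max(50, self.utr_len // 2)
            cds2 = cds_local
            if self.mismatch_stop:
                cds2 = (cds_local[0], cds_local[1] - 30)
            exon2 = [(0, self.EXON1), (self.EXON1 + self.INTRON, cut)]
            txs.append(self._make_tx(f"{self.gene_id}.t2", cut, exon2, cds2))
        return txs

    def _make_tx(self, tx_id: str, local_len: int,
                 exon_locals: list[tuple[int, int]],
                 cds_local: tuple[int, int]) -> TranscriptModel:
        if self.strand == "+":
            tx_start, tx_end = self.start, self.start + local_len
        else:
            tx_start, tx_end = self.end - local_len, self.end
        exons = sorted(self._genomic(s, e) for s, e in exon_locals)
        c0, c1 = self._genomic(*cds_local)
        return TranscriptModel(tx_id=tx_id, gene_id=self.gene_id,
                               contig=self.contig, strand=self.strand,
                               tx_start=tx_start, tx_end=tx_end, exons=exons,
                               cds_start=c0, cds_end=c1)

    def mode_for_utr_offset(self, d: int) -> int:
        """Genomic mode for a site d nt into the 3' UTR (d = 0 is the
        first UTR base; implied UTR length L_i = d + 1)."""
        a, b = self._genomic(self.UTR5 + self.cds_len + d,
                             self.UTR5 + self.cds_len + d + 1)
        return a

    def intron_center(self) -> int:
        a, _ = self._genomic(self.EXON1 + self.INTRON // 2,
                             self.EXON1 + self.INTRON // 2 + 1)
        return a


def _plan_genes(rng: np.random.Generator, cfg: SimulationConfig) -> list[_GenePlan]:
    margin = 5000
    plans: list[_GenePlan] = []
    contigs = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    cursor = {c: margin for c in contigs}
    ci = 0

    n_regular = cfg.n_genes - 2 * cfg.n_overlapping_gene_pairs
    if n_regular < 0:
        raise ValueError("n_overlapping_gene_pairs too large for n_genes")

    def place(length: int, overlap_prev: _GenePlan | None = None) -> tuple[str, int]:
        nonlocal ci
        if overlap_prev is not None:
            start = overlap_prev.end - 500
            cursor[overlap_prev.contig] = max(cursor[overlap_prev.contig],
                                              start + length + 1000)
            return overlap_prev.contig, start
        for _ in range(len(contigs)):
            c = contigs[ci % len(contigs)]
            gap = int(rng.integers(2000, 6001))
            start = cursor[c] + gap
            if start + length + 1000 <= cfg.contig_length - margin:
                cursor[c] = start + length + 1000
                return c, start
            ci += 1
        raise RuntimeError(
            f"infeasible packing: {cfg.n_genes} genes of up to "
            f"{200 + 1800 + cfg.utr_length_range[1]} nt do not fit in "
            f"{cfg.n_contigs} x {cfg.contig_length} nt contigs")

    def make(idx: int, overlap_prev: _GenePlan | None = None) -> _GenePlan:
        utr_len = int(rng.integers(*cfg.utr_length_range))
        cds_len = int(rng.integers(1000, 1801))
        length = _GenePlan.UTR5 + cds_len + utr_len
        strand = "+" if rng.random() < 0.5 else "-"
        if overlap_prev is not None:
            strand = overlap_prev.strand
        contig, start = place(length, overlap_prev)
        return _GenePlan(
            gene_id=f"gene{idx:04d}", contig=contig, strand=strand,
            start=start, length=length, utr_len=utr_len, cds_len=cds_len,
            mismatch_stop=rng.random() < cfg.frac_stop_codon_mismatch,
            second_tx=rng.random() < 0.5)

    for i in range(n_regular):
        plans.append(make(i))
        # round-robin contigs so both get genes
        ci += 1
    for j in range(cfg.n_overlapping_gene_pairs):
        a = make(n_regular + 2 * j)
        b = make(n_regular + 2 * j + 1, overlap_prev=a)
        plans.extend([a, b])
    return plans


# --------------------------------------------------------------------------
# main entry point
# --------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig,
                     out_dir: str | Path | None = None) -> SimulatedDataset:
    """Generate genome, gene models, truth PA sites and a multi-tissue
    cleavage profile; optionally write all of it to ``out_dir``."""
    rng = np.random.default_rng(config.seed)
    tissues = config.tissue_names()
    T = config.n_tissues

    arrays = _random_genome(rng, config)
    plans = _plan_genes(rng, config)
    lib_mult = {t: float(m) for t, m in
                zip(tissues, rng.uniform(*config.library_size_range, T))}

    truth: list[TruthPASite] = []
    site_mass = config.mean_tags_per_site_per_tissue * T
    uniform_w = np.full(T, 1.0 / T)

    # ---- genuine sites in 3' UTRs -------------------------------------
    per_gene_sites: dict[str, list[TruthPASite]] = {}
    per_gene_lambda: dict[str, np.ndarray] = {}
    for plan in plans:
        lo, hi = config.pa_sites_per_gene
        k = int(rng.integers(lo, hi + 1))
        max_k = 1 + max(0, (plan.utr_len - 100)) // config.min_site_spacing
        k = max(1, min(k, max_k))
        # distal first, then walk proximally with >= min spacing
        ds = [plan.utr_len - 50]
        for _ in range(k - 1):
            step = int(rng.integers(config.min_site_spacing,
                                    config.min_site_spacing + 201))
            nxt = ds[-1] - step
            if nxt < 50:
                break
            ds.append(nxt)
        ds = sorted(ds)  # proximal -> distal
        sites = []
        lam = np.zeros((len(ds), T))
        for si, d in enumerate(ds):
            shape = str(rng.choice(SHAPES, p=config.shape_mix))
            specific = rng.random() < config.frac_tissue_specific
            dom = None
            w = uniform_w
            if specific:
                dom = tissues[int(rng.integers(T))]
                w = np.full(T, (1 - config.dominant_tissue_share) / (T - 1))
                w[tissues.index(dom)] = config.dominant_tissue_share
            lam[si] = site_mass * w * np.array([lib_mult[t] for t in tissues])
            site = TruthPASite(
                site_id=f"{plan.gene_id}.pa{si + 1}", gene_id=plan.gene_id,
                contig=plan.contig, strand=plan.strand,
                mode=plan.mode_for_utr_offset(d), shape=shape,
                expected_counts={}, is_tissue_specific=specific,
                dominant_tissue=dom)
            sites.append(site)
        per_gene_sites[plan.gene_id] = sites
        per_gene_lambda[plan.gene_id] = lam

    # ---- USI coupling: designated tissue shifts tags proximally and
    # boosts expression -------------------------------------------------
    # couple only genes without tissue-specific sites: a distal site
    # dominated by some other tissue would mimic proximal-shifted usage
    # everywhere else and make the planted coupling unrecoverable
    multi = [p for p in plans
             if len(per_gene_sites[p.gene_id]) >= 2
             and not any(s.is_tissue_specific for s in per_gene_sites[p.gene_id])]
    n_coupled = int(round(config.frac_usi_coupled * config.n_genes))
    coupled_idx = rng.choice(len(multi), size=min(n_coupled, len(multi)),
                             replace=False) if multi else []
    usi_coupled: dict[str, str] = {}
    for gi in np.sort(np.asarray(coupled_idx, dtype=int)):
        plan = multi[gi]
        eligible = [i for i in config.usi_designated_tissues if i < T] or list(range(T))
        tstar = int(eligible[int(rng.integers(len(eligible)))])
        usi_coupled[plan.gene_id] = tissues[tstar]
        lam = per_gene_lambda[plan.gene_id]
        total = lam[:, tstar].sum() * config.usi_expression_fold
        k = lam.shape[0]
        lam[:, tstar] = total * (1 - config.usi_proximal_share) / (k - 1)
        lam[0, tstar] = total * config.usi_proximal_share  # row 0 = proximal

    for plan in plans:
        lam = per_gene_lambda[plan.gene_id]
        for si, site in enumerate(per_gene_sites[plan.gene_id]):
            site.expected_counts = {t: float(lam[si, ti])
                                    for ti, t in enumerate(tissues)}
            truth.append(site)

    # ---- artifact sites: intergenic + intronic A-rich tracts ----------
    by_contig_gaps: dict[str, list[tuple[int, int]]] = {}
    for c in arrays:
        spans = sorted((p.start, p.end) for p in plans if p.contig == c)
        gaps, prev = [], 6000
        for s, e in spans:
            if s - prev > 3000:
                gaps.append((prev + 1500, s - 1500))
            prev = max(prev, e)
        by_contig_gaps[c] = gaps
    n_intronic = config.n_artifact_sites // 2
    n_intergenic = config.n_artifact_sites - n_intronic
    for ai in range(n_intergenic):
        contig = f"chr{int(rng.integers(config.n_contigs)) + 1}"
        gaps = by_contig_gaps[contig]
        if not gaps:
            continue
        g = gaps[int(rng.integers(len(gaps)))]
        mode = int(rng.integers(g[0], g[1]))
        strand = "+" if rng.random() < 0.5 else "-"
        lam = site_mass * uniform_w * np.array([lib_mult[t] for t in tissues])
        truth.append(TruthPASite(
            site_id=f"artifact_ig{ai + 1:02d}", gene_id=None, contig=contig,
            strand=strand, mode=mode, shape="narrow",
            expected_counts={t: float(lam[ti]) for ti, t in enumerate(tissues)},
            is_artifact=True))
    intron_hosts = rng.choice(len(plans), size=n_intronic, replace=False)
    for ai, pi in enumerate(np.sort(intron_hosts)):
        plan = plans[int(pi)]
        lam = site_mass * uniform_w * np.array([lib_mult[t] for t in tissues])
        truth.append(TruthPASite(
            site_id=f"artifact_in{ai + 1:02d}", gene_id=None,
            contig=plan.contig, strand=plan.strand,
            mode=plan.intron_center(), shape="narrow",
            expected_counts={t: float(lam[ti]) for ti, t in enumerate(tissues)},
            is_artifact=True))

    # ---- plant sequence features --------------------------------------
    for site in truth:
        arr = arrays[site.contig]
        s, e = _sense_to_fwd(site.mode, site.strand, 1, 21)
        if site.is_artifact:
            _plant(arr, site.strand, s, e, _artifact_20mer(rng))
        else:
            _plant(arr, site.strand, s, e, _downstream_20mer(rng))
            a, b = _sense_to_fwd(site.mode, site.strand, -21, -15)
            _plant(arr, site.strand, a, b, "AATAAA")

    genome = GenomeSequence({c: "".join(_BASES[arr]) for c, arr in arrays.items()})

    # ---- emit tags -----------------------------------------------------
    # Overdispersion acts at the gene x tissue level (expression noise);
    # the split among a gene's sites, given the total, is multinomial.
    # Artifacts and single-site genes reduce to a plain NB draw.
    profile = CleavageProfile()

    def emit(site: TruthPASite, tissue: str, n: int) -> None:
        if n == 0:
            return
        clen = genome.length(site.contig)
        offs = _draw_offsets(rng, site.shape, n, config)
        pos = site.mode + offs if site.strand == "+" else site.mode - offs
        pos = np.clip(pos, 0, clen - 1)
        vals, cnts = np.unique(pos, return_counts=True)
        for p, c in zip(vals, cnts):
            profile.add(site.contig, site.strand, int(p), tissue, int(c))

    for plan in plans:
        sites = per_gene_sites[plan.gene_id]
        lam = per_gene_lambda[plan.gene_id]
        for ti, t in enumerate(tissues):
            total_mean = float(lam[:, ti].sum())
            total = _nb_draw(rng, total_mean, config.nb_dispersion)
            if total == 0 or total_mean <= 0:
                continue
            split = rng.multinomial(total, lam[:, ti] / total_mean)
            for site, n in zip(sites, split):
                emit(site, t, int(n))
    for site in truth:
        if site.is_artifact:
            for t in tissues:
                emit(site, t,
                     _nb_draw(rng, site.expected_counts[t], config.nb_dispersion))

    genes = [GeneModel(gene_id=p.gene_id, transcripts=p.transcripts())
             for p in plans]

    ds = SimulatedDataset(config=config, genome=genome, genes=genes,
                          truth=truth, profile=profile, tissues=tissues,
                          library_multipliers=lib_mult,
                          usi_coupled=usi_coupled)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        write_gene_models(genes, out / "models.bed12", out / "gene_map.tsv")
        write_cleavage_sites(profile, out / "cleavage.bed6")
        write_truth_table(truth, tissues, out / "truth.tsv")
        ds.files = {"genome": out / "genome.fa", "models": out / "models.bed12",
                    "gene_map": out / "gene_map.tsv",
                    "cleavage": out / "cleavage.bed6",
                    "truth": out / "truth.tsv"}
    return ds


def write_truth_table(truth: list[TruthPASite], tissues: list[str],
                      path: str | Path) -> None:
    cols = ["site_id", "gene_id", "contig", "strand", "mode", "shape",
            "is_artifact", "is_tissue_specific", "dominant_tissue"]
    cols += [f"expected_{t}" for t in tissues]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in truth:
            row = [s.site_id, s.gene_id or ".", s.contig, s.strand,
                   str(s.mode), s.shape, str(int(s.is_artifact)),
                   str(int(s.is_tissue_specific)), s.dominant_tissue or "."]
            row += [f"{s.expected_counts[t]:.3f}" for t in tissues]
            fh.write("\t".join(row) + "\n")


def read_truth_table(path: str | Path) -> list[TruthPASite]:
    truth = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        tissues = [c[len("expected_"):] for c in header if c.startswith("expected_")]
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            truth.append(TruthPASite(
                site_id=f["site_id"],
                gene_id=None if f["gene_id"] == "." else f["gene_id"],
                contig=f["contig"], strand=f["strand"], mode=int(f["mode"]),
                shape=f["shape"],
                expected_counts={t: float(f[f"expected_{t}"]) for t in tissues},
                is_artifact=bool(int(f["is_artifact"])),
                is_tissue_specific=bool(int(f["is_tissue_specific"])),
                dominant_tissue=None if f["dominant_tissue"] == "."
                else f["dominant_tissue"]))
    return truth


# --------------------------------------------------------------------------
# truth vs called evaluation
# --------------------------------------------------------------------------

_SHAPE_TO_CLASS = {"narrow": "NP", "broad": "BP", "dispersed": "WP"}


@dataclass
class RecoveryReport:
    n_truth: int
    n_matched: int
    sensitivity: float
    mode_errors: np.ndarray
    n_false_clusters: int
    false_cluster_fraction: float
    shape_confusion: dict[tuple[str, str], int]
    shape_agreement: float
    n_artifacts: int
    n_artifacts_surviving: int

    @property
    def mean_abs_mode_error(self) -> float:
        return float(np.mean(np.abs(self.mode_errors))) if len(self.mode_errors) else float("nan")

    @property
    def max_abs_mode_error(self) -> float:
        return float(np.max(np.abs(self.mode_errors))) if len(self.mode_errors) else float("nan")


def truth_recovery_report(truth: list[TruthPASite], called,
                          match_radius: int = 5) -> RecoveryReport:
    """Match called cluster modes to planted truth modes (same contig and
    strand, within ``match_radius`` nt) and summarise recovery."""
    from collections import defaultdict

    called_by_key: dict[tuple[str, str], list] = defaultdict(list)
    for cl in called:
        called_by_key[(cl.contig, cl.strand)].append(cl)
    for key in called_by_key:
        called_by_key[key].sort(key=lambda c: c.mode)

    genuine = [s for s in truth if not s.is_artifact]
    artifacts = [s for s in truth if s.is_artifact]

    matched_clusters: set[int] = set()
    mode_errors, confusion = [], {}
    n_matched = 0
    for site in genuine:
        cands = called_by_key.get((site.contig, site.strand), [])
        best, best_err = None, None
        for cl in cands:
            err = cl.mode - site.mode
            if abs(err) <= match_radius and (best is None or abs(err) < abs(best_err)):
                best, best_err = cl, err
        if best is not None:
            n_matched += 1
            mode_errors.append(best_err)
            matched_clusters.add(id(best))
            key = (site.shape, best.shape)
            confusion[key] = confusion.get(key, 0) + 1

    n_art_survive = 0
    for site in artifacts:
        cands = called_by_key.get((site.contig, site.strand), [])
        if any(abs(cl.mode - site.mode) <= match_radius for cl in cands):
            n_art_survive += 1
            for cl in cands:
                if abs(cl.mode - site.mode) <= match_radius:
                    matched_clusters.add(id(cl))

    n_false = sum(1 for cl in called if id(cl) not in matched_clusters)
    n_shape_ok = sum(n for (t, c), n in confusion.items()
                     if _SHAPE_TO_CLASS[t] == c)
    n_shape_all = sum(confusion.values())
    return RecoveryReport(
        n_truth=len(genuine), n_matched=n_matched,
        sensitivity=n_matched / len(genuine) if genuine else float("nan"),
        mode_errors=np.array(mode_errors, dtype=np.int64),
        n_false_clusters=n_false,
        false_cluster_fraction=n_false / len(genuine) if genuine else float("nan"),
        shape_confusion=confusion,
        shape_agreement=n_shape_ok / n_shape_all if n_shape_all else float("nan"),
        n_artifacts=len(artifacts), n_artifacts_surviving=n_art_survive)
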