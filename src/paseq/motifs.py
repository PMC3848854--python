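"""k-mer enrichment, positional motif profiles and per-position
information content around PA cluster modes.

Windows are sense-strand, fixed width (default 100 nt covering offsets
-50..+49 relative to the mode, offset 0 being the cleavage base).
Enrichment is an occurrence-count one-sided binomial test of the
foreground rate against the rate in background windows (by default
random intergenic sequence); overlapping occurrences all count, and
start positions covering an 'N' are skipped.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .formats import GenomeSequence


@dataclass
class SequenceWindowSet:
    windows: list[str]
    ids: list[str] = field(default_factory=list)
    label: str = ""
    flank: int = 50                   # offset of the mode within each window

    def __post_init__(self) -> None:
        widths = {len(w) for w in self.windows}
        if len(widths) > 1:
            raise ValueError("all windows must have the same length")
        self.windows = [w.upper() for w in self.windows]

    @property
    def width(self) -> int:
        return len(self.windows[0]) if self.windows else 0

    def __len__(self) -> int:
        return len(self.windows)


def extract_windows(clusters, genome: GenomeSequence, flank: int = 50,
                    label: str = "") -> SequenceWindowSet:
    """Sense-strand windows of width 2*flank covering offsets
    [-flank, flank) around each cluster mode; clusters whose window runs
    off the contig are skipped."""
    windows, ids = [], []
    for c in clusters:
        if c.strand == "+":
            s, e = c.mode - flank, c.mode + flank
        else:
            s, e = c.mode - flank + 1, c.mode + flank + 1
        try:
            windows.append(genome.extract_window(c.contig, c.strand, s, e))
        except ValueError:
            continue
        ids.append(c.cluster_id)
    return SequenceWindowSet(windows=windows, ids=ids, label=label, flank=flank)


def sample_background_windows(genome: GenomeSequence, genes,
                              n: int = 4000, width: int = 100,
                              seed: int = 0, margin: int = 1000) -> SequenceWindowSet:
    """Random intergenic windows (outside gene spans +/- ``margin``),
    random strand, used as the enrichment background."""
    rng = np.random.default_rng(seed)
    blocked: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in genes:
        s, e = g.span
        blocked[g.contig].append((max(0, s - margin), e + margin))
    free: list[tuple[str, int, int]] = []
    for contig in genome.contigs:
        prev = 0
        for s, e in sorted(blocked.get(contig, [])):
            if s - prev >= width:
                free.append((contig, prev, s))
            prev = max(prev, e)
        L = genome.length(contig)
        if L - prev >= width:
            free.append((contig, prev, L))
    if not free:
        raise ValueError("no intergenic space to sample background from")
    lengths = np.array([e - s - width + 1 for _, s, e in free], dtype=float)
    probs = lengths / lengths.sum()
    windows = []
    for _ in range(n):
        contig, s, e = free[int(rng.choice(len(free), p=probs))]
        start = int(rng.integers(s, e - width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        windows.append(genome.extract_window(contig, strand, start, start + width))
    return SequenceWindowSet(windows=windows, label="background", flank=width // 2)


def _count_kmers(windows: list[str], k: int) -> tuple[Counter, int]:
    """Occurrence counts over all valid start positions (those not
    covering an N) and the number of valid starts."""
    counts: Counter = Counter()
    n_starts = 0
    for w in windows:
        for i in range(len(w) - k + 1):
            kmer = w[i : i + k]
            if "N" in kmer:
                continue
            n_starts += 1
            counts[kmer] += 1
    return counts, n_starts


def kmer_enrichment(fg: SequenceWindowSet, bg: SequenceWindowSet,
                    k: int = 6, alpha: float = 1e-5) -> pd.DataFrame:
    """Per-k-mer foreground/background occurrence counts, fold
    enrichment and one-sided binomial p-value; sorted by p.

    k-mers unseen in the background get a conservative null rate of one
    occurrence over the background start count, keeping p in (0, 1].
    """
    if fg.width < k:
        raise ValueError("window width smaller than k")
    fg_counts, n_fg = _count_kmers(fg.windows, k)
    bg_counts, n_bg = _count_kmers(bg.windows, k)
    if n_bg == 0 or not bg_counts:
        raise ValueError("background contains no countable k-mers")

    rows = []
    for kmer, c_fg in sorted(fg_counts.items()):
        c_bg = bg_counts.get(kmer, 0)
        p0 = max(c_bg, 1) / n_bg
        pval = float(binom.sf(c_fg - 1, n_fg, p0))
        fold = (c_fg / n_fg) / p0
        rows.append((kmer, c_fg, c_bg, fold, pval))
    df = pd.DataFrame(rows, columns=["kmer", "fg", "bg", "fold", "p"])
    df["enriched"] = df["p"] < alpha
    return df.sort_values(["p", "kmer"]).reset_index(drop=True)


def positional_profile(windows: SequenceWindowSet, kmer: str,
                       bin_width: int = 1) -> pd.DataFrame:
    """Motif occurrence frequency per positional bin: occurrences whose
    start falls in the bin, divided by the number of windows.  Bin
    offsets are reported relative to the mode (offset 0)."""
    width = windows.width
    k = len(kmer)
    if k > width:
        raise ValueError("k-mer longer than window")
    if width % bin_width != 0:
        raise ValueError("bin_width must divide the window width")
    n_bins = width // bin_width
    occ = np.zeros(n_bins)
    for w in windows.windows:
        start = 0
        while True:
            i = w.find(kmer, start)
            if i < 0:
                break
            occ[i // bin_width] += 1
            start = i + 1
    freq = occ / len(windows)
    starts = np.arange(n_bins) * bin_width - windows.flank
    return pd.DataFrame({"bin_start_offset": starts, "occurrences": occ.astype(int),
                         "frequency": freq})


def information_content(windows: SequenceWindowSet) -> np.ndarray:
    """Per-position information content in bits: 2 + sum_b f_b log2 f_b
    over A/C/G/T column frequencies, Ns excluded from the column; NaN
    for all-N columns.  Bounded by [0, 2]."""
    if not windows.windows:
        raise ValueError("need at least one window")
    arr = np.array([list(w) for w in windows.windows])
    width = arr.shape[1]
    ic = np.empty(width)
    for j in range(width):
        col = arr[:, j]
        col = col[col != "N"]
        if col.size == 0:
            ic[j] = np.nan
            continue
        _, counts = np.unique(col, return_counts=True)
        f = counts / col.size
        ic[j] = 2.0 + float((f * np.log2(f)).sum())
    return ic
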