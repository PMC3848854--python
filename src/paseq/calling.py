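"""PA cluster calling from pooled cleavage profiles.

Candidate clusters come from a Gaussian-kernel density over tag
positions thresholded against a uniform-background null; each candidate
is resized to its 95% core (shortest window holding 95% of the tags),
filtered by a minimum tag count and by the internal-priming A-content
rule, then classified into Narrow Peak / Broad with Peak / Weak Peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .formats import CleavageProfile, GenomeSequence

logger = logging.getLogger(__name__)


@dataclass
class CallerParams:
    bandwidth: float = 10.0          # Gaussian kernel sd, nt
    threshold_sd: float = 4.0        # density threshold in background SDs
    min_tags: int = 50
    core_fraction: float = 0.95
    priming_window: int = 20
    priming_a_min: int = 15
    shape_window: int = 2            # +/- nt around mode for NP/BP fraction
    shape_span_cut: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must be in (0, 1]")
        if min(self.bandwidth, self.threshold_sd, self.min_tags) <= 0:
            raise ValueError("caller thresholds must be positive")


@dataclass
class PACluster:
    cluster_id: str
    contig: str
    strand: str
    start: int                       # 0-based half-open core bounds
    end: int
    mode: int
    positions: np.ndarray            # sorted positions within the core
    counts: np.ndarray               # pooled counts per position
    total_count: int
    tissue_counts: dict[str, int] = field(default_factory=dict)
    shape: str = ""
    internal_priming: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def resize_core_95(positions: np.ndarray, counts: np.ndarray,
                   core_fraction: float = 0.95,
                   strand: str = "+") -> tuple[int, int, int]:
    """Shortest genomic window [start, end) holding at least
    ``core_fraction`` of the tags, plus the mode within it.

    Ties in window choice go to the smaller width, then the leftmost
    start; ties in the mode go to the 5'-most position on ``strand``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("empty count map")
    order = np.argsort(positions)
    positions, counts = positions[order], counts[order]
    total = int(counts.sum())
    target = core_fraction * total

    prefix = np.concatenate([[0], np.cumsum(counts)])
    best = None  # (width, start_pos, i, j)
    j = 0
    for i in range(len(positions)):
        if j < i:
            j = i
        while j < len(positions) and prefix[j + 1] - prefix[i] < target:
            j += 1
        if j == len(positions):
            break
        width = int(positions[j] - positions[i] + 1)
        cand = (width, int(positions[i]), i, j)
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None  # full window always qualifies
    _, _, i, j = best
    core_pos = positions[i : j + 1]
    core_cnt = counts[i : j + 1]
    mx = core_cnt.max()
    tied = core_pos[core_cnt == mx]
    mode = int(tied.min() if strand == "+" else tied.max())
    return int(core_pos[0]), int(core_pos[-1] + 1), mode


def internal_priming_filter(mode: int, strand: str, contig: str,
                            genome: GenomeSequence, window: int = 20,
                            a_min: int = 15) -> bool:
    """True (drop) iff the sense-strand ``window`` nt immediately
    downstream of the mode contain >= ``a_min`` adenosines.  'N' never
    counts as 'A'.  A window running off the contig keeps the cluster.
    """
    if strand == "+":
        start, end = mode + 1, mode + 1 + window
    else:
        start, end = mode - window, mode
    try:
        seq = genome.extract_window(contig, strand, start, end)
    except ValueError:
        logger.warning("priming window off contig end at %s:%d(%s); "
                       "cluster retained", contig, mode, strand)
        return False
    return seq.count("A") >= a_min


def classify_shape(positions: np.ndarray, counts: np.ndarray, mode: int,
                   span: int, window: int = 2, span_cut: int = 10) -> str:
    """NP/BP/WP from the fraction of core tags within +/-``window`` nt of
    the mode and the core span."""
    near = (positions >= mode - window) & (positions <= mode + window)
    frac = counts[near].sum() / counts.sum()
    if frac >= 0.5:
        return "NP" if span < span_cut else "BP"
    return "WP"


def _islands(positions: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Index ranges [i, j) of runs of positions separated by <= gap."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > gap) + 1
    bounds = np.concatenate([[0], breaks, [positions.size]])
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(len(bounds) - 1)]


def call_pa_clusters(profile: CleavageProfile, params: CallerParams,
                     genome: GenomeSequence) -> list[PACluster]:
    """Call, resize, filter and classify PA clusters per contig/strand.

    The density threshold is the F-seq-style uniform null: the strand's
    tags spread evenly over the contig give a background rate lambda per
    nt; under Poisson sampling the kernel-smoothed density then has
    variance lambda * integral(k^2) = lambda / (2 * sd * sqrt(pi)), and
    the threshold is lambda + threshold_sd * sqrt(that variance).
    """
    if profile.is_empty():
        logger.info("empty cleavage profile: no clusters called")
        return []
    sigma = params.bandwidth
    pad = int(math.ceil(4 * sigma))
    clusters: list[PACluster] = []
    n_priming_dropped = n_min_tags_dropped = 0

    for contig, strand in profile.keys():
        if contig not in genome:
            raise KeyError(f"contig {contig!r} absent from genome")
        pos, cnt = profile.pooled(contig, strand)
        if pos.size == 0:
            continue
        lam = cnt.sum() / genome.length(contig)
        thr = lam + params.threshold_sd * math.sqrt(
            lam / (2.0 * sigma * math.sqrt(math.pi)))

        for i0, i1 in _islands(pos, gap=max(6 * pad // 4, 6 * int(sigma))):
            ipos, icnt = pos[i0:i1], cnt[i0:i1]
            lo = int(ipos[0]) - pad
            hi = int(ipos[-1]) + pad
            grid = np.zeros(hi - lo + 1)
            grid[ipos - lo] = icnt
            dens = gaussian_filter1d(grid, sigma=sigma, mode="constant",
                                     truncate=4.0)
            above = dens > thr
            if not above.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(
                [[0], above.view(np.int8), [0]])))
            for a, b in zip(edges[::2], edges[1::2]):
                gs, ge = lo + int(a), lo + int(b)  # candidate [gs, ge)
                sel = (ipos >= gs) & (ipos < ge)
                if not sel.any():
                    continue
                cpos, ccnt = ipos[sel], icnt[sel]
                s, e, mode = resize_core_95(cpos, ccnt,
                                            params.core_fraction, strand)
                core = (cpos >= s) & (cpos < e)
                kpos, kcnt = cpos[core], ccnt[core]
                total = int(kcnt.sum())
                if total < params.min_tags:
                    n_min_tags_dropped += 1
                    continue
                if internal_priming_filter(mode, strand, contig, genome,
                                           params.priming_window,
                                           params.priming_a_min):
                    n_priming_dropped += 1
                    continue
                shape = classify_shape(kpos, kcnt, mode, e - s,
                                       params.shape_window,
                                       params.shape_span_cut)
                clusters.append(PACluster(
                    cluster_id="", contig=contig, strand=strand, start=s,
                    end=e, mode=mode, positions=kpos, counts=kcnt,
                    total_count=total,
                    tissue_counts=profile.tissue_counts_in(contig, strand, s, e),
                    shape=shape))

    clusters.sort(key=lambda c: (c.contig, c.start, c.strand))
    for i, cl in enumerate(clusters, 1):
        cl.cluster_id = f"PAC{i:05d}"
    logger.info("called %d clusters (%d dropped by min_tags, %d by the "
                "internal-priming filter)", len(clusters),
                n_min_tags_dropped, n_priming_dropped)
    return clusters


def read_cluster_table(path) -> tuple[list[PACluster], list[str]]:
    """Read a cluster table written by :func:`write_cluster_table`.

    Per-position count maps are not serialized; the returned clusters
    carry the core bounds, mode, totals, shape and per-tissue counts,
    which is all the downstream stages use.
    """
    clusters: list[PACluster] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").lstrip("#").split("\t")
        tissues = header[9:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            counts = {t: int(c) for t, c in zip(tissues, f[9:]) if int(c)}
            clusters.append(PACluster(
                cluster_id=f[3], contig=f[0], strand=f[5], start=int(f[1]),
                end=int(f[2]), mode=int(f[6]),
                positions=np.array([], dtype=np.int64),
                counts=np.array([], dtype=np.int64),
                total_count=int(f[4]), tissue_counts=counts, shape=f[8]))
    return clusters, tissues


def write_cluster_table(clusters: list[PACluster], tissues: list[str],
                        path) -> None:
    """BED6+ cluster table: contig, start, end, id, total, strand, mode,
    span, shape, then one count column per tissue."""
    with open(path, "w") as fh:
        header = ["#contig", "start", "end", "cluster_id", "total_count",
                  "strand", "mode", "span", "shape"] + list(tissues)
        fh.write("\t".join(header) + "\n")
        for c in clusters:
            row = [c.contig, c.start, c.end, c.cluster_id, c.total_count,
                   c.strand, c.mode, c.span, c.shape]
            row += [c.tissue_counts.get(t, 0) for t in tissues]
            fh.write("\t".join(map(str, row)) + "\n")
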