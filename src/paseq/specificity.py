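"""Tissue specificity of PA cluster usage.

The clusters x tissues count matrix is library-size scaled to tags per
million and quantile normalized.  Per cluster, relative usages p_t give
the Shannon entropy H = -sum p_t log2 p_t (bits) and per-tissue
specificity scores Q_t = H - log2 p_t (defined where p_t > 0; Q is
small exactly when the cluster is both low-entropy and concentrated in
tissue t).  Calls:

* specific to tissue t:  H < median(H) - 2 sd(H)  and
                         Q_t < median(Q) - 2 sd(Q)
* constitutive:          H > mean(H) + 2 sd(H)    and
                         min_t Q_t > mean(Q) + 2 sd(Q)

with the thresholds computed over the dataset itself (median/sd of Q
over all defined Q values) and exposed as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PACountMatrix", "normalize_matrix", "quantile_normalize",
    "entropy_and_q", "classify_specificity", "tissue_usage",
    "hcluster_two_way", "matrix_from_clusters",
]


@dataclass
class PACountMatrix:
    raw: pd.DataFrame                 # clusters x tissues, integer counts
    library_sizes: pd.Series
    rpm: pd.DataFrame                 # per-million library-size scaled
    qn: pd.DataFrame                  # quantile normalized

    @property
    def tissues(self) -> list[str]:
        return list(self.raw.columns)


def matrix_from_clusters(clusters, tissues: list[str],
                         library_sizes: dict[str, int] | None = None) -> PACountMatrix:
    """Build and normalize the counts matrix from called clusters.

    Library sizes default to each tissue's total tag count in the
    profile the clusters were called from; pass them explicitly when
    clusters cover only part of the data.
    """
    raw = pd.DataFrame(
        [[c.tissue_counts.get(t, 0) for t in tissues] for c in clusters],
        index=[c.cluster_id for c in clusters], columns=tissues, dtype=float)
    if library_sizes is None:
        library_sizes = raw.sum(axis=0).to_dict()
    return normalize_matrix(raw, pd.Series(library_sizes)[tissues])


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: every column's sorted values are
    replaced by the mean order statistic across columns; ties receive the
    mean of the tied quantile values.  Idempotent."""
    values = df.to_numpy(dtype=float)
    n = values.shape[0]
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        sorted_vals = values[order, j]
        col = ref.copy()
        # average the reference over each run of tied input values
        run_start = np.flatnonzero(np.concatenate(
            [[True], sorted_vals[1:] != sorted_vals[:-1]]))
        run_end = np.concatenate([run_start[1:], [n]])
        for s, e in zip(run_start, run_end):
            if e - s > 1:
                col[s:e] = ref[s:e].mean()
        out[order, j] = col
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize_matrix(raw: pd.DataFrame, library_sizes: pd.Series) -> PACountMatrix:
    """Library-size scale each tissue to tags per million, then quantile
    normalize across tissues.  All-zero library columns are dropped with
    a warning."""
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw counts must be non-negative")
    library_sizes = library_sizes[raw.columns].astype(float)
    dead = library_sizes[library_sizes <= 0].index.tolist()
    if dead:
        warnings.warn(f"dropping all-zero tissue columns: {dead}")
        raw = raw.drop(columns=dead)
        library_sizes = library_sizes.drop(index=dead)
    rpm = raw * (1e6 / library_sizes)
    qn = quantile_normalize(rpm)
    return PACountMatrix(raw=raw, library_sizes=library_sizes, rpm=rpm, qn=qn)


def entropy_and_q(row: np.ndarray) -> tuple[float, np.ndarray]:
    """Shannon entropy H (bits) of a cluster's relative tissue usage and
    the per-tissue Q_t = H - log2 p_t (NaN where p_t = 0)."""
    row = np.asarray(row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("row must have positive total")
    p = row / total
    nz = p > 0
    H = float(-(p[nz] * np.log2(p[nz])).sum())
    q = np.full(row.shape, np.nan)
    q[nz] = H - np.log2(p[nz])
    return H, q


@dataclass
class SpecificityResult:
    table: pd.DataFrame          # per cluster: H, call, specific_tissue
    q: pd.DataFrame              # per cluster x tissue Q values (NaN where p=0)
    thresholds: dict[str, float] = field(default_factory=dict)
    n_excluded: int = 0


def classify_specificity(matrix: PACountMatrix,
                         h_specific: float | None = None,
                         q_specific: float | None = None,
                         h_constitutive: float | None = None,
                         q_constitutive: float | None = None) -> SpecificityResult:
    """Call each cluster specific / constitutive / other from its H and Q
    scores on the quantile-normalized layer.  Threshold overrides replace
    the data-derived median/mean +/- 2 sd cutoffs."""
    qn = matrix.qn
    totals = qn.sum(axis=1)
    keep = totals > 0
    n_excluded = int((~keep).sum())
    data = qn.loc[keep]
    if len(data) < 10:
        warnings.warn(f"only {len(data)} usable rows: specificity thresholds "
                      "are unreliable")

    H = np.empty(len(data))
    Q = np.empty(data.shape)
    for i, (_, row) in enumerate(data.iterrows()):
        H[i], Q[i] = entropy_and_q(row.to_numpy())

    q_flat = Q[~np.isnan(Q)]
    thr = {
        "h_specific": (float(np.median(H) - 2 * np.std(H))
                       if h_specific is None else h_specific),
        "q_specific": (float(np.median(q_flat) - 2 * np.std(q_flat))
                       if q_specific is None else q_specific),
        "h_constitutive": (float(np.mean(H) + 2 * np.std(H))
                           if h_constitutive is None else h_constitutive),
        "q_constitutive": (float(np.mean(q_flat) + 2 * np.std(q_flat))
                           if q_constitutive is None else q_constitutive),
    }

    calls, spec_tissue = [], []
    tissues = list(data.columns)
    with np.errstate(invalid="ignore"):
        for i in range(len(data)):
            qi = Q[i]
            if H[i] < thr["h_specific"] and np.nanmin(qi) < thr["q_specific"]:
                calls.append("specific")
                spec_tissue.append(tissues[int(np.nanargmin(qi))])
            elif (H[i] > thr["h_constitutive"]
                  and np.nanmin(qi) > thr["q_constitutive"]
                  and not np.isnan(qi).any()):
                calls.append("constitutive")
                spec_tissue.append(None)
            else:
                calls.append("other")
                spec_tissue.append(None)

    table = pd.DataFrame({"H": H, "call": calls, "specific_tissue": spec_tissue},
                         index=data.index)
    qdf = pd.DataFrame(Q, index=data.index, columns=data.columns)
    return SpecificityResult(table=table, q=qdf, thresholds=thr,
                             n_excluded=n_excluded)


def tissue_usage(matrix: PACountMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Boolean utilization (quantile-normalized count strictly above the
    tissue's column median) and the histogram of the number of utilizing
    tissues per cluster (bins 0..n_tissues)."""
    qn = matrix.qn
    util = qn.gt(qn.median(axis=0), axis=1)
    n_tissues = qn.shape[1]
    hist = np.bincount(util.sum(axis=1).to_numpy(), minlength=n_tissues + 1)
    return util, hist


# ---------------------------------------------------------------------------
# two-way hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class TwoWayClustering:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_newick: str
    col_newick: str
    matrix: pd.DataFrame         # log-transformed, reordered
    dropped_rows: list[str] = field(default_factory=list)


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def hcluster_two_way(df: pd.DataFrame, log_transform: bool = True) -> TwoWayClustering:
    """Cluster both axes with 1 - Pearson correlation distance and
    average (UPGMA) linkage, after an optional log2(x + 1) transform.
    Zero-variance rows are excluded (their correlation is undefined)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import pdist

    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix to cluster")
    data = np.log2(df + 1.0) if log_transform else df.astype(float)
    var = data.var(axis=1)
    dropped = list(data.index[var == 0])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} zero-variance rows")
        data = data.loc[var > 0]
    if data.var(axis=0).eq(0).any():
        cols = list(data.columns[data.var(axis=0) == 0])
        warnings.warn(f"excluding zero-variance columns: {cols}")
        data = data.drop(columns=cols)

    row_link = average(pdist(data.to_numpy(), metric="correlation"))
    col_link = average(pdist(data.to_numpy().T, metric="correlation"))
    row_order = [data.index[i] for i in leaves_list(row_link)]
    col_order = [data.columns[i] for i in leaves_list(col_link)]
    return TwoWayClustering(
        row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
        row_newick=_linkage_to_newick(row_link, list(data.index)),
        col_newick=_linkage_to_newick(col_link, list(data.columns)),
        matrix=data.loc[row_order, col_order], dropped_rows=dropped)
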