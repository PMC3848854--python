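"""Normalization, entropy/Q scores, specificity calls, tissue usage and
two-way clustering."""

import io

import numpy as np
import pandas as pd
import pytest

from paseq import (classify_specificity, entropy_and_q, hcluster_two_way,
                   normalize_matrix, quantile_normalize, tissue_usage)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_quantile_normalize_hand_example():
    df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["a", "b"])
    qn = quantile_normalize(df)
    assert qn.to_numpy().tolist() == [[1.5, 1.5], [3.5, 3.5]]


def test_quantile_normalize_equal_column_multisets_and_idempotent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.lognormal(3, 1, size=(50, 5)))  # tie-free
    qn = quantile_normalize(df)
    ref = np.sort(qn.iloc[:, 0].to_numpy())
    for j in range(qn.shape[1]):
        assert np.allclose(np.sort(qn.iloc[:, j].to_numpy()), ref)
    assert np.allclose(quantile_normalize(qn).to_numpy(), qn.to_numpy())


def test_quantile_normalize_tie_handling():
    # tied values within a column share the mean of the tied quantiles
    df = pd.DataFrame({"a": [5.0, 5.0, 10.0], "b": [1.0, 2.0, 3.0]})
    qn = quantile_normalize(df)
    assert qn["a"].iloc[0] == qn["a"].iloc[1]
    # a full-column tie gets the mean of ALL its quantile values
    df3 = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
    qn3 = quantile_normalize(df3)
    # reference = mean of sorted columns = [3, 3.5, 4]
    assert qn3["a"].tolist() == [3.5, 3.5, 3.5]
    assert qn3["b"].tolist() == [3.0, 3.5, 4.0]


def test_library_size_scaling():
    raw = pd.DataFrame({"a": [10.0, 30.0], "b": [5.0, 15.0]})
    lib = pd.Series({"a": 40.0, "b": 20.0})
    m = normalize_matrix(raw, lib)
    assert m.rpm["a"].sum() == pytest.approx(1e6)
    assert m.rpm["b"].sum() == pytest.approx(1e6)


def test_all_zero_library_column_dropped():
    raw = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
    lib = pd.Series({"a": 3.0, "b": 0.0})
    with pytest.warns(UserWarning, match="all-zero"):
        m = normalize_matrix(raw, lib)
    assert list(m.raw.columns) == ["a"]


# ---------------------------------------------------------------------------
# entropy and Q
# ---------------------------------------------------------------------------

def test_entropy_closed_forms():
    H, q = entropy_and_q(np.ones(13))
    assert H == pytest.approx(np.log2(13), abs=1e-12)
    H1, q1 = entropy_and_q([0, 0, 7, 0])
    assert H1 == 0.0
    assert q1[2] == 0.0 and np.isnan(q1[0])
    H2, q2 = entropy_and_q([5, 5, 0])
    assert H2 == pytest.approx(1.0, abs=1e-12)
    assert q2[0] == pytest.approx(2.0, abs=1e-12)
    assert q2[1] == pytest.approx(2.0, abs=1e-12)


def test_entropy_permutation_invariant_and_argmin_q():
    rng = np.random.default_rng(3)
    for _ in range(20):
        row = rng.integers(0, 100, size=8).astype(float)
        if row.sum() == 0:
            continue
        H, q = entropy_and_q(row)
        perm = rng.permutation(8)
        H2, _ = entropy_and_q(row[perm])
        assert H == pytest.approx(H2, abs=1e-12)
        assert 0 <= H <= np.log2(8) + 1e-12
        if row.max() > 0:
            assert np.nanargmin(q) == np.argmax(row)


def test_all_zero_row_excluded(matrix):
    res = classify_specificity(matrix)
    assert res.table["H"].notna().all()


def test_specificity_calls_on_planted_matrix(sim, called, matrix):
    """Planted 90%-dominated sites are called specific to the dominant
    tissue; uniform sites are never called specific."""
    truth_by_mode = {(t.contig, t.strand, t.mode): t
                     for t in sim.truth if not t.is_artifact}
    res = classify_specificity(matrix)
    tp = fn = correct = uniform_specific = 0
    for c in called:
        t = None
        for off in range(-5, 6):
            t = truth_by_mode.get((c.contig, c.strand, c.mode + off))
            if t is not None:
                break
        if t is None or c.cluster_id not in res.table.index:
            continue
        row = res.table.loc[c.cluster_id]
        if t.is_tissue_specific:
            if row["call"] == "specific":
                tp += 1
                correct += int(row["specific_tissue"] == t.dominant_tissue)
            else:
                fn += 1
        elif row["call"] == "specific":
            uniform_specific += 1
    assert tp + fn > 10
    assert tp / (tp + fn) >= 0.9
    assert correct / tp >= 0.95
    assert uniform_specific == 0


def test_few_rows_warns():
    raw = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
    m = normalize_matrix(raw, pd.Series(1.0, index=list("abc")))
    with pytest.warns(UserWarning, match="unreliable"):
        classify_specificity(m)


# ---------------------------------------------------------------------------
# tissue usage
# ---------------------------------------------------------------------------

def test_tissue_usage_strict_median_rule():
    raw = pd.DataFrame({"a": [1.0, 5.0, 9.0], "b": [2.0, 2.0, 2.0]})
    lib = pd.Series({"a": 15.0, "b": 6.0})
    m = normalize_matrix(raw, lib)
    util, hist = tissue_usage(m)
    # column medians: any value equal to the median is NOT utilized
    for col in m.qn:
        med = m.qn[col].median()
        assert (util[col] == (m.qn[col] > med)).all()
    assert hist.sum() == 3


def test_tissue_usage_histogram_top_bin(matrix):
    util, hist = tissue_usage(matrix)
    n_tissues = matrix.qn.shape[1]
    assert hist.sum() == matrix.qn.shape[0]
    assert hist[n_tissues] == (util.sum(axis=1) == n_tissues).sum()


# ---------------------------------------------------------------------------
# two-way clustering
# ---------------------------------------------------------------------------

def test_identical_columns_merge_first():
    rng = np.random.default_rng(1)
    base = rng.random(20)
    df = pd.DataFrame({"x": base, "y": base, "z": rng.random(20),
                       "w": rng.random(20)})
    cl = hcluster_two_way(df, log_transform=False)
    first = cl.col_linkage[0]
    assert first[2] == pytest.approx(0.0, abs=1e-12)
    merged = {int(first[0]), int(first[1])}
    assert merged == {0, 1}   # x and y


def test_anticorrelated_distance_two():
    from scipy.spatial.distance import pdist
    x = np.arange(10.0)
    d = pdist(np.vstack([x, -x]), metric="correlation")
    assert d[0] == pytest.approx(2.0)


def test_block_structure_topology_and_newick():
    rng = np.random.default_rng(5)
    sig1 = rng.random(30) * 10
    sig2 = rng.random(30) * 10
    df = pd.DataFrame({
        "A": sig1 + rng.normal(0, 0.01, 30),
        "B": sig1 + rng.normal(0, 0.01, 30),
        "C": sig2 + rng.normal(0, 0.01, 30),
        "D": sig2 + rng.normal(0, 0.01, 30)})
    cl = hcluster_two_way(df, log_transform=False)
    order = cl.col_order
    assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} \
        == {("A", "B"), ("C", "D")}
    from Bio import Phylo
    tree = Phylo.read(io.StringIO(cl.col_newick), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C", "D"]


def test_zero_variance_rows_excluded():
    df = pd.DataFrame({"a": [1.0, 2.0, 2.0], "b": [1.0, 4.0, 2.0],
                       "c": [1.0, 6.0, 3.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        cl = hcluster_two_way(df, log_transform=False)
    assert cl.dropped_rows == [0]
    assert len(cl.row_order) == 2
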