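"""Marker statistics: Wilcoxon exactness, thresholds, Jaccard, composition,
time-split markers and hypergeometric enrichment."""

import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from dielsc import (
    find_markers,
    generate_count_matrix,
    hypergeom_enrichment,
    jaccard_overlap,
    make_truth,
    marker_sets,
    split_markers_by_time,
    time_composition,
)
from dielsc.markers import rank_sum_p


def _adata(X, cells=None, genes=None, timepoint=None):
    X = np.asarray(X)
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    obs = pd.DataFrame(index=cells)
    if timepoint is not None:
        obs["timepoint"] = timepoint
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs,
                      var=pd.DataFrame(index=genes))


# ------------------------------------------------------------- Wilcoxon

def exhaustive_rank_sum_p(x, y):
    """Two-sided rank-sum p by full enumeration of all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        if abs(s - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_wilcoxon_six_vs_six_matches_enumeration():
    rng = np.random.default_rng(31)
    for _ in range(5):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 6)
        values = np.concatenate([x, y])[:, None]
        mask = np.zeros(12, dtype=bool)
        mask[:6] = True
        p = rank_sum_p(values, mask, np.array([0]))[0]
        assert p == pytest.approx(exhaustive_rank_sum_p(x, y), abs=1e-12)


def test_wilcoxon_exact_for_small_groups_up_to_eight():
    rng = np.random.default_rng(37)
    for n1, n2 in [(3, 5), (4, 4), (8, 8)]:
        x = rng.normal(0, 1, n1)
        y = rng.normal(1, 1, n2)
        values = np.concatenate([x, y])[:, None]
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[:n1] = True
        p = rank_sum_p(values, mask, np.array([0]))[0]
        assert p == pytest.approx(exhaustive_rank_sum_p(x, y), abs=1e-12)


# ------------------------------------------------------- marker thresholds

def test_unexpressed_gene_is_not_marker():
    # gene g0 expressed only outside the cluster; strong signal either way
    X = np.zeros((40, 2))
    X[20:, 0] = 50  # g0: 0% of in-cluster cells
    X[:20, 1] = 50
    X[:, 1] += 1
    adata = _adata(X)
    labels = pd.Series(["in"] * 20 + ["out"] * 20, index=adata.obs_names)
    table = find_markers(adata, labels)
    sub = table[(table["gene"] == "g0") & (table["cluster"] == "in")]
    assert sub.empty or not sub["is_marker"].any()


def test_planted_markers_flagged_and_nulls_controlled(two_cluster_adata):
    """Planted markers are recovered; Bonferroni keeps familywise error on
    the null genes controlled, so false markers are at most an isolated
    borderline event per scan."""
    truth = two_cluster_adata.uns["truth"]
    labels = pd.Series(
        [str(truth.cluster_of_cell[c]) for c in two_cluster_adata.obs_names],
        index=two_cluster_adata.obs_names,
    )
    sets = marker_sets(find_markers(two_cluster_adata, labels))
    n_false = 0
    for k, planted in truth.marker_genes_of_cluster.items():
        found = sets.get(str(k), set())
        assert len(found & planted) / len(planted) >= 0.9
        n_false += len(found - planted)
    assert n_false <= 1


def test_padj_at_least_p_and_marker_rows_thresholded(two_cluster_adata):
    truth = two_cluster_adata.uns["truth"]
    labels = pd.Series(
        [str(truth.cluster_of_cell[c]) for c in two_cluster_adata.obs_names],
        index=two_cluster_adata.obs_names,
    )
    table = find_markers(two_cluster_adata, labels)
    assert (table["p_adj"] >= table["p"] - 1e-15).all()
    flagged = table[table["is_marker"]]
    assert (flagged["p_adj"] < 0.05).all()
    assert (flagged["log_fc"] >= 0.25).all()
    assert (flagged["pct_in"] >= 0.05).all()


def test_markers_invariant_to_cell_order_and_depth_scaling(two_cluster_adata):
    truth = two_cluster_adata.uns["truth"]
    labels = pd.Series(
        [str(truth.cluster_of_cell[c]) for c in two_cluster_adata.obs_names],
        index=two_cluster_adata.obs_names,
    )
    base = marker_sets(find_markers(two_cluster_adata, labels))
    rng = np.random.default_rng(0)
    perm = rng.permutation(two_cluster_adata.n_obs)
    shuffled = two_cluster_adata[perm].copy()
    assert marker_sets(find_markers(shuffled, labels)) == base
    # doubling one cell's counts changes nothing after depth normalization
    scaled = two_cluster_adata.copy()
    X = scaled.X.tolil()
    X[0] = X[0] * 2
    scaled.X = X.tocsr()
    assert marker_sets(find_markers(scaled, labels)) == base


def test_single_cluster_rejected(two_cluster_adata):
    labels = pd.Series("only", index=two_cluster_adata.obs_names)
    with pytest.raises(ValueError):
        find_markers(two_cluster_adata, labels)


# ---------------------------------------------------------------- Jaccard

def test_jaccard_identical_disjoint_and_printed_example():
    a = {"x": {f"g{i}" for i in range(10)}}
    assert jaccard_overlap(a, a)["jaccard"].iloc[0] == 1.0
    b = {"y": {f"h{i}" for i in range(5)}}
    assert jaccard_overlap(a, b)["jaccard"].iloc[0] == 0.0
    # |A ∩ B| = 82, |A ∪ B| = 264 -> J = 82/264 = 0.3106...
    shared = {f"s{i}" for i in range(82)}
    setA = shared | {f"a{i}" for i in range(100)}
    setB = shared | {f"b{i}" for i in range(82)}
    row = jaccard_overlap({"root32": setA}, {"shoot13a": setB}).iloc[0]
    assert row["intersection"] == 82
    assert row["union"] == 264
    assert row["jaccard"] == pytest.approx(0.3106, abs=5e-5)
    assert round(row["jaccard"], 2) == 0.31


def test_jaccard_symmetric_bounded_and_empty_flagged():
    rng = np.random.default_rng(5)
    sets_a = {i: {f"g{rng.integers(0, 50)}" for _ in range(rng.integers(0, 20))} for i in range(4)}
    sets_b = {i: {f"g{rng.integers(0, 50)}" for _ in range(rng.integers(0, 20))} for i in range(4)}
    ab = jaccard_overlap(sets_a, sets_b)
    ba = jaccard_overlap(sets_b, sets_a)
    assert ((ab["jaccard"] >= 0) & (ab["jaccard"] <= 1)).all()
    for _, r in ab.iterrows():
        mirror = ba[(ba["cluster_a"] == r["cluster_b"]) & (ba["cluster_b"] == r["cluster_a"])]
        assert mirror["jaccard"].iloc[0] == r["jaccard"]
    empty = jaccard_overlap({"e": set()}, {"f": set()})
    assert empty["jaccard"].iloc[0] == 0.0
    assert bool(empty["both_empty"].iloc[0])


# ------------------------------------------------------------ composition

def test_all_ed_composition():
    labels = pd.Series(["0"] * 5 + ["1"] * 5, index=[f"c{i}" for i in range(10)])
    tp = pd.Series("ED", index=labels.index)
    comp = time_composition(labels, tp)
    assert (comp["frac_ED"] == 1.0).all()
    assert (comp["frac_EN"] == 0.0).all()


def test_missing_timepoint_names_cell():
    labels = pd.Series({"c1": "0", "c2": "0"})
    tp = pd.Series({"c1": "ED"})
    with pytest.raises(ValueError, match="c2"):
        time_composition(labels, tp)


def test_balanced_batches_give_mixed_clusters():
    truth = make_truth(n_cells=200, n_clusters=2, markers_per_cluster=10,
                       n_genes=100, seed=41, batch="balanced")
    labels = pd.Series({c: str(k) for c, k in truth.cluster_of_cell.items()})
    tp = pd.Series(dict(truth.batch_of_cell))
    comp = time_composition(labels, tp)
    assert np.allclose(comp["frac_ED"], 0.5, atol=0.1)
    assert comp["mixed"].all()


def test_batch_driven_clusters_are_pure():
    truth = make_truth(n_cells=200, n_clusters=2, markers_per_cluster=10,
                       n_genes=100, seed=43, batch="by_cluster")
    labels = pd.Series({c: str(k) for c, k in truth.cluster_of_cell.items()})
    tp = pd.Series(dict(truth.batch_of_cell))
    comp = time_composition(labels, tp)
    assert (comp[["frac_ED", "frac_EN"]].max(axis=1) >= 0.95).all()
    assert not comp["mixed"].any()


# ------------------------------------------------------------- time-split

def test_identical_timepoints_have_no_exclusive_markers(two_cluster_adata):
    truth = two_cluster_adata.uns["truth"]
    labels = pd.Series(
        [str(truth.cluster_of_cell[c]) for c in two_cluster_adata.obs_names],
        index=two_cluster_adata.obs_names,
    )
    # duplicate every cell into a fake ED and EN copy with identical counts
    X = two_cluster_adata.X
    both = ad.AnnData(
        X=sparse.vstack([X, X]).tocsr(),
        obs=pd.DataFrame(
            {"timepoint": ["ED"] * two_cluster_adata.n_obs + ["EN"] * two_cluster_adata.n_obs},
            index=[f"{c}@ED" for c in two_cluster_adata.obs_names]
            + [f"{c}@EN" for c in two_cluster_adata.obs_names],
        ),
        var=two_cluster_adata.var.copy(),
    )
    lab2 = pd.Series(
        list(labels) * 2, index=both.obs_names
    )
    res = split_markers_by_time(both, lab2)
    assert res["exclusive"].empty


def test_ed_only_marker_is_exclusive_but_not_global_de():
    """A gene cluster-specific only within ED cells, globally balanced
    between ED and EN, appears ED-exclusive with global_de False."""
    rng = np.random.default_rng(47)
    n = 240  # 60 cells per (cluster, timepoint)
    X = rng.poisson(5, size=(n, 60)).astype(float)
    cells = [f"c{i}" for i in range(n)]
    cluster = np.array(["A", "B"] * (n // 2))
    tp = np.array(["ED"] * (n // 2) + ["EN"] * (n // 2))
    special = (cluster == "A") & (tp == "ED")
    # ED: A-specific. EN: expressed equally in A and B at the same mean, so
    # globally (ED+EN vs nothing) ED and EN carry the same total signal.
    X[special, 0] = rng.poisson(40, special.sum())
    X[tp == "EN", 0] = rng.poisson(20, (tp == "EN").sum())
    X[~special & (tp == "ED"), 0] = 0.0
    adata = _adata(X, cells=cells, timepoint=list(tp))
    labels = pd.Series(cluster, index=cells)
    res = split_markers_by_time(adata, labels)
    row = res["exclusive"][(res["exclusive"]["gene"] == "g0")]
    assert not row.empty
    assert set(row["exclusive_to"]) == {"ED"}
    assert not row["global_de"].any()


# ------------------------------------------------------------- enrichment

def test_hypergeometric_closed_form_cases():
    uni = {f"g{i}" for i in range(10)}
    cat = {f"g{i}" for i in range(5)}
    markers = {f"g{i}" for i in range(4)}
    res = hypergeom_enrichment({"c": markers}, {"cat": cat}, uni)
    # k=4, K=5, n=4, N=10: p = C(5,4)C(5,0)/C(10,4) = 5/210
    assert res["p"].iloc[0] == pytest.approx(5 / 210, rel=1e-12)
    assert res["k"].iloc[0] == 4

    # k = 0 -> p = P(X >= 0) = 1
    res0 = hypergeom_enrichment({"c": {"g9"}}, {"cat": {"g0"}}, uni)
    assert res0["p"].iloc[0] == pytest.approx(1.0)

    # category = universe -> k = n, p = 1
    resU = hypergeom_enrichment({"c": markers}, {"all": uni}, uni)
    assert resU["k"].iloc[0] == len(markers)
    assert resU["p"].iloc[0] == pytest.approx(1.0)


def test_hypergeometric_matches_combinatorial_oracle():
    rng = np.random.default_rng(53)
    uni = [f"g{i}" for i in range(30)]
    for _ in range(20):
        K = int(rng.integers(1, 20))
        n = int(rng.integers(1, 15))
        cat = set(rng.choice(uni, K, replace=False))
        markers = set(rng.choice(uni, n, replace=False))
        res = hypergeom_enrichment({"c": markers}, {"cat": cat}, set(uni))
        k = len(cat & markers)
        N = 30
        expected = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
        )
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_enrichment_input_validation():
    with pytest.raises(ValueError):
        hypergeom_enrichment({"c": {"g1"}}, {"cat": {"g1"}}, set())
    with pytest.raises(ValueError):
        hypergeom_enrichment({"c": {"outsider"}}, {"cat": {"g1"}}, {"g1"})
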