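"""One-vs-rest marker genes, marker-set overlap, time-point composition
and category enrichment.

Marker detection reproduces the standard droplet workflow thresholds:
counts are depth-normalized to 10,000 per cell and ln(1+x) transformed;
each gene is tested per cluster with a two-sided Wilcoxon rank-sum of
in-cluster versus all remaining cells; a gene is a marker when its
Bonferroni-adjusted p-value is below 0.05, its natural-log fold change is
at least 0.25, and at least 5% of in-cluster cells express it.  The
rank-sum p-value is exact (full permutation null) for small tie-free
groups and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .cluster import ClusterAssignment

__all__ = [
    "find_markers",
    "marker_sets",
    "jaccard_overlap",
    "time_composition",
    "split_markers_by_time",
    "hypergeom_enrichment",
    "read_category_map",
]

_EPS = 1e-9
_EXACT_MAX_N = 8  # per-group ceiling for the exact permutation p-value


def _depth_normalized(adata: ad.AnnData, target_sum: float = 1e4) -> np.ndarray:
    """Counts per ``target_sum`` (linear scale)."""
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return X / totals * target_sum


def _normalized(adata: ad.AnnData, target_sum: float = 1e4) -> np.ndarray:
    return np.log1p(_depth_normalized(adata, target_sum))


def rank_sum_p(values: np.ndarray, in_mask: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p for selected gene columns.

    ``values`` is cells × genes (normalized expression), ``in_mask`` the
    in-group indicator, ``genes`` the column indices to test.  Uses the
    exact distribution when both groups have at most 8 cells and the
    column has no ties; otherwise a tie-corrected normal approximation
    without continuity correction.
    """
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    n = n1 + n2
    out = np.ones(len(genes))
    if n1 == 0 or n2 == 0:
        return out
    sub = values[:, genes]
    small = n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N
    ranks = stats.rankdata(sub, axis=0)
    r_in = ranks[in_mask].sum(axis=0)
    u = r_in - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per column
    tie_term = np.zeros(len(genes))
    for j in range(len(genes)):
        _, counts = np.unique(sub[:, j], return_counts=True)
        t = counts[counts > 1]
        tie_term[j] = (t**3 - t).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    for j in range(len(genes)):
        col = sub[:, j]
        has_ties = len(np.unique(col)) < n
        if small and not has_ties:
            out[j] = stats.mannwhitneyu(
                col[in_mask], col[~in_mask], alternative="two-sided", method="exact"
            ).pvalue
        elif var[j] <= 0:
            out[j] = 1.0
        else:
            z = (u[j] - mu) / np.sqrt(var[j])
            out[j] = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return out


def find_markers(
    adata: ad.AnnData,
    clusters: ClusterAssignment | pd.Series,
    logfc_min: float = 0.25,
    min_pct: float = 0.05,
    alpha: float = 0.05,
    *,
    adjust: str = "bonferroni",
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker table across all clusters.

    Returns one row per (gene, cluster) that survives the pre-screen
    (expressed in at least ``min_pct`` of cells on either side and
    \\|log fold change\\| ≥ ``logfc_min``), with columns ``gene, cluster,
    log_fc, pct_in, pct_out, p, p_adj, is_marker``.  ``log_fc`` is
    ln(mean_in + ε) − ln(mean_out + ε) of depth-normalized expression
    (linear scale); the rank-sum test runs on the log-normalized values,
    whose ranks are identical.  Bonferroni
    adjustment multiplies by the total gene count of the matrix; pass
    ``adjust="bh"`` for Benjamini–Hochberg within each cluster.  Clusters
    with fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = clusters.label_of_cell if isinstance(clusters, ClusterAssignment) else clusters
    labels = labels.reindex(adata.obs_names)
    uniq = sorted(labels.dropna().unique())
    if len(uniq) < 2:
        raise ValueError("marker detection needs at least two clusters")
    linear = _depth_normalized(adata)
    norm = np.log1p(linear)  # ranks under the test are the same either way
    n_genes = adata.n_vars
    rows = []
    for cl in uniq:
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < min_cells:
            import warnings

            warnings.warn(f"cluster {cl!r} has <{min_cells} cells; skipped")
            continue
        out_mask = ~in_mask
        pct_in = (linear[in_mask] > 0).mean(axis=0)
        pct_out = (linear[out_mask] > 0).mean(axis=0)
        # fold change on the depth-normalized linear scale
        mean_in = linear[in_mask].mean(axis=0)
        mean_out = linear[out_mask].mean(axis=0)
        log_fc = np.log(mean_in + _EPS) - np.log(mean_out + _EPS)
        tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (np.abs(log_fc) >= logfc_min)
        idx = np.flatnonzero(tested)
        if idx.size == 0:
            continue
        p = rank_sum_p(norm, in_mask, idx)
        if adjust == "bonferroni":
            p_adj = np.minimum(1.0, p * n_genes)
        elif adjust == "bh":
            p_adj = stats.false_discovery_control(p, method="bh")
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for k, j in enumerate(idx):
            rows.append(
                {
                    "gene": adata.var_names[j],
                    "cluster": cl,
                    "log_fc": log_fc[j],
                    "pct_in": pct_in[j],
                    "pct_out": pct_out[j],
                    "p": p[k],
                    "p_adj": p_adj[k],
                    "is_marker": bool(
                        p_adj[k] < alpha and log_fc[j] >= logfc_min and pct_in[j] >= min_pct
                    ),
                }
            )
    cols = ["gene", "cluster", "log_fc", "pct_in", "pct_out", "p", "p_adj", "is_marker"]
    return pd.DataFrame(rows, columns=cols)


def marker_sets(table: pd.DataFrame) -> dict:
    """Per-cluster sets of flagged marker genes from a marker table."""
    out: dict = {}
    if table.empty:
        return out
    for cl, sub in table[table["is_marker"].astype(bool)].groupby("cluster", observed=True):
        out[cl] = set(sub["gene"])
    return out


def jaccard_overlap(
    markers_a: Mapping[object, set],
    markers_b: Mapping[object, set],
) -> pd.DataFrame:
    """Jaccard index J = \\|A∩B\\| / \\|A∪B\\| for every cluster pair.

    Long-format frame with the intersection size alongside; when both sets
    are empty J is defined as 0 and the pair flagged.
    """
    rows = []
    for ca, sa in markers_a.items():
        for cb, sb in markers_b.items():
            inter = len(sa & sb)
            union = len(sa | sb)
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "intersection": inter,
                    "union": union,
                    "jaccard": inter / union if union else 0.0,
                    "both_empty": union == 0,
                }
            )
    return pd.DataFrame(rows)


def time_composition(
    clusters: ClusterAssignment | pd.Series,
    timepoints: pd.Series,
    mixed_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-cluster ED/EN cell fractions.

    A cluster is "mixed" when its minority time point holds at least
    ``mixed_threshold`` of its cells.  Raises if any clustered cell lacks
    a time point, naming the cell.
    """
    labels = clusters.label_of_cell if isinstance(clusters, ClusterAssignment) else clusters
    tp = timepoints.reindex(labels.index)
    missing = tp.index[tp.isna()]
    if len(missing):
        raise ValueError(f"cell {missing[0]!r} has no timepoint")
    rows = []
    for cl in sorted(labels.unique()):
        sub = tp[labels == cl]
        n = len(sub)
        f_ed = float((sub == "ED").mean())
        f_en = float((sub == "EN").mean())
        rows.append(
            {
                "cluster": cl,
                "n_cells": n,
                "frac_ED": f_ed,
                "frac_EN": f_en,
                "mixed": min(f_ed, f_en) >= mixed_threshold,
            }
        )
    return pd.DataFrame(rows)


def split_markers_by_time(
    adata: ad.AnnData,
    clusters: ClusterAssignment | pd.Series,
    timepoints: pd.Series | None = None,
    logfc_min: float = 0.25,
    min_pct: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Marker detection restricted to ED cells and to EN cells separately.

    Returns ``{"ED": table, "EN": table, "exclusive": frame}``.  The
    exclusive frame lists (gene, cluster) markers found at one time point
    only, with a ``global_de`` flag saying whether that gene is also
    differentially expressed between ED and EN over all cells at the same
    thresholds — time-point-exclusive markers need not be (and often are
    not) globally time-regulated.
    """
    labels = clusters.label_of_cell if isinstance(clusters, ClusterAssignment) else clusters
    if timepoints is None:
        timepoints = adata.obs["timepoint"]
    tables = {}
    for tp in ("ED", "EN"):
        mask = (timepoints.reindex(adata.obs_names) == tp).to_numpy()
        sub = adata[mask].copy()
        tables[tp] = find_markers(
            sub, labels.reindex(sub.obs_names), logfc_min=logfc_min, min_pct=min_pct, alpha=alpha
        )
    sets_ed = marker_sets(tables["ED"])
    sets_en = marker_sets(tables["EN"])

    # global ED-vs-EN differential expression at the same thresholds
    linear = _depth_normalized(adata)
    norm = np.log1p(linear)
    ed_mask = (timepoints.reindex(adata.obs_names) == "ED").to_numpy()
    mean_ed = linear[ed_mask].mean(axis=0)
    mean_en = linear[~ed_mask].mean(axis=0)
    g_logfc = np.abs(np.log(mean_ed + _EPS) - np.log(mean_en + _EPS))
    pct_ed = (linear[ed_mask] > 0).mean(axis=0)
    pct_en = (linear[~ed_mask] > 0).mean(axis=0)
    g_tested = ((pct_ed >= min_pct) | (pct_en >= min_pct)) & (g_logfc >= logfc_min)
    gidx = np.flatnonzero(g_tested)
    global_de: set = set()
    if gidx.size:
        gp = rank_sum_p(norm, ed_mask, gidx)
        gp_adj = np.minimum(1.0, gp * adata.n_vars)
        global_de = {adata.var_names[j] for j, padj in zip(gidx, gp_adj) if padj < alpha}

    rows = []
    for cl in sorted(set(sets_ed) | set(sets_en)):
        ed, en = sets_ed.get(cl, set()), sets_en.get(cl, set())
        for gene in sorted(ed - en):
            rows.append({"gene": gene, "cluster": cl, "exclusive_to": "ED", "global_de": gene in global_de})
        for gene in sorted(en - ed):
            rows.append({"gene": gene, "cluster": cl, "exclusive_to": "EN", "global_de": gene in global_de})
    exclusive = pd.DataFrame(rows, columns=["gene", "cluster", "exclusive_to", "global_de"])
    return {"ED": tables["ED"], "EN": tables["EN"], "exclusive": exclusive}


def read_category_map(path: str) -> dict[str, set[str]]:
    """Read a two-column (gene, category) TSV into category → gene sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"])
    return {cat: set(sub["gene"]) for cat, sub in df.groupby("category")}


def hypergeom_enrichment(
    marker_sets_by_cluster: Mapping[object, set],
    category_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    *,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of categories in marker sets.

    With N genes in the universe, K in the category, n markers and k in
    the overlap, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n).
    Significance is called at unadjusted p < ``alpha``; pass
    ``adjust="bh"`` for Benjamini–Hochberg across each cluster's
    categories.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    N = len(universe)
    rows = []
    for cl, markers in marker_sets_by_cluster.items():
        markers = set(markers)
        if not markers <= universe:
            raise ValueError(f"marker set of cluster {cl!r} not contained in universe")
        n = len(markers)
        for cat, genes in category_map.items():
            genes = set(genes)
            if not genes <= universe:
                raise ValueError(f"category {cat!r} not contained in universe")
            K = len(genes)
            k = len(markers & genes)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rows.append({"cluster": cl, "category": cat, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["cluster", "category", "k", "K", "n", "N", "p"])
    if adjust == "bh" and len(df):
        df["p_adj"] = df.groupby("cluster")["p"].transform(
            lambda s: stats.false_discovery_control(s, method="bh")
        )
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df
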