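"""Cell clustering and robustness scoring by read subsampling.

Clustering wraps the standard droplet workflow (depth normalization, log
transform, highly-variable-gene selection, PCA, kNN graph, Leiden) behind a
deterministic, seedable interface; any backend honouring the same contract
can replace it.  Robustness is scored by repeatedly thinning the counts to
a fraction of the original depth, reclustering with the *original* variable
genes, and asking what proportion of each original cluster's cells still
co-occur in a single cluster of the replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "RobustnessReport",
    "cluster_cells",
    "subsample_counts",
    "robustness_score",
    "star_rating",
]


@dataclass
class ClusterParams:
    """Settings for the wrapped clustering backend."""

    n_top_genes: int = 200
    n_pcs: int = 10
    n_neighbors: int = 15
    resolution: float = 0.3
    target_sum: float = 1e4


@dataclass
class ClusterAssignment:
    """One clustering run: labels, the variable genes used, and settings."""

    label_of_cell: pd.Series  # index: cell, value: cluster id (str)
    variable_genes: list[str]
    params: ClusterParams
    seed: int

    @property
    def clusters(self) -> list[str]:
        return sorted(self.label_of_cell.unique())

    def members(self, cluster: str) -> pd.Index:
        return self.label_of_cell.index[self.label_of_cell == cluster]


@dataclass
class RobustnessReport:
    """Per-cluster co-occurrence scores (0–100) and their star ratings."""

    score_of_cluster: dict[str, float]
    stars_of_cluster: dict[str, str]
    n_replicates: int
    fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": list(self.score_of_cluster),
                "score": list(self.score_of_cluster.values()),
                "stars": [self.stars_of_cluster[c] for c in self.score_of_cluster],
            }
        )


def cluster_cells(
    adata: ad.AnnData,
    params: ClusterParams | None = None,
    batch_correct: Callable[[ad.AnnData], None] | None = None,
    seed: int = 0,
    *,
    variable_genes: list[str] | None = None,
) -> ClusterAssignment:
    """Cluster a filtered count matrix; deterministic for a given seed.

    ``batch_correct`` is an in-place hook applied after PCA (it may adjust
    ``.obsm["X_pca"]`` using ``.obs``, e.g. to remove a harvest-time batch
    effect); the default is the identity, which realizes the
    without-batch-normalization variant.  ``variable_genes`` overrides HVG
    selection — the robustness scorer uses this to re-use the original
    gene list on thinned counts.
    """
    params = params or ClusterParams()
    if adata.n_obs == 0:
        raise ValueError("cannot cluster an empty matrix")
    if adata.n_obs <= params.n_neighbors:
        raise ValueError(
            f"{adata.n_obs} cells but {params.n_neighbors} neighbors requested"
        )
    work = adata.copy()
    sc.pp.normalize_total(work, target_sum=params.target_sum)
    sc.pp.log1p(work)
    if variable_genes is None:
        n_top = min(params.n_top_genes, work.n_vars)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(work, n_top_genes=n_top, flavor="seurat")
        variable_genes = list(work.var_names[work.var["highly_variable"]])
    work = work[:, [g for g in variable_genes if g in work.var_names]].copy()
    if sparse.issparse(work.X):
        work.X = np.asarray(work.X.todense())  # scaling densifies anyway
    sc.pp.scale(work, max_value=10)
    n_pcs = min(params.n_pcs, work.n_vars - 1, work.n_obs - 1)
    sc.pp.pca(work, n_comps=n_pcs, svd_solver="arpack", random_state=seed)
    if batch_correct is not None:
        batch_correct(work)
    sc.pp.neighbors(work, n_neighbors=params.n_neighbors, n_pcs=n_pcs, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(
            work,
            resolution=params.resolution,
            random_state=seed,
            flavor="leidenalg",
        )
    labels = work.obs["leiden"].astype(str)
    labels.index = adata.obs_names
    return ClusterAssignment(
        label_of_cell=labels,
        variable_genes=list(variable_genes),
        params=params,
        seed=seed,
    )


def subsample_counts(adata: ad.AnnData, fraction: float, seed: int = 0) -> ad.AnnData:
    """Binomially thin every count to ``fraction`` of the original depth.

    Each count c is replaced by a Binomial(c, fraction) draw, the
    matrix-level surrogate for subsampling a fraction of the library
    reads: every molecule keeps inclusion probability ``fraction``.
    Cell and gene sets are unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = adata.copy()
    if fraction == 1.0:
        return out
    if sparse.issparse(out.X):
        X = out.X.tocsr(copy=True)
        X.data = rng.binomial(X.data.astype(np.int64), fraction)
        X.eliminate_zeros()
        out.X = X
    else:
        out.X = rng.binomial(out.X.astype(np.int64), fraction)
    return out


def star_rating(score: float) -> str:
    """Map a 0–100 co-occurrence score to its star bin.

    Bins are closed on the left: [75, 100] → ***, [50, 75) → **,
    [25, 50) → *, below 25 → no stars.
    """
    if score >= 75:
        return "***"
    if score >= 50:
        return "**"
    if score >= 25:
        return "*"
    return ""


def robustness_score(
    original: ClusterAssignment,
    adata: ad.AnnData,
    n_replicates: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    *,
    recluster: Callable[[ad.AnnData, int], pd.Series] | None = None,
) -> RobustnessReport:
    """Score each original cluster's stability under count thinning.

    For each replicate the counts are binomially thinned to ``fraction``
    and reclustered with the original variable genes and settings.  The
    co-occurrence of an original cluster C in a replicate is
    max over replicate clusters C' of \\|C ∩ C'\\| / \\|C\\| — the share of
    C's cells that still sit together in one cluster — and the score is
    100 × the mean over replicates.  ``recluster(thinned, seed) -> labels``
    swaps in an alternative backend.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if recluster is None:

        def recluster(thinned: ad.AnnData, rep_seed: int) -> pd.Series:
            return cluster_cells(
                thinned,
                params=original.params,
                seed=rep_seed,
                variable_genes=original.variable_genes,
            ).label_of_cell

    cells = original.label_of_cell.index
    clusters = original.clusters
    members = {c: set(original.members(c)) for c in clusters}
    sums = {c: 0.0 for c in clusters}
    ss = np.random.SeedSequence([seed, 3])
    rep_seeds = ss.generate_state(n_replicates) % (2**31)
    for r in range(n_replicates):
        thinned = subsample_counts(adata, fraction, seed=int(rep_seeds[r]))
        labels = recluster(thinned, int(rep_seeds[r]))
        labels = labels.reindex(cells)
        rep_members: dict[str, set] = {}
        for cell, lab in labels.items():
            rep_members.setdefault(lab, set()).add(cell)
        for c in clusters:
            best = max((len(members[c] & m) for m in rep_members.values()), default=0)
            sums[c] += best / len(members[c])
    scores = {c: 100.0 * sums[c] / n_replicates for c in clusters}
    stars = {c: star_rating(s) for c, s in scores.items()}
    return RobustnessReport(
        score_of_cluster=scores,
        stars_of_cluster=stars,
        n_replicates=n_replicates,
        fraction=fraction,
    )
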