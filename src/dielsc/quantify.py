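"""UMI collapsing and cell filtering.

A molecule is a distinct (cell barcode, UMI) pair; a gene's count in a cell
is the number of such molecules whose reads were assigned to the gene.  A
read is assigned to a gene when any aligned block overlaps the gene's
interval by at least 1 bp (strand-matched when counting strand-specifically,
the default).  Reads whose blocks overlap two or more genes are treated as
read-through evidence, not expression, and are excluded from per-gene
counts — the di-cistronic caller consumes them instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .annotation import AnnotationSet
from .reads import TaggedRead

__all__ = ["FilterConfig", "QCReport", "collapse_umis", "filter_cells", "cell_qc_table"]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Cell-retention thresholds.

    Defaults follow the root-library cutoffs: at least 500 transcripts and
    200 detected genes per cell.  The plastid filter removes stressed or
    broken protoplasts dominated by plastidial transcripts; 0.2 is this
    package's default since no published value accompanies the rule.
    """

    min_transcripts: int = 500
    min_genes: int = 200
    max_plastid_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.min_transcripts < 0 or self.min_genes < 0 or self.max_plastid_fraction < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QCReport:
    """Read-assignment bookkeeping from :func:`collapse_umis`."""

    n_reads: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0  # reads overlapping >= 2 genes
    n_unassigned: int = 0  # reads overlapping no gene
    n_unknown_chrom: int = 0


def collapse_umis(
    reads: Iterable[TaggedRead],
    annot: AnnotationSet,
    strand_specific: bool = True,
) -> ad.AnnData:
    """Collapse tagged reads into a cells × genes UMI count matrix.

    Counts the distinct (cell, UMI) pairs per gene.  Reads on unknown
    chromosomes are logged and skipped; assignment statistics are stored in
    ``.uns["qc_report"]``.  The gene axis always covers the full annotation;
    the cell axis covers every barcode seen.
    """
    if len(annot) == 0:
        raise ValueError("annotation is empty")
    qc = QCReport()
    molecules: set[tuple[str, str, str]] = set()  # (cell, umi, gene)
    for r in reads:
        qc.n_reads += 1
        if not annot.has_chrom(r.chrom):
            qc.n_unknown_chrom += 1
            logger.warning("read on unknown chromosome %r skipped", r.chrom)
            continue
        strand = r.strand if strand_specific else None
        hit_ids: set[str] = set()
        for s, e in r.blocks:
            hit_ids.update(g.id for g in annot.overlapping(r.chrom, s, e, strand))
        if len(hit_ids) == 1:
            qc.n_assigned += 1
            molecules.add((r.cell, r.umi, next(iter(hit_ids))))
        elif len(hit_ids) >= 2:
            qc.n_ambiguous += 1
        else:
            qc.n_unassigned += 1

    cells = sorted({c for c, _, _ in molecules})
    gene_ids = annot.gene_ids
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    cell_pos = {c: i for i, c in enumerate(cells)}
    X = sparse.lil_matrix((len(cells), len(gene_ids)), dtype=np.int64)
    for cell, _, gene in molecules:
        X[cell_pos[cell], gene_pos[gene]] += 1
    adata = ad.AnnData(
        X=X.tocsr(),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(
            {
                "biotype": [annot[g].biotype for g in gene_ids],
                "plastid": [annot[g].plastid for g in gene_ids],
            },
            index=pd.Index(gene_ids, name="gene"),
        ),
    )
    adata.uns["qc_report"] = vars(qc).copy()
    return adata


def cell_qc_table(adata: ad.AnnData, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-cell totals, detected genes, plastid fraction and pass/fail flags."""
    cfg = cfg or FilterConfig()
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    if "plastid" in adata.var:
        pl = adata.var["plastid"].to_numpy(dtype=bool)
        plastid_counts = np.asarray(X[:, pl].sum(axis=1)).ravel() if pl.any() else np.zeros(adata.n_obs)
    else:
        plastid_counts = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        plastid_frac = np.where(totals > 0, plastid_counts / np.maximum(totals, 1), 0.0)
    qc = pd.DataFrame(
        {
            "total_transcripts": totals.astype(int),
            "n_genes": n_genes.astype(int),
            "plastid_fraction": plastid_frac,
        },
        index=adata.obs_names,
    )
    qc["pass_transcripts"] = qc["total_transcripts"] >= cfg.min_transcripts
    qc["pass_genes"] = qc["n_genes"] >= cfg.min_genes
    qc["pass_plastid"] = qc["plastid_fraction"] <= cfg.max_plastid_fraction
    qc["pass"] = qc[["pass_transcripts", "pass_genes", "pass_plastid"]].all(axis=1)
    return qc


def filter_cells(adata: ad.AnnData, cfg: FilterConfig | None = None) -> ad.AnnData:
    """Retain cells meeting all three QC thresholds.

    The full per-cell QC table (including the removed cells) is stored in
    ``.uns["cell_qc"]``.  Idempotent: filtering a filtered matrix changes
    nothing.
    """
    cfg = cfg or FilterConfig()
    if adata.n_obs == 0:
        warnings.warn("filter_cells called on an empty matrix")
        out = adata.copy()
        out.uns["cell_qc"] = cell_qc_table(adata, cfg)
        return out
    qc = cell_qc_table(adata, cfg)
    out = adata[qc["pass"].to_numpy()].copy()
    out.uns["cell_qc"] = qc
    return out
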