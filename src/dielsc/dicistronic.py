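"""Di-cistronic transcript calling and mRNA–tRNA (TLS) classification.

A read supports an ordered gene pair when its aligned blocks overlap both
genes (any overlap, strand-agnostic at the read level).  A pair encodes a
di-cistronic transcript when it is supported by at least 100 reads and
either both genes are protein-coding on the same strand or at least one
gene is non-coding (tRNA counts as non-coding here).

For a host gene with a tRNA locus downstream on the same strand
(the choline-kinase case), molecules — (cell, UMI) read groups — are
classified as read-through (``tls``) when at least one read overlaps the
tRNA region and as ``mono`` otherwise; because a molecule only counts as
``tls`` when a junction-covering read was actually observed, the estimated
read-through ratio systematically underestimates the true one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .annotation import AnnotationSet, GeneModel
from .cluster import ClusterAssignment
from .markers import rank_sum_p, _normalized
from .reads import TaggedRead

__all__ = [
    "DicistronicCall",
    "MoleculeClass",
    "detect_dicistronic_pairs",
    "classify_molecules",
    "tls_cluster_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DicistronicCall:
    """One candidate gene pair (ordered by coordinate) with its verdict."""

    geneA: str
    geneB: str
    support: int
    strandA: str
    strandB: str
    biotypeA: str
    biotypeB: str
    passed: bool
    fail_reason: str | None  # "low_support" | "strand_biotype_rule" | None


@dataclass(frozen=True)
class MoleculeClass:
    """Classification of one host-gene molecule."""

    molecule: tuple[str, str]  # (cell, umi)
    gene: str
    label: str  # "mono" | "tls"
    n_reads: int
    tRNA_overlap_reads: int
    flagged: bool = False  # mono molecule reading past the tRNA without touching it


def _pair_rule(a: GeneModel, b: GeneModel) -> bool:
    """Retained iff both protein-coding on the same strand, or ≥1 non-coding."""
    both_coding = a.biotype == "protein_coding" and b.biotype == "protein_coding"
    if both_coding:
        return a.strand == b.strand
    return True


def detect_dicistronic_pairs(
    reads: Iterable[TaggedRead],
    annot: AnnotationSet,
    min_support: int = 100,
) -> list[DicistronicCall]:
    """Call di-cistronic gene pairs from read–annotation overlap.

    Every read overlapping two or more genes contributes one unit of
    support to each pair of genes it overlaps (a ≥3-gene read feeds all
    its pairs and is logged).  Candidates with support ≥ ``min_support``
    are then filtered by the strand/biotype rule; all candidates are
    returned with verdicts, sorted by coordinate.
    """
    support: dict[tuple[str, str], int] = {}
    for r in reads:
        if not annot.has_chrom(r.chrom):
            continue
        hits: dict[str, GeneModel] = {}
        for s, e in r.blocks:
            for g in annot.overlapping(r.chrom, s, e):
                hits[g.id] = g
        if len(hits) < 2:
            continue
        genes = sorted(hits.values(), key=lambda g: (g.start, g.id))
        if len(genes) > 2:
            logger.info(
                "read %s/%s overlaps %d genes; counted toward every pair",
                r.cell, r.umi, len(genes),
            )
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                support[(genes[i].id, genes[j].id)] = support.get((genes[i].id, genes[j].id), 0) + 1

    calls = []
    for (a_id, b_id), n in sorted(support.items()):
        a, b = annot[a_id], annot[b_id]
        rule_ok = _pair_rule(a, b)
        if n < min_support:
            passed, reason = False, "low_support"
        elif not rule_ok:
            passed, reason = False, "strand_biotype_rule"
        else:
            passed, reason = True, None
        calls.append(
            DicistronicCall(
                geneA=a_id, geneB=b_id, support=n,
                strandA=a.strand, strandB=b.strand,
                biotypeA=a.biotype, biotypeB=b.biotype,
                passed=passed, fail_reason=reason,
            )
        )
    calls.sort(key=lambda c: (annot[c.geneA].chrom, annot[c.geneA].start, c.geneA, c.geneB))
    return calls


def calls_to_frame(calls: list[DicistronicCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def classify_molecules(
    reads: Iterable[TaggedRead],
    host_gene: str,
    trna_gene: str,
    annot: AnnotationSet,
) -> list[MoleculeClass]:
    """Classify host-gene molecules as mono- or read-through (tls).

    Reads are grouped into molecules by (cell, UMI).  A molecule is
    ``tls`` when at least one of its read blocks overlaps the tRNA
    interval, ``mono`` when none does; molecules with no read overlapping
    the host gene are excluded.  A mono molecule whose reads extend past
    the base immediately preceding the tRNA start (strand-aware) without
    touching the tRNA is kept as mono but flagged.
    """
    host = annot[host_gene]
    trna = annot[trna_gene]
    if host.strand != trna.strand:
        raise ValueError("host and tRNA genes must share a strand")
    if host.strand == "+" and trna.start < host.start:
        raise ValueError("tRNA must lie downstream of the host gene")
    if host.strand == "-" and trna.end > host.end:
        raise ValueError("tRNA must lie downstream of the host gene")

    by_mol: dict[tuple[str, str], list[TaggedRead]] = {}
    for r in reads:
        if r.chrom != host.chrom:
            continue
        by_mol.setdefault((r.cell, r.umi), []).append(r)

    out = []
    for mol, rs in sorted(by_mol.items()):
        host_hit = any(host.overlaps(s, e) for r in rs for s, e in r.blocks)
        if not host_hit:
            continue
        trna_hits = sum(
            1 for r in rs if any(trna.overlaps(s, e) for s, e in r.blocks)
        )
        if trna_hits >= 1:
            label, flagged = "tls", False
        else:
            if host.strand == "+":
                past = any(e > trna.start for r in rs for _, e in r.blocks)
            else:
                past = any(s < trna.end for r in rs for s, _ in r.blocks)
            label, flagged = "mono", past
        out.append(
            MoleculeClass(
                molecule=mol,
                gene=host_gene,
                label=label,
                n_reads=sum(1 for _ in rs),
                tRNA_overlap_reads=trna_hits,
                flagged=flagged,
            )
        )
    return out


def tls_cluster_enrichment(
    classes: list[MoleculeClass],
    clusters: ClusterAssignment | pd.Series,
    adata: ad.AnnData,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster read-through ratio and the marker-based enrichment call.

    Builds two per-cell pseudo-gene vectors (tls molecules, mono
    molecules) over the cells of ``adata``.  For each cluster, the ratio
    tls / (tls + mono) is computed over host-expressing cells (cells with
    at least one classified molecule); a cluster is enriched when the tls
    pseudo-gene is a marker for it (two-tailed Wilcoxon rank-sum on
    normalized pseudo-counts, unadjusted p < ``alpha``, higher inside the
    cluster) and the mono pseudo-gene is not.  Clusters with no
    host-expressing cells get a missing ratio.
    """
    labels = clusters.label_of_cell if isinstance(clusters, ClusterAssignment) else clusters
    labels = labels.reindex(adata.obs_names)
    cell_pos = {c: i for i, c in enumerate(adata.obs_names)}
    tls_counts = np.zeros(adata.n_obs)
    mono_counts = np.zeros(adata.n_obs)
    for mc in classes:
        i = cell_pos.get(mc.molecule[0])
        if i is None:
            continue
        if mc.label == "tls":
            tls_counts[i] += 1
        else:
            mono_counts[i] += 1

    # normalize the pseudo-genes by each cell's library depth, like any gene
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0
    pseudo = np.log1p(np.column_stack([tls_counts, mono_counts]) / totals[:, None] * 1e4)

    expressing = (tls_counts + mono_counts) > 0
    rows = []
    for cl in sorted(labels.dropna().unique()):
        in_mask = (labels == cl).to_numpy()
        expr = in_mask & expressing
        n_tls = tls_counts[expr].sum()
        n_mono = mono_counts[expr].sum()
        if n_tls + n_mono == 0:
            rows.append(
                {"cluster": cl, "n_expressing": 0, "tls": 0, "mono": 0,
                 "tls_ratio": np.nan, "p_tls": np.nan, "p_mono": np.nan, "enriched": False}
            )
            continue
        p_tls, p_mono = rank_sum_p(pseudo, in_mask, np.array([0, 1]))
        mean_in = pseudo[in_mask].mean(axis=0)
        mean_out = pseudo[~in_mask].mean(axis=0)
        tls_marker = p_tls < alpha and mean_in[0] > mean_out[0]
        mono_marker = p_mono < alpha and mean_in[1] > mean_out[1]
        rows.append(
            {
                "cluster": cl,
                "n_expressing": int(expr.sum()),
                "tls": int(n_tls),
                "mono": int(n_mono),
                "tls_ratio": n_tls / (n_tls + n_mono),
                "p_tls": p_tls,
                "p_mono": p_mono,
                "enriched": bool(tls_marker and not mono_marker),
            }
        )
    return pd.DataFrame(rows)
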