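"""Synthetic data with planted ground truth.

Three generators mirror the three kinds of input the pipeline consumes:

* :func:`generate_annotation` — flat gene models laid out on one chromosome,
  including adjacent gene pairs (read-through candidates) and, optionally, a
  protein-coding host gene with a tRNA locus a short gap downstream on the
  same strand (the choline-kinase/tRNA-Gly configuration).
* :func:`generate_reads` — tagged alignments (cell barcode, UMI, strand,
  aligned blocks) with planted di-cistronic junction reads at exact support
  levels and host-gene read-through molecules at per-cluster rates.
* :func:`generate_count_matrix` — negative-binomial UMI counts with planted
  cluster markers, plastid-inflated cells, forced low-depth cells and an
  end-of-day / end-of-night batch shift.

Everything planted is recorded in :class:`SimTruth` so downstream stages can
be tested for parameter recovery, and every generator is deterministic for a
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .annotation import AnnotationSet, GeneModel
from .reads import TaggedRead

__all__ = [
    "SimTruth",
    "ReadSet",
    "make_truth",
    "generate_annotation",
    "generate_reads",
    "generate_count_matrix",
]

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth shared by the read and count generators.

    Cells are identified by their barcode strings.  ``dicistronic_pairs``
    holds (upstream gene, downstream gene, planted read support) triples;
    ``tls_fraction_of_cluster`` gives the per-cluster probability that a
    host-gene molecule reads through into the downstream tRNA.
    """

    cluster_of_cell: Mapping[str, int]
    marker_genes_of_cluster: Mapping[int, frozenset[str]]
    dicistronic_pairs: tuple[tuple[str, str, int], ...]
    tls_fraction_of_cluster: Mapping[int, float]
    batch_of_cell: Mapping[str, str]
    low_depth_cells: frozenset[str]
    seed: int
    high_plastid_cells: frozenset[str] = frozenset()
    plastid_genes: frozenset[str] = frozenset()
    batch_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.cluster_of_cell) != set(self.batch_of_cell):
            raise ValueError("every cell needs exactly one cluster and one batch")
        for c, f in self.tls_fraction_of_cluster.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"tls fraction for cluster {c} outside [0, 1]")
        for a, b, s in self.dicistronic_pairs:
            if s < 0:
                raise ValueError(f"planted support for ({a}, {b}) is negative")
        if not self.low_depth_cells <= set(self.cluster_of_cell):
            raise ValueError("low_depth_cells must be a subset of the cells")

    @property
    def cells(self) -> list[str]:
        return sorted(self.cluster_of_cell)


class ReadSet(list):
    """A list of :class:`TaggedRead` that also records per-cell molecule counts.

    ``molecules_per_cell`` maps each barcode to the number of distinct
    (cell, UMI) molecules generated for it, before any low-depth scaling —
    the conservation reference for the generator's output.
    """

    def __init__(self, reads, molecules_per_cell: dict[str, int]):
        super().__init__(reads)
        self.molecules_per_cell = molecules_per_cell


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(_NT[rng.integers(0, 4, size=length)])
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def make_truth(
    n_cells: int = 200,
    n_clusters: int = 2,
    markers_per_cluster: int = 20,
    n_genes: int = 500,
    seed: int = 0,
    *,
    n_low_depth: int = 0,
    n_high_plastid: int = 0,
    tls_fractions: Mapping[int, float] | None = None,
    dicistronic_pairs: Sequence[tuple[str, str, int]] = (),
    batch: str = "balanced",
    n_batch_genes: int = 0,
    n_plastid_genes: int = 0,
    barcode_length: int = 12,
) -> SimTruth:
    """Build a consistent :class:`SimTruth` for the generators.

    Cells get random collision-free barcodes and are dealt round-robin to
    clusters.  Marker genes are taken from the front of the gene list
    (``G0000`` upward), batch-shift and plastid genes from the back, so the
    blocks never collide.  ``batch`` is ``"balanced"`` (ED/EN alternating
    within each cluster), ``"by_cluster"`` (cluster parity decides the time
    point) or ``"all_ED"``.
    """
    if markers_per_cluster * n_clusters + n_batch_genes + n_plastid_genes > n_genes:
        raise ValueError("gene blocks exceed n_genes")
    rng = np.random.default_rng(seed)
    cells = _random_barcodes(rng, n_cells, barcode_length)
    cluster_of_cell = {c: i % n_clusters for i, c in enumerate(cells)}
    if batch == "balanced":
        batch_of_cell = {c: ("ED", "EN")[(i // n_clusters) % 2] for i, c in enumerate(cells)}
    elif batch == "by_cluster":
        batch_of_cell = {c: ("ED", "EN")[cluster_of_cell[c] % 2] for c in cells}
    elif batch == "all_ED":
        batch_of_cell = {c: "ED" for c in cells}
    else:
        raise ValueError(f"unknown batch design {batch!r}")
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    markers = {
        k: frozenset(gene_ids[k * markers_per_cluster : (k + 1) * markers_per_cluster])
        for k in range(n_clusters)
    }
    plastid_genes = frozenset(gene_ids[n_genes - n_plastid_genes :]) if n_plastid_genes else frozenset()
    batch_genes = (
        frozenset(gene_ids[n_genes - n_plastid_genes - n_batch_genes : n_genes - n_plastid_genes])
        if n_batch_genes
        else frozenset()
    )
    low_depth = frozenset(cells[n_cells - n_low_depth :]) if n_low_depth else frozenset()
    high_plastid = (
        frozenset(cells[n_cells - n_low_depth - n_high_plastid : n_cells - n_low_depth])
        if n_high_plastid
        else frozenset()
    )
    return SimTruth(
        cluster_of_cell=cluster_of_cell,
        marker_genes_of_cluster=markers,
        dicistronic_pairs=tuple(dicistronic_pairs),
        tls_fraction_of_cluster=dict(tls_fractions or {}),
        batch_of_cell=batch_of_cell,
        low_depth_cells=low_depth,
        seed=seed,
        high_plastid_cells=high_plastid,
        plastid_genes=plastid_genes,
        batch_genes=batch_genes,
    )


# ------------------------------------------------------------- annotation

def generate_annotation(
    n_gene_pairs: int,
    n_singletons: int,
    tls_host: bool = False,
    seed: int = 0,
    *,
    chrom: str = "1",
    gene_length: tuple[int, int] = (800, 1500),
    pair_gap: tuple[int, int] = (5, 60),
    feature_gap: int = 500,
    pair_strands: Sequence[tuple[str, str]] | tuple[str, str] = ("+", "+"),
    pair_biotypes: Sequence[tuple[str, str]] | tuple[str, str] = ("protein_coding", "protein_coding"),
    tls_gap: int = 20,
    trna_length: int = 72,
    tls_strand: str = "+",
    n_plastid_singletons: int = 0,
) -> AnnotationSet:
    """Lay out synthetic gene models along one chromosome.

    Pairs ``PAIR<i>_A`` / ``PAIR<i>_B`` sit a small ``pair_gap`` apart
    (read-through candidates); singletons ``SGL<j>`` are isolated by the
    much larger ``feature_gap``.  With ``tls_host``, a host gene ``HOST``
    gets a tRNA gene ``TRNA`` starting ``tls_gap`` bp downstream on the
    same strand.  Deterministic for a given seed.
    """
    if n_gene_pairs < 0 or n_singletons < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pos = feature_gap

    def glen() -> int:
        return int(rng.integers(gene_length[0], gene_length[1] + 1))

    strands = list(pair_strands) if pair_strands and isinstance(pair_strands[0], (tuple, list)) else [tuple(pair_strands)] * n_gene_pairs
    biotypes = list(pair_biotypes) if pair_biotypes and isinstance(pair_biotypes[0], (tuple, list)) else [tuple(pair_biotypes)] * n_gene_pairs
    for i in range(n_gene_pairs):
        sA, sB = strands[i % len(strands)] if strands else ("+", "+")
        bA, bB = biotypes[i % len(biotypes)] if biotypes else ("protein_coding", "protein_coding")
        lA, lB = glen(), glen()
        gap = int(rng.integers(pair_gap[0], pair_gap[1] + 1))
        genes.append(GeneModel(f"PAIR{i}_A", chrom, sA, pos, pos + lA, biotype=bA))
        genes.append(GeneModel(f"PAIR{i}_B", chrom, sB, pos + lA + gap, pos + lA + gap + lB, biotype=bB))
        pos += lA + gap + lB + feature_gap
    for j in range(n_singletons):
        L = glen()
        genes.append(
            GeneModel(f"SGL{j}", chrom, "+" if rng.random() < 0.5 else "-", pos, pos + L,
                      plastid=j < n_plastid_singletons)
        )
        pos += L + feature_gap
    if tls_host:
        L = glen()
        if tls_strand == "+":
            genes.append(GeneModel("HOST", chrom, "+", pos, pos + L))
            genes.append(GeneModel("TRNA", chrom, "+", pos + L + tls_gap, pos + L + tls_gap + trna_length, biotype="tRNA"))
            pos += L + tls_gap + trna_length + feature_gap
        else:
            genes.append(GeneModel("TRNA", chrom, "-", pos, pos + trna_length, biotype="tRNA"))
            genes.append(GeneModel("HOST", chrom, "-", pos + trna_length + tls_gap, pos + trna_length + tls_gap + L))
            pos += L + tls_gap + trna_length + feature_gap
    return AnnotationSet(genes)


# ------------------------------------------------------------------ reads

class ConsistencyError(ValueError):
    """Planted truth refers to features absent from the annotation."""


def generate_reads(
    annot: AnnotationSet,
    truth: SimTruth,
    depth_per_cell: int,
    *,
    read_length: int = 60,
    reads_per_molecule: tuple[int, int] = (2, 5),
    umi_length: int = 8,
    host_gene: str = "HOST",
    trna_gene: str = "TRNA",
    host_molecules_per_cell: int = 0,
) -> ReadSet:
    """Generate tagged reads for every cell in ``truth``.

    Each cell receives ``depth_per_cell`` background molecules drawn from
    the non-tRNA genes (plus ``host_molecules_per_cell`` forced host-gene
    molecules when a TLS host is present).  A host-gene molecule in cluster
    ``k`` reads through into the tRNA with probability
    ``truth.tls_fraction_of_cluster[k]``: read-through molecules get one
    read guaranteed to overlap the tRNA region and their remaining reads
    anywhere on the host-to-tRNA span.  Mono molecules never extend past
    the base before the tRNA start.  Each planted di-cistronic pair
    contributes exactly its planted support in junction-spanning reads.
    Deterministic for ``truth.seed``.
    """
    if depth_per_cell < 0:
        raise ValueError("depth_per_cell must be non-negative")
    for a, b, _ in truth.dicistronic_pairs:
        if a not in annot or b not in annot:
            raise ConsistencyError(f"planted pair ({a}, {b}) absent from annotation")
    has_tls = truth.tls_fraction_of_cluster and host_gene in annot
    if has_tls and trna_gene not in annot:
        raise ConsistencyError(f"tRNA gene {trna_gene} absent from annotation")

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 1]))
    pool = [g for g in annot if g.biotype != "tRNA"]
    if not pool and depth_per_cell > 0:
        raise ConsistencyError("annotation has no non-tRNA genes to draw reads from")
    host = annot[host_gene] if has_tls else None
    trna = annot[trna_gene] if has_tls else None

    reads: list[TaggedRead] = []
    molecules: dict[str, int] = {}
    umis_used: dict[str, set[str]] = {}

    def fresh_umi(cell: str) -> str:
        used = umis_used.setdefault(cell, set())
        while True:
            u = "".join(_NT[rng.integers(0, 4, size=umi_length)])
            if u not in used:
                used.add(u)
                return u

    def contained_read(g: GeneModel, cell: str, umi: str) -> TaggedRead:
        lo, hi = g.start, max(g.start, g.end - read_length)
        s = int(rng.integers(lo, hi + 1))
        return TaggedRead(cell, umi, g.chrom, g.strand, ((s, min(g.end, s + read_length)),))

    cells = truth.cells
    for cell in cells:
        k = truth.cluster_of_cell[cell]
        tls_p = float(truth.tls_fraction_of_cluster.get(k, 0.0))
        n_host = host_molecules_per_cell if has_tls else 0
        molecules[cell] = depth_per_cell + n_host
        for m in range(depth_per_cell + n_host):
            umi = fresh_umi(cell)
            n_reads = int(rng.integers(reads_per_molecule[0], reads_per_molecule[1] + 1))
            if m < n_host:
                g = host
            else:
                g = pool[int(rng.integers(0, len(pool)))]
            if has_tls and g.id == host_gene:
                if rng.random() < tls_p:
                    reads.extend(_tls_molecule(rng, host, trna, cell, umi, n_reads, read_length))
                else:
                    reads.extend(_mono_molecule(rng, host, trna, cell, umi, n_reads, read_length))
            else:
                reads.extend(contained_read(g, cell, umi) for _ in range(n_reads))

    for a_id, b_id, support in truth.dicistronic_pairs:
        A, B = annot[a_id], annot[b_id]
        if A.start > B.start:
            A, B = B, A
        for _ in range(support):
            cell = cells[int(rng.integers(0, len(cells)))]
            molecules[cell] += 1
            o1 = int(rng.integers(1, min(read_length, len(A)) + 1))
            o2 = int(rng.integers(1, min(read_length, len(B)) + 1))
            reads.append(
                TaggedRead(cell, fresh_umi(cell), A.chrom, A.strand, ((A.end - o1, B.start + o2),))
            )
    return ReadSet(reads, molecules)


def _tls_span(host: GeneModel, trna: GeneModel) -> tuple[int, int]:
    return (host.start, trna.end) if host.strand == "+" else (trna.start, host.end)


def _tls_molecule(rng, host, trna, cell, umi, n_reads, rl) -> list[TaggedRead]:
    span_lo, span_hi = _tls_span(host, trna)
    out = []
    # one read guaranteed to overlap the tRNA region
    lo = max(span_lo, trna.start - rl + 1)
    hi = trna.end - 1
    s = int(rng.integers(lo, hi + 1))
    out.append(TaggedRead(cell, umi, host.chrom, host.strand, ((s, min(span_hi, s + rl)),)))
    for _ in range(n_reads - 1):
        s = int(rng.integers(span_lo, max(span_lo, span_hi - rl) + 1))
        out.append(TaggedRead(cell, umi, host.chrom, host.strand, ((s, min(span_hi, s + rl)),)))
    return out


def _mono_molecule(rng, host, trna, cell, umi, n_reads, rl) -> list[TaggedRead]:
    # reads stay on the host side, ending at or before the base preceding the tRNA
    out = []
    if host.strand == "+":
        lo, hi = host.start, max(host.start, trna.start - rl)
        for _ in range(n_reads):
            s = int(rng.integers(lo, hi + 1))
            out.append(TaggedRead(cell, umi, host.chrom, "+", ((s, min(trna.start, s + rl)),)))
    else:
        lo, hi = trna.end, max(trna.end, host.end - rl)
        for _ in range(n_reads):
            s = int(rng.integers(lo, hi + 1))
            out.append(TaggedRead(cell, umi, host.chrom, "-", ((s, min(host.end, s + rl)),)))
    return out


# ----------------------------------------------------------- count matrix

def generate_count_matrix(
    truth: SimTruth,
    n_genes: int,
    nb_dispersion: float = 0.3,
    marker_logfc: float = 1.0,
    batch_shift: float = 0.0,
    *,
    mean_depth: int = 2000,
    depth_sigma: float = 0.25,
    logmean_sigma: float = 1.0,
    plastid_boost: float = 50.0,
    low_depth_range: tuple[int, int] = (100, 400),
    n_replicates: int = 1,
    seed: int | None = None,
) -> ad.AnnData:
    """Simulate a cells × genes UMI count matrix around the planted truth.

    Counts are negative-binomial with log-normally distributed per-gene
    means scaled to an expected per-cell depth of ``mean_depth`` (the root
    libraries average roughly 2,000 transcripts per cell, which sets the
    default).  ``nb_dispersion`` is the NB dispersion α (var = μ + αμ²).
    Planted markers are raised by ``marker_logfc`` (natural-log scale) in
    their own cluster; plastid genes are boosted ``plastid_boost``-fold in
    the designated high-plastid cells; batch genes are shifted by
    ``batch_shift`` (log scale) in EN cells; low-depth cells are exactly
    downsampled to a total inside ``low_depth_range``.  Returns an AnnData
    with cell metadata (timepoint, replicate, true cluster) and gene
    metadata (biotype, plastid).
    """
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    gene_set = set(gene_ids)
    planted = set().union(*truth.marker_genes_of_cluster.values()) if truth.marker_genes_of_cluster else set()
    if not planted <= gene_set:
        raise ValueError("n_genes too small for the planted marker genes")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed, 2]) if seed is None else seed
    )
    cells = truth.cells
    n_cells = len(cells)

    mu_g = rng.lognormal(0.0, logmean_sigma, size=n_genes)
    mu_g *= mean_depth / mu_g.sum()
    if planted:
        # a marker is by construction a detectably expressed gene: floor the
        # baseline mean of planted markers at the average gene mean
        planted_idx = [gene_ids.index(g) for g in sorted(planted)]
        mu_g[planted_idx] = np.maximum(mu_g[planted_idx], mean_depth / n_genes)
    depth_factor = rng.lognormal(0.0, depth_sigma, size=n_cells)

    marker_mask = np.zeros((max(truth.marker_genes_of_cluster, default=-1) + 1, n_genes), dtype=bool)
    for k, gs in truth.marker_genes_of_cluster.items():
        marker_mask[k, [gene_ids.index(g) for g in sorted(gs)]] = True
    batch_idx = np.array([gene_ids.index(g) for g in sorted(truth.batch_genes)], dtype=int)
    plastid_idx = np.array([gene_ids.index(g) for g in sorted(truth.plastid_genes)], dtype=int)

    X = np.empty((n_cells, n_genes), dtype=np.int64)
    alpha = nb_dispersion
    for i, cell in enumerate(cells):
        mu = mu_g * depth_factor[i]
        k = truth.cluster_of_cell[cell]
        if k < marker_mask.shape[0] and marker_mask[k].any():
            mu = mu.copy()
            mu[marker_mask[k]] *= np.exp(marker_logfc)
        if batch_idx.size and truth.batch_of_cell[cell] == "EN" and batch_shift != 0.0:
            mu = mu.copy()
            mu[batch_idx] *= np.exp(batch_shift)
        if plastid_idx.size and cell in truth.high_plastid_cells:
            mu = mu.copy()
            mu[plastid_idx] *= plastid_boost
        r = 1.0 / alpha
        X[i] = rng.negative_binomial(r, r / (r + mu))

    for i, cell in enumerate(cells):
        if cell in truth.low_depth_cells:
            target = int(rng.integers(low_depth_range[0], low_depth_range[1] + 1))
            total = int(X[i].sum())
            if total > target:
                X[i] = rng.multivariate_hypergeometric(X[i], target)

    obs = pd.DataFrame(
        {
            "timepoint": [truth.batch_of_cell[c] for c in cells],
            "replicate": [f"r{(i % n_replicates) + 1}" for i in range(n_cells)],
            "true_cluster": [truth.cluster_of_cell[c] for c in cells],
        },
        index=pd.Index(cells, name="cell"),
    )
    var = pd.DataFrame(
        {
            "biotype": ["protein_coding"] * n_genes,
            "plastid": [g in truth.plastid_genes for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
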