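"""Shared fixtures: small synthetic datasets with planted truth."""

import numpy as np
import pytest

from dielsc import (
    cluster_cells,
    generate_annotation,
    generate_count_matrix,
    generate_reads,
    make_truth,
)


@pytest.fixture(scope="session")
def tls_annot():
    """Three adjacent gene pairs, ten singletons, and a host gene with a
    downstream tRNA locus."""
    return generate_annotation(3, 10, tls_host=True, seed=7)


@pytest.fixture(scope="session")
def tls_truth():
    return make_truth(
        n_cells=40,
        n_clusters=2,
        seed=7,
        dicistronic_pairs=[("PAIR0_A", "PAIR0_B", 120), ("PAIR1_A", "PAIR1_B", 99)],
        tls_fractions={0: 0.3, 1: 0.05},
    )


@pytest.fixture(scope="session")
def tls_reads(tls_annot, tls_truth):
    return generate_reads(tls_annot, tls_truth, depth_per_cell=30, host_molecules_per_cell=5)


@pytest.fixture(scope="session")
def two_cluster_adata():
    """Well-separated two-cluster count matrix with planted markers."""
    truth = make_truth(n_cells=200, n_clusters=2, markers_per_cluster=20, n_genes=300, seed=11)
    adata = generate_count_matrix(truth, 300, marker_logfc=1.5)
    adata.uns["truth"] = truth
    return adata


@pytest.fixture(scope="session")
def two_cluster_assignment(two_cluster_adata):
    return cluster_cells(two_cluster_adata, seed=0)


def brute_force_pair_support(reads, annot):
    """Independent double-loop recount of reads overlapping two genes."""
    support = {}
    genes = list(annot)
    for r in reads:
        hit = []
        for g in genes:
            if g.chrom != r.chrom:
                continue
            if any(g.start < e and s < g.end for s, e in r.blocks):
                hit.append(g)
        hit.sort(key=lambda g: (g.start, g.id))
        for i in range(len(hit)):
            for j in range(i + 1, len(hit)):
                key = (hit[i].id, hit[j].id)
                support[key] = support.get(key, 0) + 1
    return support


def brute_force_counts(reads, annot, strand_specific=True):
    """Independent recount over distinct (cell, umi, gene) triples."""
    triples = set()
    for r in reads:
        hit = []
        for g in annot:
            if g.chrom != r.chrom:
                continue
            if strand_specific and g.strand != r.strand:
                continue
            if any(g.start < e and s < g.end for s, e in r.blocks):
                hit.append(g.id)
        if len(set(hit)) == 1:
            triples.add((r.cell, r.umi, hit[0]))
    counts = {}
    for cell, _, gene in triples:
        counts[(cell, gene)] = counts.get((cell, gene), 0) + 1
    return counts
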