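"""On-disk exchange formats: MTX count matrices with sidecar TSVs."""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

__all__ = ["write_mtx_dir", "read_mtx_dir"]


def write_mtx_dir(adata: ad.AnnData, outdir: str) -> None:
    """Write counts as matrix.mtx plus genes.tsv, barcodes.tsv and cell_meta.tsv.

    The matrix is stored genes × cells (the droplet-pipeline convention).
    """
    os.makedirs(outdir, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    sio.mmwrite(os.path.join(outdir, "matrix.mtx"), X.T.astype(np.int64))
    adata.var.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", header=True)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False
    )
    adata.obs.to_csv(os.path.join(outdir, "cell_meta.tsv"), sep="\t", header=True)


def read_mtx_dir(indir: str) -> ad.AnnData:
    """Read a directory written by :func:`write_mtx_dir`."""
    X = sio.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    var = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", index_col=0)
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t")["barcode"]
    obs = pd.read_csv(os.path.join(indir, "cell_meta.tsv"), sep="\t", index_col=0)
    obs = obs.reindex(barcodes)
    obs.index.name = "cell"
    return ad.AnnData(X=X, obs=obs, var=var)
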