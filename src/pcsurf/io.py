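"""10x-style MTX triplet I/O and tabular outputs.

A dataset directory holds ``matrix.mtx`` (MatrixMarket coordinate
integer matrix, genes x cells, 1-based), ``features.tsv`` (gene id,
gene name) and ``barcodes.tsv`` (one barcode per line); cell metadata
(barcode, dataset, patient, stage) travels in a separate TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["read_mtx_triplet", "write_mtx_triplet"]


def write_mtx_triplet(adata: ad.AnnData, directory) -> Path:
    """Write an AnnData as an MTX triplet plus a cell-metadata TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x = adata.X
    x = x.tocsr() if sparse.issparse(x) else sparse.csr_matrix(np.asarray(x))
    mat = x.T.tocoo()  # genes x cells on disk, 10x convention
    mat = sparse.coo_matrix(
        (mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape
    )
    spio.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.DataFrame(
        {"gene_id": adata.var_names, "gene_name": adata.var_names}
    ).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.rename_axis("barcode").to_csv(directory / "metadata.tsv", sep="\t")
    return directory


def read_mtx_triplet(directory) -> ad.AnnData:
    """Read an MTX triplet directory back into an AnnData.

    Rejects non-integer or negative matrix entries and dimension
    mismatches between the matrix and the feature/barcode files.
    """
    directory = Path(directory)
    mat = spio.mmread(str(directory / "matrix.mtx"))
    data = np.asarray(mat.data if sparse.issparse(mat) else mat, dtype=float)
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise ValueError("matrix entries must be non-negative integers")

    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    n_genes, n_cells = mat.shape
    if len(features) != n_genes:
        raise ValueError(
            f"features file has {len(features)} rows but matrix declares {n_genes} genes"
        )
    if len(barcodes) != n_cells:
        raise ValueError(
            f"barcodes file has {len(barcodes)} rows but matrix declares {n_cells} cells"
        )

    x = sparse.csr_matrix(mat.T).astype(np.int32)
    obs = pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="barcode"))
    meta_path = directory / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs = obs.join(meta)
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene"))
    return ad.AnnData(X=x, obs=obs, var=var)
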