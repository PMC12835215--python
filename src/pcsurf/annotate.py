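"""Cell-type annotation by nearest-centroid cosine similarity.

Each QC-passing cell is log-normalised and compared, over the genes
shared with a reference-signature table, to per-type centroid profiles
(mean log-normalised expression).  The label is the highest-scoring type
when the cosine similarity clears ``min_score``, otherwise "Unassigned".
This is a defined, order-free classifier standing in for reference-
embedding projection, whose internals are out of scope here; any centroid
table with matching gene ids can be plugged in.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["log_normalize", "score_cell_types", "MIN_SHARED_GENES"]

MIN_SHARED_GENES = 50
PC_LABEL = "Plasma cell"
UNASSIGNED = "Unassigned"


def log_normalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Per-cell depth normalisation: value = ln(1 + scale * count / total).

    Zero-total cells map to all-zero rows.  Returns a new AnnData with the
    same obs/var; counts must be non-negative.
    """
    x = adata.X
    if sparse.issparse(x):
        x = x.tocsr().astype(float)
        if x.nnz and x.data.min() < 0:
            raise ValueError("counts must be non-negative")
        totals = np.asarray(x.sum(axis=1)).ravel()
        inv = np.divide(scale, totals, out=np.zeros_like(totals, dtype=float),
                        where=totals > 0)
        norm = x.multiply(inv[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        x = np.asarray(x, dtype=float)
        if x.size and x.min() < 0:
            raise ValueError("counts must be non-negative")
        totals = x.sum(axis=1)
        inv = np.divide(scale, totals, out=np.zeros_like(totals), where=totals > 0)
        norm = np.log1p(x * inv[:, None])
    out = ad.AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    return out


def score_cell_types(
    norm: ad.AnnData, ref: pd.DataFrame, min_score: float = 0.1
) -> pd.DataFrame:
    """Nearest-centroid annotation over the genes shared with ``ref``.

    ``ref``: rows genes, columns cell types (mean log-normalised
    expression).  Returns a DataFrame indexed by cell barcode with
    ``label`` (argmax type, ties broken by lexicographic type label, or
    "Unassigned" when the best cosine score is below ``min_score``),
    ``score`` (best cosine similarity) and ``margin`` (best minus
    second-best).  Zero-vector cells are Unassigned with score 0.
    """
    if ref.shape[1] < 2:
        raise ValueError("reference must contain at least two cell types")
    shared = norm.var_names.intersection(ref.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference "
            f"(need >= {MIN_SHARED_GENES})"
        )
    # Lexicographic column order makes argmax tie-breaking well defined.
    ref = ref[sorted(ref.columns)]
    centroids = ref.loc[shared].to_numpy(dtype=float)  # genes x types
    c_norm = np.linalg.norm(centroids, axis=0)
    if np.any(c_norm == 0):
        raise ValueError("reference contains an all-zero centroid")

    x = norm[:, shared].X
    x = x.tocsr() if sparse.issparse(x) else np.asarray(x, dtype=float)
    dots = np.asarray(x @ centroids)  # cells x types
    if sparse.issparse(x):
        cell_norm = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    else:
        cell_norm = np.linalg.norm(x, axis=1)
    denom = np.outer(cell_norm, c_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / np.maximum(denom, 1e-300), 0.0)

    best_idx = np.argmax(cos, axis=1)
    order = np.sort(cos, axis=1)
    best = order[:, -1]
    second = order[:, -2] if cos.shape[1] > 1 else np.zeros_like(best)
    labels = np.array(sorted(ref.columns), dtype=object)[best_idx]
    labels[(best < min_score) | (cell_norm == 0)] = UNASSIGNED
    return pd.DataFrame(
        {
            "label": labels,
            "score": np.where(cell_norm == 0, 0.0, best),
            "margin": np.maximum(best - second, 0.0),
        },
        index=norm.obs_names,
    )
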