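"""Consensus plasma-cell marker discovery across datasets.

Per dataset, every gene is scored with a Wilcoxon rank-sum test of its
log-normalised expression in plasma cells against all other annotated
cells (midranks, tie-corrected normal approximation), with BH adjustment
across genes within the dataset.  Per-dataset up-regulated gene lists
(adj p <= 0.05, logFC >= 0.5 by default) are then intersected across
datasets and restricted to genes annotated as surface / CD molecules in
the bundled surface table — the pipeline's core discovery computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as _ilres

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm as _norm

from .annotate import PC_LABEL
from .stats import bh_adjust, midrank_rows, wilcoxon_rank_sum  # noqa: F401 (re-export)

__all__ = [
    "SelectionParams",
    "load_surface_table",
    "rank_pc_markers",
    "select_dataset_markers",
    "intersect_marker_lists",
    "filter_surface_genes",
    "build_consensus_panel",
    "wilcoxon_rank_sum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Per-dataset marker selection: up-regulated, significant, intersected.

    ``min_datasets=None`` means strict intersection across all datasets.
    """

    adj_p_max: float = 0.05
    log_fc_min: float = 0.5
    min_datasets: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.adj_p_max) or not np.isfinite(self.log_fc_min):
            raise ValueError("thresholds must be finite")
        if self.min_datasets is not None and self.min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")


def load_surface_table(path=None) -> pd.DataFrame:
    """Surface/CD annotation table: gene -> (is_surface, cd_alias).

    The bundled default covers the plasma-cell surface panel, a broader
    CD-molecule list, and explicit non-surface exclusions.  Unknown genes
    are treated as non-surface by lookup helpers.
    """
    if path is None:
        with _ilres.files("pcsurf.resources").joinpath("surface_table.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    table["is_surface"] = table["is_surface"].map(
        {True: True, False: False, "True": True, "False": False}
    )
    if table["is_surface"].isna().any():
        raise ValueError("surface table has unparseable is_surface entries")
    return table.set_index("gene")


def _sparse_ranksum(xt: sparse.csr_matrix, is_pc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene rank sum of the PC group and tie term, zero-aware.

    ``xt`` is genes x cells CSR with strictly positive stored values
    (log-normalised expression); the implicit zeros of each gene share
    one tie group occupying the lowest ranks, so only stored values are
    sorted — one composite-key argsort over the nonzeros instead of a
    full dense ranking.
    """
    n_genes, n_cells = xt.shape
    data = xt.data
    cols = xt.indices
    m = np.diff(xt.indptr)  # stored values per gene
    row_id = np.repeat(np.arange(n_genes), m)

    # key = gene * offset + value sorts by (gene, value) in one pass;
    # offset is an integer above max(value) so equal values in a gene map
    # to exactly equal keys.
    offset = float(np.ceil(data.max() + 1.0)) if data.size else 1.0
    order = np.argsort(row_id * offset + data)
    row_sorted = row_id[order]
    data_sorted = data[order]

    new = np.ones(data_sorted.size, dtype=bool)
    if data_sorted.size > 1:
        new[1:] = (data_sorted[1:] != data_sorted[:-1]) | (
            row_sorted[1:] != row_sorted[:-1]
        )
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], data_sorted.size)
    sizes = (ends - starts).astype(float)
    g_of = row_sorted[starts]
    s_local = starts - xt.indptr[g_of]
    e_local = ends - xt.indptr[g_of]
    z0 = (n_cells - m).astype(float)  # zeros per gene
    group_rank = z0[g_of] + (s_local + e_local + 1) / 2.0

    gid = np.cumsum(new) - 1
    ranks_sorted = group_rank[gid]
    pc_sorted = is_pc[cols[order]].astype(float)
    w_nonzero = np.bincount(row_sorted, weights=ranks_sorted * pc_sorted,
                            minlength=n_genes)
    nnz_pc = np.bincount(row_id, weights=is_pc[cols].astype(float),
                         minlength=n_genes)
    zero_pc = float(is_pc.sum()) - nnz_pc
    w = w_nonzero + zero_pc * (z0 + 1.0) / 2.0
    tie = np.bincount(g_of, weights=sizes**3 - sizes, minlength=n_genes)
    tie += z0**3 - z0
    return w, tie


def rank_pc_markers(
    norm: ad.AnnData, annot: pd.DataFrame, pc_label: str = PC_LABEL
) -> pd.DataFrame:
    """Per-gene PC-vs-rest Wilcoxon statistics for one dataset.

    Cells labelled ``pc_label`` form group x; every other annotated cell
    (including "Unassigned") forms the rest.  Returns a gene-indexed frame
    with W, z, p_two_sided, adj_p (BH within dataset), log_fc (difference
    of group means of log-normalised values) and detection fractions.
    Needs >= 2 cells in each group.
    """
    labels = annot.loc[norm.obs_names, "label"].to_numpy()
    is_pc = labels == pc_label
    n_pc = int(is_pc.sum())
    n_rest = int((~is_pc).sum())
    ds = norm.obs["dataset"].iloc[0] if "dataset" in norm.obs else "?"
    if n_pc == 0:
        raise ValueError(f"no plasma cells annotated in dataset {ds}")
    if n_pc < 2 or n_rest < 2:
        raise ValueError(f"need >= 2 cells per group in dataset {ds}")
    n_total = n_pc + n_rest

    if sparse.issparse(norm.X):
        x = norm.X.tocsr()
        x.eliminate_zeros()
        w, tie_term = _sparse_ranksum(x.T.tocsr(), is_pc)
        pc_rows = x[is_pc]
        rest_rows = x[~is_pc]
        mean_pc = np.asarray(pc_rows.sum(axis=0)).ravel() / n_pc
        mean_rest = np.asarray(rest_rows.sum(axis=0)).ravel() / n_rest
        pct_pc = pc_rows.getnnz(axis=0) / n_pc
        pct_rest = rest_rows.getnnz(axis=0) / n_rest
    else:
        x = np.asarray(norm.X, dtype=float).T  # genes x cells
        ranks, tie_term = midrank_rows(x)
        w = ranks[:, is_pc].sum(axis=1)
        mean_pc = x[:, is_pc].mean(axis=1)
        mean_rest = x[:, ~is_pc].mean(axis=1)
        pct_pc = (x[:, is_pc] > 0).mean(axis=1)
        pct_rest = (x[:, ~is_pc] > 0).mean(axis=1)

    mu = n_pc * (n_total + 1) / 2.0
    var = (n_pc * n_rest / 12.0) * (
        (n_total + 1) - tie_term / (n_total * (n_total - 1))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = np.minimum(np.where(var > 0, 2.0 * _norm.sf(np.abs(z)), 1.0), 1.0)

    return pd.DataFrame(
        {
            "W": w,
            "z": z,
            "p_two_sided": p,
            "adj_p": bh_adjust(p),
            "log_fc": mean_pc - mean_rest,
            "pct_in_pc": pct_pc,
            "pct_in_rest": pct_rest,
        },
        index=pd.Index(norm.var_names, name="gene"),
    )


def select_dataset_markers(
    stats: pd.DataFrame, params: SelectionParams | None = None
) -> list[str]:
    """Up-regulated significant genes of one dataset, ordered by z desc."""
    params = params or SelectionParams()
    keep = (
        (stats["adj_p"] <= params.adj_p_max)
        & (stats["log_fc"] >= params.log_fc_min)
        & (stats["z"] > 0)
    )
    return stats.loc[keep].sort_values("z", ascending=False).index.tolist()


def intersect_marker_lists(
    lists: dict[str, list[str]], min_datasets: int | None = None
) -> pd.DataFrame:
    """Support-counted intersection of per-dataset gene lists.

    ``min_datasets=None`` requires a gene in every list (strict
    intersection).  Returns a gene-indexed frame with the support count,
    sorted by support then gene id.
    """
    if not lists:
        raise ValueError("need at least one gene list")
    threshold = len(lists) if min_datasets is None else min_datasets
    support: dict[str, int] = {}
    for genes in lists.values():
        for g in set(genes):
            support[g] = support.get(g, 0) + 1
    table = pd.DataFrame(
        {"support": pd.Series(support, dtype=int)}
    ).rename_axis("gene")
    table = table[table["support"] >= threshold]
    return table.sort_values(["support", "gene"], ascending=[False, True])


def filter_surface_genes(genes, table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a gene list to surface-annotated genes, order preserved.

    Genes absent from the table are treated as unknown (non-surface) and
    dropped with a logged warning.  Returns gene-indexed frame with the
    CD alias.
    """
    rows = []
    for g in genes:
        if g not in table.index:
            logger.warning("gene %s unknown to the surface table; dropped", g)
            continue
        if bool(table.loc[g, "is_surface"]):
            rows.append((g, table.loc[g, "cd_alias"]))
    return pd.DataFrame(rows, columns=["gene", "cd_alias"]).set_index("gene")


def build_consensus_panel(
    stats_by_dataset: dict[str, pd.DataFrame],
    params: SelectionParams | None = None,
    surface_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Select per dataset, intersect, surface-filter; the consensus panel.

    Returns a gene-indexed frame with support count, median z across
    datasets and CD alias, ordered by median z descending.
    """
    params = params or SelectionParams()
    surface_table = surface_table if surface_table is not None else load_surface_table()
    lists = {ds: select_dataset_markers(st, params) for ds, st in stats_by_dataset.items()}
    supported = intersect_marker_lists(lists, params.min_datasets)
    panel = filter_surface_genes(supported.index.tolist(), surface_table)
    if panel.empty:
        return panel.assign(support=pd.Series(dtype=int), median_z=pd.Series(dtype=float))
    panel["support"] = supported.loc[panel.index, "support"]
    z = pd.DataFrame({ds: st["z"] for ds, st in stats_by_dataset.items()})
    panel["median_z"] = z.loc[panel.index].median(axis=1)
    return panel.sort_values("median_z", ascending=False)
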