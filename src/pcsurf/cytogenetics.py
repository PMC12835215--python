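"""Pseudobulk cytogenetic-proxy clustering of myeloma patients.

Each patient's profile is the mean log-normalised expression over up to
100 randomly sampled plasma cells.  Patients are clustered by Ward-linkage
hierarchical clustering on their z-scored expression of eight
transcriptional proxies of canonical cytogenetic lesions (FGFR3, CCND1,
CCND2, CCND3, MAF, MAFB, MCL1, IL6R); the number of clusters is chosen by
mean silhouette over a candidate range unless fixed.  Candidate-gene
expression is then contrasted between clusters with pairwise Welch
t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .annotate import PC_LABEL
from .simulate import PROXY_GENES, substream
from .stats import bh_adjust, significance_tier, welch_t_test

__all__ = [
    "PROXY_GENES",
    "ClusterAssignment",
    "make_pseudobulk",
    "cluster_pseudobulk",
    "compare_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Patient cluster labels plus the model-selection record."""

    labels: pd.Series            # patient -> cluster label (1..k)
    k: int
    silhouettes: dict[int, float]
    linkage_matrix: np.ndarray | None


def make_pseudobulk(
    norm: ad.AnnData,
    annot: pd.DataFrame,
    sample_size: int = 100,
    seed: int = 0,
    pc_label: str = PC_LABEL,
) -> pd.DataFrame:
    """Per-patient mean log-normalised profile over sampled plasma cells.

    Samples min(sample_size, available PCs) cells per patient without
    replacement under a named substream of ``seed``.  Patients with fewer
    PCs than ``sample_size`` are retained with a warning; patients with no
    annotated PCs are excluded with a warning.  Returns a patient-indexed
    frame of gene means plus an ``n_sampled`` column.
    """
    labels = annot.loc[norm.obs_names, "label"].to_numpy()
    is_pc = labels == pc_label
    patients = norm.obs["patient"].to_numpy()
    x = norm.X
    x = x.tocsr() if hasattr(x, "tocsr") else np.asarray(x)

    rows, ns, index = [], [], []
    for patient in pd.unique(patients):
        idx = np.flatnonzero(is_pc & (patients == patient))
        if idx.size == 0:
            logger.warning("patient %s has no annotated plasma cells; excluded", patient)
            continue
        if idx.size < sample_size:
            logger.warning(
                "patient %s has only %d plasma cells (< %d); using all",
                patient, idx.size, sample_size,
            )
            chosen = idx
        else:
            rng = substream(seed, f"pseudobulk:{patient}")
            chosen = idx[rng.choice(idx.size, size=sample_size, replace=False)]
        sub = x[chosen]
        mean = np.asarray(sub.mean(axis=0)).ravel()
        rows.append(mean)
        ns.append(chosen.size)
        index.append(patient)
    profiles = pd.DataFrame(rows, index=pd.Index(index, name="patient"),
                            columns=norm.var_names)
    profiles.insert(0, "n_sampled", ns)
    return profiles


def _zscore_proxies(profiles: pd.DataFrame, proxy_genes) -> np.ndarray:
    missing = [g for g in proxy_genes if g not in profiles.columns]
    if missing:
        raise KeyError(f"proxy genes absent from profiles: {missing}")
    x = profiles[list(proxy_genes)].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def cluster_pseudobulk(
    profiles: pd.DataFrame,
    proxy_genes=PROXY_GENES,
    k_range=range(2, 9),
    fixed_k: int | None = None,
) -> ClusterAssignment:
    """Ward hierarchical clustering on z-scored proxy-gene vectors.

    k is the silhouette-maximising candidate in ``k_range`` unless
    ``fixed_k`` is given.  All-identical profiles collapse to a single
    cluster with silhouette reported as NaN.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles to cluster")
    z = _zscore_proxies(profiles, proxy_genes)
    if np.allclose(z, z[0]):
        labels = pd.Series(1, index=profiles.index, name="cluster")
        return ClusterAssignment(labels=labels, k=1,
                                 silhouettes={1: float("nan")}, linkage_matrix=None)

    lk = linkage(z, method="ward")
    silhouettes: dict[int, float] = {}
    candidates = [fixed_k] if fixed_k is not None else [
        k for k in k_range if 2 <= k <= len(profiles) - 1
    ]
    best_k, best_s = None, -np.inf
    labels_by_k = {}
    for k in candidates:
        lab = fcluster(lk, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        if len(np.unique(lab)) < 2:
            silhouettes[k] = float("nan")
            continue
        s = float(silhouette_score(z, lab))
        silhouettes[k] = s
        if s > best_s:
            best_k, best_s = k, s
    if fixed_k is not None:
        best_k = fixed_k
    if best_k is None:
        raise ValueError("silhouette undefined for every candidate k")
    labels = pd.Series(labels_by_k[best_k], index=profiles.index, name="cluster")
    return ClusterAssignment(labels=labels, k=int(best_k),
                             silhouettes=silhouettes, linkage_matrix=lk)


def compare_clusters(
    profiles: pd.DataFrame, assignment: ClusterAssignment, gene: str
) -> pd.DataFrame:
    """Pairwise Welch t-tests of one gene's pseudobulk values by cluster.

    Pairs involving a cluster with < 2 patients are reported as NA; the
    remaining p-values are BH-adjusted across pairs.
    """
    if gene not in profiles.columns:
        raise KeyError(f"gene {gene!r} absent from profiles")
    values = profiles[gene]
    clusters = sorted(assignment.labels.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to compare")
    rows = []
    for a, b in combinations(clusters, 2):
        va = values[assignment.labels == a].to_numpy(dtype=float)
        vb = values[assignment.labels == b].to_numpy(dtype=float)
        if va.size < 2 or vb.size < 2:
            rows.append((a, b, np.nan, np.nan, np.nan,
                         float(va.mean()) if va.size else np.nan,
                         float(vb.mean()) if vb.size else np.nan))
            continue
        t, df, p = welch_t_test(va, vb)
        rows.append((a, b, t, df, p, float(va.mean()), float(vb.mean())))
    table = pd.DataFrame(
        rows,
        columns=["cluster_i", "cluster_j", "t", "df", "p_raw",
                 "mean_i", "mean_j"],
    )
    ok = table["p_raw"].notna()
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p_raw"].to_numpy())
    table["tier"] = [significance_tier(q) if not np.isnan(q) else "NA"
                     for q in table["p_adj"]]
    return table
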