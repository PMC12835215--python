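"""Candidate-gene expression across the disease-stage continuum.

Plasma cells are pooled across datasets within each stage (HD, MGUS, SMM,
MM, RRMM) and each candidate gene's log-normalised expression is compared
with a Kruskal-Wallis omnibus test plus all pairwise two-group contrasts,
BH-corrected across the contrasts per gene.  A gene's trend is flagged
monotone when its per-stage medians are non-decreasing in stage order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd

from .annotate import PC_LABEL
from .simulate import STAGES
from .stats import bh_adjust, kruskal_wallis, significance_tier

__all__ = ["StageComparison", "stage_compare", "kruskal_wallis"]


@dataclass
class StageComparison:
    """Per-gene stage comparison: summaries, omnibus test, pairwise table."""

    gene: str
    summaries: pd.DataFrame   # per stage: n, median, mean
    H: float
    p_omnibus: float
    pairwise: pd.DataFrame    # stage_i, stage_j, p_raw, p_adj, tier
    trend_monotone: bool


def _pc_values_by_stage(
    norms: list[ad.AnnData], annots: list[pd.DataFrame], gene: str,
    pc_label: str = PC_LABEL,
) -> dict[str, np.ndarray]:
    values: dict[str, list[np.ndarray]] = {}
    for norm, annot in zip(norms, annots):
        if gene not in norm.var_names:
            raise KeyError(f"gene {gene!r} absent from dataset matrix")
        labels = annot.loc[norm.obs_names, "label"].to_numpy()
        is_pc = labels == pc_label
        col = norm[:, gene].X
        col = np.asarray(col.todense()).ravel() if hasattr(col, "todense") else np.asarray(col).ravel()
        stages = norm.obs["stage"].to_numpy()
        for stage in np.unique(stages[is_pc]):
            sel = is_pc & (stages == stage)
            values.setdefault(str(stage), []).append(col[sel])
    return {s: np.concatenate(v) for s, v in values.items()}


def stage_compare(
    norms: list[ad.AnnData],
    annots: list[pd.DataFrame],
    gene: str,
    pc_label: str = PC_LABEL,
    min_cells: int = 2,
) -> StageComparison:
    """Compare one gene's PC expression across disease stages.

    Pools PCs across datasets per stage; runs the omnibus Kruskal-Wallis
    over stages with >= ``min_cells`` PCs, then a two-group Kruskal-Wallis
    per stage pair with BH correction across the pairs.
    """
    by_stage = _pc_values_by_stage(norms, annots, gene, pc_label)
    present = [s for s in STAGES if s in by_stage and by_stage[s].size >= min_cells]
    if len(present) < 2:
        raise ValueError(f"need >= 2 stages with >= {min_cells} PC cells for {gene}")

    groups = [by_stage[s] for s in present]
    h, p = kruskal_wallis(groups)
    summaries = pd.DataFrame(
        {
            "n": [g.size for g in groups],
            "median": [float(np.median(g)) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
        },
        index=pd.Index(present, name="stage"),
    )

    pairs = list(combinations(present, 2))
    raw = []
    for a, b in pairs:
        _, p_pair = kruskal_wallis([by_stage[a], by_stage[b]])
        raw.append(p_pair)
    adj = bh_adjust(raw)
    pairwise = pd.DataFrame(
        {
            "stage_i": [a for a, _ in pairs],
            "stage_j": [b for _, b in pairs],
            "p_raw": raw,
            "p_adj": adj,
            "tier": [significance_tier(q) for q in adj],
        }
    )
    medians = summaries["median"].to_numpy()
    monotone = bool(np.all(np.diff(medians) >= 0))
    return StageComparison(
        gene=gene, summaries=summaries, H=h, p_omnibus=p,
        pairwise=pairwise, trend_monotone=monotone,
    )
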