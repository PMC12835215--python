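"""End-to-end orchestration of the discovery pipeline.

``run_all`` executes simulate -> QC -> annotate -> consensus markers ->
stage comparison -> cytogenetic clustering -> survival on a single
:class:`PipelineConfig` and returns a machine-readable report.  All
randomness flows from one global seed through named per-stage substreams,
so the same config and seed always give the same report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import PC_LABEL, log_normalize, score_cell_types
from .cytogenetics import cluster_pseudobulk, compare_clusters, make_pseudobulk
from .markers import SelectionParams, build_consensus_panel, rank_pc_markers
from .qc import QCParams, run_qc
from .simulate import (
    CANDIDATE_GENES,
    SimConfig,
    reference_signatures,
    simulate_cohort,
    simulate_survival_cohort,
)
from .staging import stage_compare
from .survival import gene_survival_analysis

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """One config to drive every stage; seed propagates to all of them."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCParams = field(default_factory=QCParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    candidate_genes: tuple[str, ...] = CANDIDATE_GENES
    pseudobulk_sample_size: int = 100
    fixed_k: int | None = None
    survival_n: int = 1000
    survival_censor_fraction: float = 0.2
    survival_split: str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed; the simulator and survival cohort derive their
        # own substreams from it
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QCParams(**raw.pop("qc", {}))
        sel = SelectionParams(**raw.pop("selection", {}))
        cfg = cls(sim=sim, qc=qc, selection=sel, **raw)
        return cfg


def run_all(config: PipelineConfig | None = None) -> dict:
    """Run the whole pipeline; returns the run report as a plain dict."""
    config = config or PipelineConfig()
    adatas, truth = simulate_cohort(config.sim)
    ref = reference_signatures(config.sim)

    report: dict = {
        "pcsurf_version": __version__,
        "seed": config.seed,
        "datasets": {},
    }

    norms, annots = [], []
    stats_by_dataset = {}
    for adata in adatas:
        ds = str(adata.obs["dataset"].iloc[0])
        kept, qc_table, fit = run_qc(adata, params=config.qc)
        norm = log_normalize(kept)
        annot = score_cell_types(norm, ref)
        stats = rank_pc_markers(norm, annot)
        norms.append(norm)
        annots.append(annot)
        stats_by_dataset[ds] = stats
        report["datasets"][ds] = {
            "cells_in": int(adata.n_obs),
            "cells_pass_qc": int(kept.n_obs),
            "complexity_slope": round(fit.slope, 6),
            "pcs_annotated": int((annot["label"] == PC_LABEL).sum()),
        }

    panel = build_consensus_panel(stats_by_dataset, config.selection)
    report["consensus_panel"] = panel.index.tolist()
    report["n_panel_genes"] = int(len(panel))

    report["staging"] = {}
    for gene in config.candidate_genes:
        cmp_ = stage_compare(norms, annots, gene)
        report["staging"][gene] = {
            "H": round(cmp_.H, 6),
            "p_omnibus": float(cmp_.p_omnibus),
            "trend_monotone": bool(cmp_.trend_monotone),
            "stage_medians": {
                s: round(float(m), 6)
                for s, m in cmp_.summaries["median"].items()
            },
        }

    # Cytogenetic clustering over newly diagnosed MM patients only.
    mm_profiles = []
    for norm, annot in zip(norms, annots):
        mm = norm[norm.obs["stage"].to_numpy() == "MM"]
        if mm.n_obs == 0:
            continue
        prof = make_pseudobulk(
            mm, annot.loc[mm.obs_names],
            sample_size=config.pseudobulk_sample_size, seed=config.seed,
        )
        mm_profiles.append(prof)
    clusters_report: dict = {"k": 0, "n_patients": 0}
    if mm_profiles:
        profiles = pd.concat(mm_profiles)
        if len(profiles) >= 3:
            assignment = cluster_pseudobulk(profiles, fixed_k=config.fixed_k)
            clusters_report = {
                "k": int(assignment.k),
                "n_patients": int(len(profiles)),
                "cluster_sizes": {
                    int(c): int(n)
                    for c, n in assignment.labels.value_counts().sort_index().items()
                },
                "candidate_cluster_tests": {},
            }
            if assignment.k >= 2:
                for gene in config.candidate_genes:
                    table = compare_clusters(profiles, assignment, gene)
                    sig = table["p_adj"].dropna()
                    clusters_report["candidate_cluster_tests"][gene] = {
                        "min_p_adj": float(sig.min()) if len(sig) else None,
                    }
    report["cytogenetics"] = clusters_report

    cohort, surv_truth = simulate_survival_cohort(
        config.survival_n,
        censor_fraction=config.survival_censor_fraction,
        seed=config.seed,
    )
    report["survival"] = {}
    for gene in surv_truth.betas:
        res = gene_survival_analysis(cohort, gene, split=config.survival_split)
        report["survival"][gene] = {
            "hr": round(res["cox"].hr, 6),
            "ci95": [round(v, 6) for v in res["cox"].ci95],
            "wald_p": float(res["cox"].wald_p),
            "logrank_p": float(res["logrank_p"]),
        }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def consensus_panel_experiment(
    seed: int,
    sim: SimConfig | None = None,
    qc_params: QCParams | None = None,
    selection: SelectionParams | None = None,
) -> list[str]:
    """Discovery stages only (simulate -> QC -> annotate -> markers).

    Returns the consensus surface panel for one seed; the fast path used
    when only the panel is of interest.
    """
    sim = sim or SimConfig()
    sim.seed = seed
    adatas, _ = simulate_cohort(sim)
    ref = reference_signatures(sim)
    stats_by_dataset = {}
    for adata in adatas:
        ds = str(adata.obs["dataset"].iloc[0])
        kept, _, _ = run_qc(adata, params=qc_params or QCParams())
        norm = log_normalize(kept)
        annot = score_cell_types(norm, ref)
        stats_by_dataset[ds] = rank_pc_markers(norm, annot)
    panel = build_consensus_panel(stats_by_dataset, selection or SelectionParams())
    return panel.index.tolist()


def archetype_recovery_experiment(
    seed: int, n_mm_patients: int = 54, sample_size: int = 100
) -> tuple[int, pd.Series, pd.Series, pd.DataFrame]:
    """Single-dataset MM cohort -> pseudobulk -> proxy-gene clustering.

    Generates ``n_mm_patients`` newly diagnosed MM patients drawn from the
    default cytogenetic archetypes, runs QC, annotation and pseudobulk
    clustering, and returns (selected k, cluster labels, true archetypes,
    pseudobulk profiles) aligned on patient id.
    """
    # enough cells that a typical patient yields the full 100-PC sample
    sim = SimConfig(
        n_datasets=1,
        stages_per_dataset={"MM": n_mm_patients},
        cells_per_patient=(340, 500),
        seed=seed,
    )
    adatas, truth = simulate_cohort(sim)
    ref = reference_signatures(sim)
    kept, _, _ = run_qc(adatas[0])
    norm = log_normalize(kept)
    annot = score_cell_types(norm, ref)
    profiles = make_pseudobulk(norm, annot, sample_size=sample_size, seed=seed)
    assignment = cluster_pseudobulk(profiles)
    true_archetypes = truth.patients.loc[assignment.labels.index, "archetype"]
    return assignment.k, assignment.labels, true_archetypes, profiles
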