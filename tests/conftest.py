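"""Shared fixtures: one small simulated cohort processed through QC and
annotation, reused by the recovery tests."""

from __future__ import annotations

import logging

import pytest

from pcsurf.annotate import log_normalize, score_cell_types
from pcsurf.qc import run_qc
from pcsurf.simulate import SimConfig, reference_signatures, simulate_cohort

logging.getLogger("pcsurf").setLevel(logging.ERROR)


def small_config(seed: int = 11) -> SimConfig:
    """A reduced cohort: 3 datasets, 11 patients each, ~150-220 cells."""
    return SimConfig(
        n_datasets=3,
        stages_per_dataset={"HD": 3, "MGUS": 2, "SMM": 2, "MM": 3, "RRMM": 2},
        cells_per_patient=(150, 220),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    adatas, truth = simulate_cohort(cfg)
    return cfg, adatas, truth


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    """(config, truth, qc tables, log-normalised AnnDatas, annotations)."""
    cfg, adatas, truth = small_cohort
    ref = reference_signatures(cfg)
    qc_tables, norms, annots = [], [], []
    for adata in adatas:
        kept, qc_table, _ = run_qc(adata)
        norm = log_normalize(kept)
        qc_tables.append(qc_table)
        norms.append(norm)
        annots.append(score_cell_types(norm, ref))
    return cfg, truth, qc_tables, norms, annots
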