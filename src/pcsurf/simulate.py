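"""Synthetic bone-marrow scRNA-seq cohorts and bulk survival cohorts.

The generator emulates the statistical structure the discovery pipeline
assumes: several datasets of bone-marrow cells in which plasma cells (PCs)
are a minority population; a planted panel of PC-specific surface genes;
five candidate genes whose PC expression shifts with disease stage
(HD -> MGUS -> SMM -> MM -> RRMM); mitochondrial content confined to a
band for good cells and elevated in planted low-quality cells; a second
low-quality sub-population with suppressed transcriptomic complexity;
four cytogenetic archetypes among MM patients expressed through fold
changes on eight proxy genes; and a bulk survival cohort with stated
per-gene hazard signs.

Counts are negative binomial (mean/dispersion parameterisation, shared
dispersion) around per-cell-type expected proportions; mitochondrial
counts are constructed so that a good cell's mitochondrial fraction lies
inside the configured band exactly.  Every planted property is recorded
in a :class:`SimTruth` object so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "STAGES",
    "PANEL_GENES",
    "CANDIDATE_GENES",
    "PROXY_GENES",
    "MITO_GENES",
    "CELL_TYPES",
    "SimConfig",
    "SimTruth",
    "SurvivalTruth",
    "simulate_cohort",
    "simulate_survival_cohort",
    "reference_signatures",
    "substream",
]

# Disease-stage continuum, in progression order.
STAGES = ("HD", "MGUS", "SMM", "MM", "RRMM")

# The 15 PC-upregulated surface genes planted as the discovery target.
PANEL_GENES = (
    "TNFRSF17", "SDC1", "CD63", "FCRL5", "CD38", "SLAMF7", "TNFRSF13B",
    "CD59", "BST2", "BSG", "SLC44A1", "FCGR2B", "CD79B", "CD320", "ICAM3",
)

# The five candidates with stage-dependent regulation (subset of the panel).
CANDIDATE_GENES = ("TNFRSF13B", "CD59", "FCGR2B", "SLC44A1", "CD320")

# Transcriptional proxies of canonical myeloma cytogenetic lesions.
PROXY_GENES = ("FGFR3", "CCND1", "CCND2", "CCND3", "MAF", "MAFB", "MCL1", "IL6R")

# PC-restricted but intracellular genes: exercise the surface filter.
PC_DECOY_GENES = ("MZB1", "XBP1", "JCHAIN", "PRDM1", "DERL3")

# 13 mitochondrially encoded genes, named with the conventional MT- prefix.
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

CELL_TYPES = (
    "Plasma cell", "B", "CD4 T", "CD8 T", "NK",
    "Monocyte", "DC", "Erythroid", "HSPC",
)

# Composition of the non-PC bone-marrow compartment.
_OTHER_TYPE_PROPS = {
    "B": 0.15, "CD4 T": 0.25, "CD8 T": 0.18, "NK": 0.10,
    "Monocyte": 0.18, "DC": 0.04, "Erythroid": 0.06, "HSPC": 0.04,
}


def _default_stage_effects() -> dict[str, dict[str, float]]:
    """Stage-dependent PC fold changes for the five candidates.

    Monotone genes step x1.5 per stage; "late" genes jump in MM/RRMM;
    CD59 is elevated from SMM onward.
    """
    step = 1.5
    mono = {s: step**i for i, s in enumerate(STAGES)}
    late = {"HD": 1.0, "MGUS": 1.0, "SMM": 1.0, "MM": step**2, "RRMM": step**2}
    mid = {"HD": 1.0, "MGUS": 1.0, "SMM": step**2, "MM": step**2, "RRMM": step**2}
    return {
        "CD320": dict(mono),
        "SLC44A1": dict(mono),
        "TNFRSF13B": dict(late),
        "FCGR2B": dict(late),
        "CD59": dict(mid),
    }


def _default_archetypes() -> dict[str, dict[str, float]]:
    """Four cytogenetic archetypes as proxy-gene fold-change vectors.

    Primary lesion markers carry x6 folds; secondary cyclin-D/IL6R
    signatures follow the standard translocation/cyclin-D picture of
    myeloma (t(4;14) and MAF-driven disease upregulate CCND2; the
    hyperdiploid group is the IL6R-associated one with a moderate CCND1
    signal).
    """
    f = 6.0
    return {
        "CCND1_MCL1": {"CCND1": f, "MCL1": f},                 # t(11;14)-like
        "FGFR3_MCL1": {"FGFR3": f, "MCL1": f, "CCND2": 3.0},   # t(4;14)-like
        "MAF_MAFB": {"MAF": f, "MAFB": f, "CCND2": 3.0},       # t(14;16)/t(14;20)-like
        "HYPERDIPLOID": {"IL6R": 3.0, "CCND1": 2.0},           # hyperdiploid-like
    }


def _default_archetype_candidate_effects() -> dict[str, dict[str, float]]:
    # Couplings between genetic background and candidate surface antigens:
    # CD320 enriched in FGFR3/MCL1-driven disease, TNFRSF13B in CCND1/MCL1.
    return {
        "FGFR3_MCL1": {"CD320": 2.0},
        "CCND1_MCL1": {"TNFRSF13B": 2.0},
    }


@dataclass
class SimConfig:
    """Study conditions for a synthetic multi-dataset cohort."""

    n_datasets: int = 11
    stages_per_dataset: dict[str, int] = field(
        default_factory=lambda: {"HD": 3, "MGUS": 3, "SMM": 3, "MM": 3, "RRMM": 3}
    )
    cells_per_patient: tuple[int, int] = (200, 250)
    pc_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "HD": 0.05, "MGUS": 0.10, "SMM": 0.15, "MM": 0.30, "RRMM": 0.35,
        }
    )
    n_genes: int = 2000
    planted_surface_panel: tuple[str, ...] = PANEL_GENES
    planted_pc_fold: float = 8.0
    candidate_stage_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_stage_effects
    )
    mito_gene_ids: tuple[str, ...] = MITO_GENES
    mito_band: tuple[float, float] = (0.02, 0.06)
    lowq_mito_range: tuple[float, float] = (0.15, 0.35)
    lowq_fraction: float = 0.10
    lowq_gene_subset_fraction: float = 0.10
    nb_dispersion: float = 0.3
    archetype_spec: dict[str, dict[str, float]] = field(default_factory=_default_archetypes)
    archetype_candidate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_archetype_candidate_effects
    )
    library_size_range: tuple[int, int] = (1200, 6000)
    baseline_sigma: float = 1.0
    special_floor: float = 1.5
    type_marker_fold: float = 6.0
    n_type_markers: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for stage in self.stages_per_dataset:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        for frac in self.pc_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("pc_fraction values must lie in [0, 1]")
        if not 0.0 <= self.lowq_fraction <= 1.0:
            raise ValueError("lowq_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for effects in self.candidate_stage_effects.values():
            if any(f <= 0 for f in effects.values()):
                raise ValueError("fold changes must be positive")
        for spec in self.archetype_spec.values():
            if any(f <= 0 for f in spec.values()):
                raise ValueError("archetype fold changes must be positive")
        n_named = (
            len(self.planted_surface_panel) + len(PC_DECOY_GENES)
            + len(PROXY_GENES) + len(self.mito_gene_ids)
        )
        if self.n_genes < n_named + 50:
            raise ValueError("n_genes too small for the named gene sets")
        if set(self.mito_gene_ids) & set(self.planted_surface_panel):
            raise ValueError("mito genes must be disjoint from the planted panel")
        lo, hi = self.cells_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("invalid cells_per_patient range")
        for stage, n_pat in self.stages_per_dataset.items():
            if n_pat > 0 and self.pc_fraction.get(stage, 0.0) * lo < 1.0:
                raise ValueError("no plasma cells generable")


@dataclass
class SimTruth:
    """Ground truth for every planted property of a simulated cohort."""

    cells: pd.DataFrame      # barcode-indexed: dataset, patient, stage, cell_type, quality
    patients: pd.DataFrame   # patient-indexed: dataset, stage, archetype
    genes: pd.DataFrame      # gene-indexed: planted_pc_log_fc, stage_trend


@dataclass
class SurvivalTruth:
    """Planted log-hazard coefficients of a simulated survival cohort."""

    betas: dict[str, float]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a global seed.

    Streams are keyed by (seed, crc32(name)) so adding a stage never
    shifts another stage's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


class _GeneModel:
    """Deterministic gene universe shared by a cohort and its reference."""

    def __init__(self, config: SimConfig):
        rng = substream(config.seed, "gene-model")
        panel = list(config.planted_surface_panel)
        named = panel + [g for g in PC_DECOY_GENES if g not in panel]
        named += [g for g in PROXY_GENES if g not in named]
        mito = list(config.mito_gene_ids)
        n_filler = config.n_genes - len(named) - len(mito)
        filler = [f"GENE{i:04d}" for i in range(n_filler)]
        self.genes = np.array(named + mito + filler)
        self.n_genes = config.n_genes

        index = {g: i for i, g in enumerate(self.genes)}
        self.index = index
        self.panel_idx = np.array([index[g] for g in panel])
        self.decoy_idx = np.array([index[g] for g in PC_DECOY_GENES])
        self.proxy_idx = np.array([index[g] for g in PROXY_GENES])
        self.mito_idx = np.array([index[g] for g in mito])
        self.nonmito_idx = np.setdiff1d(np.arange(config.n_genes), self.mito_idx)

        # Log-normal baseline abundances; PC-planted and proxy genes floored
        # so their expression is reliably detectable at typical library sizes.
        w = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=config.n_genes)
        floored = np.concatenate([self.panel_idx, self.decoy_idx, self.proxy_idx])
        w[floored] = np.maximum(w[floored], config.special_floor)
        self.baseline = w
        self.mito_weights = rng.lognormal(0.0, 0.5, size=len(mito))
        self.mito_weights /= self.mito_weights.sum()

        # Disjoint marker-gene sets for the non-PC cell types, drawn from
        # the filler pool.
        filler_idx = np.array([index[g] for g in filler])
        picks = rng.choice(
            filler_idx, size=config.n_type_markers * len(_OTHER_TYPE_PROPS), replace=False
        )
        self.type_markers = {
            t: picks[i * config.n_type_markers : (i + 1) * config.n_type_markers]
            for i, t in enumerate(_OTHER_TYPE_PROPS)
        }
        self._config = config

    def _nonmito_props(self, weights: np.ndarray) -> np.ndarray:
        w = weights[self.nonmito_idx]
        return w / w.sum()

    def type_weights(self, cell_type: str, stage: str, archetype: str | None) -> np.ndarray:
        """Full-universe expected relative abundances for one cell state."""
        cfg = self._config
        w = self.baseline.copy()
        if cell_type == "Plasma cell":
            w[self.panel_idx] *= cfg.planted_pc_fold
            w[self.decoy_idx] *= cfg.planted_pc_fold
            for gene, effects in cfg.candidate_stage_effects.items():
                w[self.index[gene]] *= effects.get(stage, 1.0)
            if archetype is not None:
                for gene, fold in cfg.archetype_spec.get(archetype, {}).items():
                    w[self.index[gene]] *= fold
                for gene, fold in cfg.archetype_candidate_effects.get(archetype, {}).items():
                    w[self.index[gene]] *= fold
        elif cell_type in self.type_markers:
            w[self.type_markers[cell_type]] *= cfg.type_marker_fold
        return w

    def nonmito_props(self, cell_type: str, stage: str, archetype: str | None) -> np.ndarray:
        return self._nonmito_props(self.type_weights(cell_type, stage, archetype))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean m, var m + a m^2) as a gamma-Poisson mixture.

    Poisson with Gamma(shape 1/a, scale a*m) rate is exactly the
    mean/dispersion negative binomial; sampling the mixture directly is
    considerably faster than numpy's (r, p) path for large mean arrays.
    """
    r = 1.0 / dispersion
    lam = rng.standard_gamma(r, size=np.shape(mean)) * (mean / r)
    return rng.poisson(lam)


def _dense_to_csr(counts: np.ndarray) -> sparse.csr_matrix:
    """Single-pass dense-int -> CSR conversion (row-major scan)."""
    n_rows, n_cols = counts.shape
    flat = counts.ravel()
    nz = np.flatnonzero(flat)
    data = flat[nz]
    indices = (nz % n_cols).astype(np.int32)
    row_counts = np.bincount((nz // n_cols).astype(np.int64), minlength=n_rows)
    indptr = np.concatenate([[0], np.cumsum(row_counts)]).astype(np.int64)
    return sparse.csr_matrix((data, indices, indptr), shape=(n_rows, n_cols))


def _mito_counts_in_band(totals: np.ndarray, frac: np.ndarray,
                         band: tuple[float, float] | None) -> np.ndarray:
    """Mitochondrial totals hitting target fractions; clamped into the band.

    m/(m+T) >= lo iff m >= lo*T/(1-lo) (and symmetrically for hi), so the
    realised fraction of any cell with T > 0 lies inside [lo, hi] exactly.
    """
    m = np.rint(frac * totals / (1.0 - frac))
    if band is not None:
        lo, hi = band
        m_lo = np.ceil(lo * totals / (1.0 - lo))
        m_hi = np.floor(hi * totals / (1.0 - hi))
        m = np.clip(m, m_lo, np.maximum(m_lo, m_hi))
    m[totals == 0] = 0
    return m.astype(np.int64)


def _simulate_patient(
    rng: np.random.Generator,
    model: _GeneModel,
    config: SimConfig,
    stage: str,
    archetype: str | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts, true types and quality labels for one patient's cells."""
    lo, hi = config.cells_per_patient
    n_cells = int(rng.integers(lo, hi + 1))
    g_total = model.n_genes

    pc_frac = config.pc_fraction[stage]
    other = np.array(list(_OTHER_TYPE_PROPS.values()))
    probs = np.concatenate([[pc_frac], (1.0 - pc_frac) * other])
    type_names = np.array(["Plasma cell"] + list(_OTHER_TYPE_PROPS))
    type_idx = rng.choice(len(type_names), size=n_cells, p=probs)
    types = type_names[type_idx]

    quality = np.full(n_cells, "ok", dtype=object)
    is_lowq = rng.random(n_cells) < config.lowq_fraction
    kind = rng.random(n_cells) < 0.5
    quality[is_lowq & kind] = "high_mito"
    quality[is_lowq & ~kind] = "low_complexity"

    lib = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1,
                       size=n_cells)

    counts = np.zeros((n_cells, g_total), dtype=np.int32)
    n_nonmito = model.nonmito_idx.size
    lowc = quality == "low_complexity"
    n_keep = max(1, int(round(config.lowq_gene_subset_fraction * n_nonmito)))

    for t in np.unique(types):
        props = model.nonmito_props(t, stage, archetype)
        sel = (types == t) & ~lowc
        if sel.any():
            mean = lib[sel, None] * props[None, :]
            counts[np.ix_(sel, model.nonmito_idx)] = _nb_draw(
                rng, mean, config.nb_dispersion
            )
        # Low-complexity cells: transcripts concentrated into a random
        # per-cell subset of genes so they fall below the complexity
        # regression.  One batched draw over (cells x kept genes).
        rows = np.flatnonzero((types == t) & lowc)
        if rows.size:
            keep = np.argsort(rng.random((rows.size, n_nonmito)), axis=1)[:, :n_keep]
            p_sub = props[keep]
            p_sub /= p_sub.sum(axis=1, keepdims=True)
            mean = lib[rows, None] * p_sub
            counts[rows[:, None], model.nonmito_idx[keep]] = _nb_draw(
                rng, mean, config.nb_dispersion
            )

    totals = counts.sum(axis=1)
    frac = rng.uniform(*config.mito_band, size=n_cells)
    high = quality == "high_mito"
    frac[high] = rng.uniform(*config.lowq_mito_range, size=int(high.sum()))
    m = np.zeros(n_cells, dtype=np.int64)
    good = ~high
    m[good] = _mito_counts_in_band(totals[good], frac[good], config.mito_band)
    m[high] = _mito_counts_in_band(totals[high], frac[high], None)
    counts[:, model.mito_idx] = rng.multinomial(m, model.mito_weights)

    return counts, types, quality


def simulate_cohort(config: SimConfig | None = None) -> tuple[list[ad.AnnData], SimTruth]:
    """Generate one multi-dataset bone-marrow cohort plus ground truth.

    Returns one :class:`anndata.AnnData` per dataset (sparse integer UMI
    counts; ``obs``: dataset, patient, stage; ``var``: gene ids) and a
    :class:`SimTruth` recording every planted assignment.  Identical
    config and seed give bit-identical output.
    """
    config = config or SimConfig()
    config.validate()
    model = _GeneModel(config)
    archetype_names = list(config.archetype_spec)

    adatas: list[ad.AnnData] = []
    cell_rows: list[pd.DataFrame] = []
    patient_rows: list[dict] = []

    for d in range(config.n_datasets):
        ds_id = f"DS{d:02d}"
        rng = substream(config.seed, f"dataset:{ds_id}")
        blocks, obs_frames = [], []
        mm_counter = 0
        for stage in STAGES:
            n_pat = config.stages_per_dataset.get(stage, 0)
            for p in range(n_pat):
                patient = f"{ds_id}_{stage}{p:02d}"
                archetype = None
                if stage == "MM":
                    archetype = archetype_names[
                        (d + mm_counter) % len(archetype_names)
                    ]
                    mm_counter += 1
                counts, types, quality = _simulate_patient(
                    rng, model, config, stage, archetype
                )
                n_cells = counts.shape[0]
                barcodes = [f"{patient}_C{i:04d}" for i in range(n_cells)]
                obs = pd.DataFrame(
                    {"dataset": ds_id, "patient": patient, "stage": stage},
                    index=barcodes,
                )
                blocks.append(counts)
                obs_frames.append(obs)
                cell_rows.append(
                    obs.assign(cell_type=types, quality=quality)
                )
                patient_rows.append(
                    {"patient": patient, "dataset": ds_id, "stage": stage,
                     "archetype": archetype if archetype is not None else "NA"}
                )
        x = _dense_to_csr(np.concatenate(blocks, axis=0))
        obs = pd.concat(obs_frames)
        var = pd.DataFrame(index=pd.Index(model.genes, name="gene"))
        adatas.append(ad.AnnData(X=x, obs=obs, var=var))

    log_fc = np.zeros(model.n_genes)
    log_fc[model.panel_idx] = np.log(config.planted_pc_fold)
    log_fc[model.decoy_idx] = np.log(config.planted_pc_fold)
    trend = np.full(model.n_genes, "none", dtype=object)
    trend_map = {"CD320": "increasing", "SLC44A1": "increasing",
                 "TNFRSF13B": "late", "FCGR2B": "late", "CD59": "mid"}
    for gene, t in trend_map.items():
        if gene in model.index:
            trend[model.index[gene]] = t
    genes_df = pd.DataFrame(
        {"planted_pc_log_fc": log_fc, "stage_trend": trend},
        index=pd.Index(model.genes, name="gene"),
    )
    truth = SimTruth(
        cells=pd.concat(cell_rows),
        patients=pd.DataFrame(patient_rows).set_index("patient"),
        genes=genes_df,
    )
    return adatas, truth


def reference_signatures(config: SimConfig | None = None, scale: float = 10_000.0) -> pd.DataFrame:
    """Expected log-normalised cell-type centroids of the generative model.

    Rows are genes, columns cell types; entry = ln(1 + scale * p_g) where
    p_g is the expected share of gene g in that type's transcriptome
    (mitochondrial content at the centre of the good-cell band).  The PC
    centroid averages the stage-specific expected profiles, with no
    archetype folds.  Serves as the bundled reference for annotation.
    """
    config = config or SimConfig()
    config.validate()
    model = _GeneModel(config)
    f_mito = float(np.mean(config.mito_band))

    def full_props(cell_type: str, stage: str) -> np.ndarray:
        p = np.zeros(model.n_genes)
        p[model.nonmito_idx] = (1.0 - f_mito) * model.nonmito_props(cell_type, stage, None)
        p[model.mito_idx] = f_mito * model.mito_weights
        return p

    cols = {}
    for t in CELL_TYPES:
        if t == "Plasma cell":
            p = np.mean([full_props(t, s) for s in STAGES], axis=0)
        else:
            p = full_props(t, "HD")
        cols[t] = np.log1p(scale * p)
    return pd.DataFrame(cols, index=pd.Index(model.genes, name="gene"))


def _default_betas() -> dict[str, float]:
    # Planted prognostic directions: favourable (negative log-hazard) for
    # TNFRSF13B, CD59, FCGR2B; adverse for CD320 and SLC44A1, with
    # TNFRSF13B and CD320 the strongest in each direction.
    return {"TNFRSF13B": -0.5, "CD59": -0.3, "FCGR2B": -0.3,
            "SLC44A1": 0.35, "CD320": 0.5}


def simulate_survival_cohort(
    n_patients: int,
    betas: dict[str, float] | None = None,
    censor_fraction: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> tuple[pd.DataFrame, SurvivalTruth]:
    """Bulk survival cohort with exponential event times.

    Per-patient standardised expression values are standard normal per
    gene; event times are exponential with hazard
    ``h0 * exp(sum_g beta_g x_g)``; censoring is independent uniform with
    its scale tuned so the expected censored fraction equals
    ``censor_fraction``.  Returns (table, truth) where the table has
    columns ``patient``, one column per gene, ``time`` and ``event``.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if not 0.0 <= censor_fraction < 1.0:
        raise ValueError("censor_fraction must lie in [0, 1)")
    betas = dict(betas) if betas is not None else _default_betas()
    rng = substream(seed, "survival")

    genes = list(betas)
    x = rng.standard_normal((n_patients, len(genes)))
    lp = x @ np.array([betas[g] for g in genes])
    hazard = baseline_hazard * np.exp(lp)
    times = rng.exponential(1.0 / hazard)

    if censor_fraction == 0.0:
        event = np.ones(n_patients, dtype=int)
        obs_time = times
    else:
        from scipy.optimize import brentq

        # With C ~ U(0, c), P(censored | T=t) = min(t/c, 1); tune c so the
        # sample-average censoring probability matches the request.
        def mean_censored(c: float) -> float:
            return float(np.mean(np.minimum(times / c, 1.0))) - censor_fraction

        c_hi = float(times.max()) / max(censor_fraction, 1e-12) + 1.0
        c = brentq(mean_censored, 1e-12, c_hi)
        censor_times = rng.uniform(0.0, c, size=n_patients)
        event = (times <= censor_times).astype(int)
        obs_time = np.minimum(times, censor_times)

    table = pd.DataFrame(x, columns=genes)
    table.insert(0, "patient", [f"P{i:05d}" for i in range(n_patients)])
    table["time"] = np.maximum(obs_time, np.finfo(float).tiny)
    table["event"] = event
    return table, SurvivalTruth(betas=betas)
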