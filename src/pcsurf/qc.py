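"""Two-step single-cell quality control.

Step one is a uniform mitochondrial band filter (cells keep between 1%
and 10% mitochondrial UMIs by default).  Step two is dataset-specific: a
linear model of log10(genes detected) on log10(total UMIs) is fitted per
dataset over the cells that pass the mito band, and cells deviating from
the regression line by more than ``residual_k`` residual standard
deviations are excluded, together with hard bounds on genes per cell
(> min_genes) and UMIs per cell (< max_umis).  The complexity fit is
always computed per dataset, never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "QCParams",
    "ComplexityFit",
    "infer_mito_genes",
    "compute_cell_qc",
    "fit_complexity_model",
    "apply_qc_filters",
    "run_qc",
]


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the two-step filter.

    mito band inclusive at both ends; gene bound strict (> min_genes);
    UMI bound strict (< max_umis); complexity bound |residual| <=
    residual_k * residual SD (two-sided).
    """

    mito_low: float = 0.01
    mito_high: float = 0.10
    min_genes: int = 200
    max_umis: int = 30_000
    residual_k: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_low < self.mito_high <= 1.0:
            raise ValueError("require 0 <= mito_low < mito_high <= 1")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.max_umis <= self.min_genes:
            raise ValueError("max_umis must exceed min_genes")
        if self.residual_k <= 0:
            raise ValueError("residual_k must be positive")


@dataclass
class ComplexityFit:
    """OLS fit of log10(genes + 1) on log10(UMIs + 1) for one dataset."""

    slope: float
    intercept: float
    residual_sd: float
    n_cells_fit: int

    def predict(self, log_umis: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_umis, dtype=float)


def infer_mito_genes(var_names, prefix: str = "MT-") -> set[str]:
    """Mitochondrial gene ids identified by name prefix."""
    return {g for g in var_names if str(g).startswith(prefix)}


def compute_cell_qc(adata: ad.AnnData, mito_genes) -> pd.DataFrame:
    """Per-cell QC metrics: total UMIs, genes detected, mito fraction.

    Totals are exact integer sums; ``mito_fraction`` is mito UMIs over
    total UMIs exactly, defined as 0 for zero-total cells (which then
    fail the gene-count criterion downstream).
    """
    mito_genes = set(mito_genes)
    unknown = mito_genes - set(adata.var_names)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    if not mito_genes:
        warnings.warn("empty mitochondrial gene set; mito fractions will be 0")

    x = adata.X
    x = x.tocsr() if hasattr(x, "tocsr") else np.asarray(x)
    if hasattr(x, "toarray"):
        totals = np.asarray(x.sum(axis=1)).ravel()
        n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
        mito_mask = adata.var_names.isin(mito_genes)
        mito_totals = np.asarray(x[:, mito_mask].sum(axis=1)).ravel()
    else:
        totals = x.sum(axis=1)
        n_genes = (x > 0).sum(axis=1)
        mito_mask = adata.var_names.isin(mito_genes)
        mito_totals = x[:, mito_mask].sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "total_umis": totals.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_fraction": mito_fraction,
        },
        index=adata.obs_names,
    )


def fit_complexity_model(qc: pd.DataFrame, params: QCParams | None = None) -> ComplexityFit:
    """Fit the per-dataset complexity regression and write back residuals.

    Ordinary least squares of log10(n_genes + 1) on log10(total_umis + 1)
    over cells inside the mito band (the fit excludes mito-failed cells so
    contaminated cells do not drag the line); residuals are computed for
    every cell and stored in ``qc['complexity_residual']``.
    """
    params = params or QCParams()
    usable = (
        (qc["total_umis"] > 0)
        & (qc["mito_fraction"] >= params.mito_low)
        & (qc["mito_fraction"] <= params.mito_high)
    )
    if int(usable.sum()) < 10:
        raise ValueError("insufficient cells for complexity fit")

    lx = np.log10(qc["total_umis"].to_numpy(dtype=float) + 1.0)
    ly = np.log10(qc["n_genes"].to_numpy(dtype=float) + 1.0)
    design = np.column_stack([np.ones(int(usable.sum())), lx[usable.to_numpy()]])
    coef, *_ = np.linalg.lstsq(design, ly[usable.to_numpy()], rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])

    fitted_resid = ly[usable.to_numpy()] - (intercept + slope * lx[usable.to_numpy()])
    sd = float(fitted_resid.std(ddof=1)) if fitted_resid.size > 1 else 0.0
    qc["complexity_residual"] = ly - (intercept + slope * lx)
    return ComplexityFit(
        slope=slope, intercept=intercept, residual_sd=sd, n_cells_fit=int(usable.sum())
    )


def apply_qc_filters(
    qc: pd.DataFrame, fit: ComplexityFit, params: QCParams | None = None
) -> pd.Series:
    """Boolean keep-mask combining all four criteria; flags written back.

    A cell passes iff mito_low <= mito_fraction <= mito_high AND
    n_genes > min_genes AND total_umis < max_umis AND
    |complexity_residual| <= residual_k * residual_sd.  A degenerate fit
    (residual_sd == 0) defines no deviation, so the complexity criterion
    passes every cell.
    """
    params = params or QCParams()
    if "complexity_residual" not in qc:
        raise ValueError("complexity residuals not populated; run fit_complexity_model")
    pass_mito = (qc["mito_fraction"] >= params.mito_low) & (
        qc["mito_fraction"] <= params.mito_high
    )
    pass_genes = qc["n_genes"] > params.min_genes
    pass_umis = qc["total_umis"] < params.max_umis
    if fit.residual_sd <= 1e-12:  # degenerate fit: no deviation definable
        pass_complexity = pd.Series(True, index=qc.index)
    else:
        pass_complexity = (
            qc["complexity_residual"].abs() <= params.residual_k * fit.residual_sd
        )
    qc["pass_mito"] = pass_mito
    qc["pass_min_genes"] = pass_genes
    qc["pass_max_umis"] = pass_umis
    qc["pass_complexity"] = pass_complexity
    mask = pass_mito & pass_genes & pass_umis & pass_complexity
    qc["pass"] = mask
    return mask


def run_qc(
    adata: ad.AnnData, mito_genes=None, params: QCParams | None = None
) -> tuple[ad.AnnData, pd.DataFrame, ComplexityFit]:
    """Convenience wrapper: metrics, fit, filter; returns the kept subset."""
    params = params or QCParams()
    if mito_genes is None:
        mito_genes = infer_mito_genes(adata.var_names)
    qc = compute_cell_qc(adata, mito_genes)
    fit = fit_complexity_model(qc, params)
    mask = apply_qc_filters(qc, fit, params)
    return adata[mask.to_numpy()].copy(), qc, fit
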