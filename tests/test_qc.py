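"""Two-step QC: metrics arithmetic, complexity regression, filter logic."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsurf.qc import (
    ComplexityFit,
    QCParams,
    apply_qc_filters,
    compute_cell_qc,
    fit_complexity_model,
    infer_mito_genes,
)


def _adata(counts, genes, barcodes=None):
    counts = np.asarray(counts)
    barcodes = barcodes or [f"c{i}" for i in range(counts.shape[0])]
    return ad.AnnData(
        X=counts.astype(np.int32),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def _qc_table(total, genes, mito, residual=0.0):
    n = len(total)
    return pd.DataFrame(
        {
            "total_umis": total,
            "n_genes": genes,
            "mito_fraction": mito,
            "complexity_residual": np.full(n, residual, dtype=float),
        },
        index=[f"c{i}" for i in range(n)],
    )


class TestCellMetrics:
    def test_exact_arithmetic(self):
        adata = _adata([[5, 5]], ["geneA", "MT-1"])
        qc = compute_cell_qc(adata, {"MT-1"})
        row = qc.iloc[0]
        assert row["total_umis"] == 10
        assert row["n_genes"] == 2
        assert row["mito_fraction"] == 0.5

    def test_all_zero_cell_is_degenerate(self):
        adata = _adata([[0, 0], [3, 1]], ["geneA", "MT-1"])
        qc = compute_cell_qc(adata, {"MT-1"})
        assert qc.iloc[0]["total_umis"] == 0
        assert qc.iloc[0]["n_genes"] == 0
        assert qc.iloc[0]["mito_fraction"] == 0.0
        qc["complexity_residual"] = 0.0
        fit = ComplexityFit(slope=1.0, intercept=0.0, residual_sd=0.0, n_cells_fit=2)
        mask = apply_qc_filters(qc, fit, QCParams(min_genes=0, mito_low=0.0, mito_high=1.0))
        assert not mask.iloc[0]  # 0 genes fails even a min_genes=0 bound

    def test_unknown_mito_gene_rejected(self):
        adata = _adata([[1, 1]], ["geneA", "MT-1"])
        with pytest.raises(ValueError, match="absent"):
            compute_cell_qc(adata, {"MT-9"})

    def test_mito_prefix_inference(self):
        assert infer_mito_genes(["MT-CO1", "ACTB", "MT-ND1"]) == {"MT-CO1", "MT-ND1"}


class TestComplexityFit:
    def test_perfect_line_recovered_exactly(self):
        totals = np.array([100, 300, 1000, 3000, 10000, 500, 700, 1500, 2500, 4000])
        genes = 10 ** (0.8 * np.log10(totals + 1.0) + 0.1) - 1.0
        qc = _qc_table(totals, genes, np.full(10, 0.05))
        fit = fit_complexity_model(qc)
        assert fit.slope == pytest.approx(0.8, abs=1e-9)
        assert fit.intercept == pytest.approx(0.1, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        mask = apply_qc_filters(qc, fit, QCParams(min_genes=0, max_umis=10**6))
        assert mask.all()  # zero residual SD: no deviation definable

    def test_planted_outlier_fails_complexity(self):
        totals = np.geomspace(200, 20000, 30).round()
        genes = 10 ** (0.8 * np.log10(totals + 1.0) + 0.1) - 1.0
        # one cell half a log10 unit below the line
        genes[7] = 10 ** (0.8 * np.log10(totals[7] + 1.0) + 0.1 - 0.5) - 1.0
        qc = _qc_table(totals, genes, np.full(30, 0.05))
        fit = fit_complexity_model(qc)
        mask = apply_qc_filters(qc, fit, QCParams(min_genes=0, max_umis=10**6))
        assert not mask.iloc[7]
        assert mask.drop(mask.index[7]).all()
        # oracle: residual computed by hand from an independent lstsq
        lx = np.log10(totals + 1.0)
        ly = np.log10(genes + 1.0)
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(30), lx]), ly, rcond=None)
        resid7 = ly[7] - (coef[0] + coef[1] * lx[7])
        assert qc["complexity_residual"].iloc[7] == pytest.approx(resid7, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        totals = rng.integers(100, 30000, size=200)
        genes = np.minimum(totals, rng.integers(50, 4000, size=200))
        qc = _qc_table(totals, genes, rng.uniform(0.02, 0.08, size=200))
        fit = fit_complexity_model(qc)
        lx = np.log10(totals + 1.0)
        ly = np.log10(genes + 1.0)
        xm, ym = lx.mean(), ly.mean()
        slope = np.sum((lx - xm) * (ly - ym)) / np.sum((lx - xm) ** 2)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(ym - slope * xm, abs=1e-9)

    def test_fit_excludes_mito_failed_cells(self):
        totals = np.concatenate([np.geomspace(300, 10000, 20).round(),
                                 np.array([5000.0, 6000.0])])
        genes = 10 ** (0.5 * np.log10(totals + 1.0)) - 1.0
        genes[-2:] = 5.0  # two contaminated cells far off the line
        mito = np.concatenate([np.full(20, 0.05), np.array([0.5, 0.6])])
        qc = _qc_table(totals, genes, mito)
        fit = fit_complexity_model(qc)
        assert fit.n_cells_fit == 20
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_cells_rejected(self):
        qc = _qc_table([100] * 5, [50] * 5, [0.05] * 5)
        with pytest.raises(ValueError, match="insufficient cells"):
            fit_complexity_model(qc)


class TestFilterBounds:
    @pytest.mark.parametrize(
        "mito,n_genes,total,expected",
        [
            (0.005, 500, 5000, False),  # below the mito band
            (0.05, 500, 5000, True),
            (0.12, 500, 5000, False),   # above the mito band
            (0.01, 500, 5000, True),    # band inclusive at both ends
            (0.10, 500, 5000, True),
            (0.05, 200, 5000, False),   # gene bound strict
            (0.05, 201, 5000, True),
            (0.05, 500, 30000, False),  # UMI bound strict
            (0.05, 500, 29999, True),
        ],
    )
    def test_threshold_boundaries(self, mito, n_genes, total, expected):
        qc = _qc_table([total], [n_genes], [mito])
        fit = ComplexityFit(slope=1.0, intercept=0.0, residual_sd=0.0, n_cells_fit=10)
        mask = apply_qc_filters(qc, fit, QCParams())
        assert bool(mask.iloc[0]) is expected

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(0.0, 0.05), st.floats(0.06, 0.5),
        st.integers(0, 400), st.integers(500, 40000), st.floats(0.5, 5.0),
    )
    def test_tightening_bounds_never_admits_a_cell(
        self, mito_low, mito_high, min_genes, max_umis, k
    ):
        rng = np.random.default_rng(17)
        qc = _qc_table(
            rng.integers(1, 40000, size=60),
            rng.integers(0, 3000, size=60),
            rng.uniform(0, 0.5, size=60),
            residual=0.0,
        )
        qc["complexity_residual"] = rng.normal(0, 1, size=60)
        fit = ComplexityFit(slope=1.0, intercept=0.0, residual_sd=1.0, n_cells_fit=60)
        loose = apply_qc_filters(qc.copy(), fit, QCParams(
            mito_low=mito_low, mito_high=mito_high, min_genes=min_genes,
            max_umis=max_umis, residual_k=k))
        tight = apply_qc_filters(qc.copy(), fit, QCParams(
            mito_low=mito_low + 0.002, mito_high=mito_high - 0.002,
            min_genes=min_genes + 10, max_umis=max_umis - 10,
            residual_k=k * 0.5))
        assert not (tight & ~loose).any()

    def test_mask_is_pure_function_of_inputs(self):
        rng = np.random.default_rng(9)
        qc = _qc_table(rng.integers(100, 20000, 50), rng.integers(10, 2000, 50),
                       rng.uniform(0, 0.2, 50))
        qc["complexity_residual"] = rng.normal(0, 0.1, 50)
        fit = ComplexityFit(slope=0.8, intercept=0.1, residual_sd=0.1, n_cells_fit=50)
        m1 = apply_qc_filters(qc.copy(), fit, QCParams())
        m2 = apply_qc_filters(qc.copy(), fit, QCParams())
        pd.testing.assert_series_equal(m1, m2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QCParams(mito_low=0.2, mito_high=0.1)
        with pytest.raises(ValueError):
            QCParams(min_genes=500, max_umis=400)


class TestTruthRecovery:
    def test_planted_low_quality_cells_removed(self, processed_cohort):
        """Low-quality cells removed and good cells kept, both >= 95%."""
        cfg, truth, qc_tables, _, _ = processed_cohort
        for qc in qc_tables:
            quality = truth.cells.loc[qc.index, "quality"]
            bad = quality != "ok"
            good = ~bad
            assert (~qc.loc[bad.to_numpy(), "pass"]).mean() >= 0.95
            assert qc.loc[good.to_numpy(), "pass"].mean() >= 0.95

    def test_high_mito_cells_caught_by_mito_band(self, processed_cohort):
        cfg, truth, qc_tables, _, _ = processed_cohort
        for qc in qc_tables:
            high_mito = truth.cells.loc[qc.index, "quality"] == "high_mito"
            flagged = ~qc["pass_mito"]
            assert flagged[high_mito.to_numpy()].mean() >= 0.95
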