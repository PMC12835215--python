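"""Pseudobulk profiles, proxy-gene clustering, cluster contrasts."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from pcsurf.cytogenetics import (
    PROXY_GENES,
    cluster_pseudobulk,
    compare_clusters,
    make_pseudobulk,
)
from pcsurf.pipeline import archetype_recovery_experiment


def _norm_with_patients(values, patients, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    adata = ad.AnnData(
        X=sparse.csr_matrix(values),
        obs=pd.DataFrame({"patient": patients},
                         index=[f"c{i}" for i in range(values.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    annot = pd.DataFrame({"label": ["Plasma cell"] * values.shape[0]},
                         index=adata.obs_names)
    return adata, annot


def _profiles(points, noise=0.02, seed=0, genes=PROXY_GENES):
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for label, (center, n) in enumerate(points):
        for i in range(n):
            rows.append(center + rng.normal(0, noise, len(genes)))
            names.append(f"P{label}_{i}")
    df = pd.DataFrame(rows, columns=list(genes),
                      index=pd.Index(names, name="patient"))
    df.insert(0, "n_sampled", 100)
    return df


class TestMakePseudobulk:
    def test_caps_sample_at_requested_size(self):
        values = np.random.default_rng(0).uniform(0, 2, size=(250, 5))
        adata, annot = _norm_with_patients(values, ["A"] * 250)
        prof = make_pseudobulk(adata, annot, sample_size=100, seed=1)
        assert prof.loc["A", "n_sampled"] == 100

    def test_patient_with_exactly_sample_size_uses_all(self):
        values = np.random.default_rng(0).uniform(0, 2, size=(100, 5))
        adata, annot = _norm_with_patients(values, ["A"] * 100)
        prof = make_pseudobulk(adata, annot, sample_size=100, seed=7)
        assert prof.loc["A", "n_sampled"] == 100
        np.testing.assert_allclose(prof.loc["A"].drop("n_sampled").to_numpy(),
                                   values.mean(axis=0), atol=1e-9)

    def test_constant_gene_gives_constant_pseudobulk(self):
        values = np.full((120, 3), 1.7)
        adata, annot = _norm_with_patients(values, ["A"] * 120)
        prof = make_pseudobulk(adata, annot, sample_size=50, seed=3)
        assert prof.loc["A", "g0"] == pytest.approx(1.7, abs=1e-9)

    def test_reproducible_under_seed(self):
        values = np.random.default_rng(1).uniform(0, 2, size=(300, 4))
        adata, annot = _norm_with_patients(values, ["A"] * 150 + ["B"] * 150)
        p1 = make_pseudobulk(adata, annot, seed=5)
        p2 = make_pseudobulk(adata, annot, seed=5)
        pd.testing.assert_frame_equal(p1, p2)
        p3 = make_pseudobulk(adata, annot, seed=6)
        assert not np.allclose(p1.drop(columns="n_sampled"),
                               p3.drop(columns="n_sampled"))

    def test_patient_without_pcs_excluded(self):
        values = np.random.default_rng(2).uniform(0, 2, size=(40, 4))
        adata, annot = _norm_with_patients(values, ["A"] * 20 + ["B"] * 20)
        annot.loc[adata.obs["patient"] == "B", "label"] = "NK"
        prof = make_pseudobulk(adata, annot, sample_size=10, seed=0)
        assert prof.index.tolist() == ["A"]


class TestClusterPseudobulk:
    def test_two_point_masses_give_two_clusters(self):
        prof = _profiles([(np.zeros(8), 20), (np.full(8, 5.0), 20)])
        assignment = cluster_pseudobulk(prof)
        assert assignment.k == 2
        left = assignment.labels.iloc[:20]
        right = assignment.labels.iloc[20:]
        assert left.nunique() == 1 and right.nunique() == 1
        assert left.iloc[0] != right.iloc[0]

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(4)
        centers = [np.zeros(8), np.eye(8)[0] * 4, np.eye(8)[3] * 4]
        prof = _profiles([(c, 15) for c in centers], noise=0.3)
        a1 = cluster_pseudobulk(prof)
        perm = rng.permutation(len(prof))
        a2 = cluster_pseudobulk(prof.iloc[perm])
        joined = pd.concat([a1.labels.rename("a"), a2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_identical_profiles_collapse_to_one_cluster(self):
        prof = _profiles([(np.ones(8), 10)], noise=0.0)
        assignment = cluster_pseudobulk(prof)
        assert assignment.k == 1
        assert np.isnan(assignment.silhouettes[1])

    def test_fixed_k_override(self):
        prof = _profiles([(np.zeros(8), 12), (np.full(8, 4.0), 12)])
        assignment = cluster_pseudobulk(prof, fixed_k=3)
        assert assignment.k == 3

    def test_archetype_recovery_single_seed(self):
        """Planted archetypes recovered from a small MM-only cohort."""
        k, labels, truth, _ = archetype_recovery_experiment(seed=3, n_mm_patients=32)
        assert k == 4
        assert adjusted_rand_score(truth.to_numpy(), labels.to_numpy()) >= 0.9


class TestCompareClusters:
    def _assignment(self, labels, index):
        from pcsurf.cytogenetics import ClusterAssignment
        s = pd.Series(labels, index=index, name="cluster")
        return ClusterAssignment(labels=s, k=len(set(labels)),
                                 silhouettes={}, linkage_matrix=None)

    def test_identical_value_multisets_are_null(self):
        prof = _profiles([(np.zeros(8), 10)], noise=0.0)
        prof["CD320"] = [1.0, 2.0, 3.0, 4.0, 5.0] * 2
        assignment = self._assignment([1] * 5 + [2] * 5, prof.index)
        table = compare_clusters(prof, assignment, "CD320")
        assert table.iloc[0]["t"] == 0.0
        assert table.iloc[0]["p_raw"] == 1.0

    def test_separated_clusters_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for seed in range(10):
            prof = _profiles([(np.zeros(8), 15), (np.ones(8), 15)], seed=seed)
            prof["CD320"] = np.concatenate([
                np.random.default_rng(seed).normal(0, 1, 15),
                np.random.default_rng(seed + 100).normal(3, 1, 15),
            ])
            assignment = self._assignment([1] * 15 + [2] * 15, prof.index)
            table = compare_clusters(prof, assignment, "CD320")
            if table.iloc[0]["p_raw"] < 0.001:
                hits += 1
        assert hits >= 9

    def test_small_cluster_reported_na(self):
        prof = _profiles([(np.zeros(8), 6)], noise=0.1)
        prof["CD320"] = np.arange(6, dtype=float)
        assignment = self._assignment([1, 1, 1, 1, 1, 2], prof.index)
        table = compare_clusters(prof, assignment, "CD320")
        assert np.isnan(table.iloc[0]["t"])
        assert table.iloc[0]["tier"] == "NA"

    def test_candidate_archetype_coupling_recovered(self):
        """CD320 is enriched in the FGFR3-archetype pseudobulk cluster."""
        from pcsurf.cytogenetics import ClusterAssignment

        k, labels, truth, profiles = archetype_recovery_experiment(
            seed=12, n_mm_patients=32
        )
        fgfr3 = truth == "FGFR3_MCL1"
        assert profiles.loc[fgfr3, "CD320"].mean() > profiles.loc[~fgfr3, "CD320"].mean()
        assignment = ClusterAssignment(labels=labels, k=k, silhouettes={},
                                       linkage_matrix=None)
        table = compare_clusters(profiles, assignment, "CD320")
        # the FGFR3-dominated cluster separates from at least one other
        fgfr3_cluster = labels[fgfr3.to_numpy()].mode().iloc[0]
        involved = table[(table["cluster_i"] == fgfr3_cluster)
                         | (table["cluster_j"] == fgfr3_cluster)]
        assert (involved["p_adj"].dropna() < 0.05).any()
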