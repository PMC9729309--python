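"""Heterogeneity quantification: oracles, boundary identities, ordering."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_adata
from scipy.cluster.hierarchy import fcluster

import ecofinger as ef
from ecofinger.hetero import (
    celltype_region_correlation,
    correlation_distributions,
    covariate_association,
    immune_scores,
    region_dendrogram,
    select_variable_genes,
)


class TestVariableGenes:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 1, (30, 5))
        X[:, 2] = 1.0  # constant
        ranked = select_variable_genes(make_adata(X), top_k=4)
        assert "g2" not in ranked.index

    def test_larger_standardized_variance_wins(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 0.5, (60, 12))
        X[:, 7] = 5 + rng.normal(0, 4, 60)  # same mean, inflated variance
        ranked = select_variable_genes(make_adata(np.abs(X)), top_k=1)
        assert list(ranked.index) == ["g7"]

    def test_matches_bruteforce_standardized_variance(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(0.5, 0.8, (25, 50))
        ranked = select_variable_genes(make_adata(X), top_k=50)

        # independent brute force: same definition, plain loops
        n = X.shape[0]
        mean = X.mean(axis=0)
        var = X.var(axis=0, ddof=1)
        coef = np.polyfit(np.log10(mean), np.log10(var), 2)
        scores = []
        for j in range(50):
            sd_hat = np.sqrt(10 ** np.polyval(coef, np.log10(mean[j])))
            z = np.clip((X[:, j] - mean[j]) / sd_hat, -np.sqrt(n), np.sqrt(n))
            scores.append(np.var(z, ddof=1))
        expected = [
            f"g{j}" for j in np.argsort(scores, kind="stable")[::-1]
        ]
        # compare score values gene-by-gene (ordering may tie-break)
        np.testing.assert_allclose(
            ranked.loc[[f"g{j}" for j in range(50)], "score"],
            scores,
            rtol=1e-9,
        )
        assert list(ranked.index[:10]) == expected[:10]

    def test_top_k_larger_than_gene_count_returns_all(self):
        X = np.random.default_rng(3).lognormal(0, 1, (10, 4))
        ranked = select_variable_genes(make_adata(X), top_k=99)
        assert len(ranked) == 4


class TestCorrelationDistributions:
    @staticmethod
    def _adata(X, patients, regions):
        a = make_adata(X, patient=patients, region=regions)
        a.obs["is_malignant"] = True
        return a

    def test_anticorrelated_cells_give_minus_one(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        a = self._adata(X, ["P1", "P1"], ["T1", "T1"])
        res = correlation_distributions(a, a.obs, a.var_names)
        assert res["pairs"]["level"].tolist() == ["intraregion"]
        np.testing.assert_allclose(res["pairs"]["r"], [-1.0])

    def test_identical_cells_give_plus_one(self):
        X = np.tile([1.0, 5.0, 2.0, 4.0], (6, 1))
        a = self._adata(
            X, ["P1"] * 3 + ["P2"] * 3, ["T1", "T1", "T2", "T1", "T1", "T2"]
        )
        res = correlation_distributions(a, a.obs, a.var_names)
        np.testing.assert_allclose(res["pairs"]["r"], 1.0)
        assert set(res["pairs"]["level"]) == {
            "intraregion", "interregion", "intertumor"
        }

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(4)
        n = 12
        X = rng.lognormal(0, 1, (n, 20))
        patients = ["P1"] * 6 + ["P2"] * 6
        regions = (["T1"] * 3 + ["T2"] * 3) * 2
        a = self._adata(X, patients, regions)
        res = correlation_distributions(a, a.obs, a.var_names)["pairs"]

        from scipy.stats import pearsonr

        for i in range(n):
            for j in range(i + 1, n):
                r_oracle = pearsonr(X[i], X[j])[0]
                if patients[i] != patients[j]:
                    level = "intertumor"
                elif regions[i] != regions[j]:
                    level = "interregion"
                else:
                    level = "intraregion"
                row = res[
                    (
                        (res["patient_a"] == patients[i])
                        & (res["patient_b"] == patients[j])
                        | (res["patient_a"] == patients[j])
                        & (res["patient_b"] == patients[i])
                    )
                ]
                assert level in set(row["level"])
                assert np.isclose(np.abs(row["r"] - r_oracle).min(), 0,
                                  atol=1e-9)

    def test_single_cell_region_flagged_not_detectable(self):
        X = np.random.default_rng(5).lognormal(0, 1, (3, 8))
        a = self._adata(X, ["P1"] * 3, ["T1", "T1", "T2"])
        res = correlation_distributions(a, a.obs, a.var_names)
        assert ("P1", "T2") in res["not_detectable"]

    def test_patient_programs_order_intertumor_below_interregion(self):
        # planted patient-specific malignant programs shared across the
        # regions of a patient
        wins = 0
        n_sims = 30
        for s in range(n_sims):
            cfg = ef.SimulationConfig(
                seed=200 + s, n_patients=3,
                regions_per_patient=("T1", "T2", "N"),
                n_malignant_per_region=8, n_per_celltype=1,
                n_genes=300, n_chromosomes=5,
                planted_pairs=(),
            )
            a = ef.simulate.generate_cohort(cfg)
            norm = ef.cells.qc_and_normalize(a, min_genes_per_cell=10)
            norm.obs["is_malignant"] = norm.obs["true_malignant"]
            hv = select_variable_genes(
                norm[norm.obs["is_malignant"]], top_k=150
            )
            res = correlation_distributions(norm, norm.obs, hv.index)
            m = res["pairs"].groupby("level")["r"].mean()
            wins += m["intertumor"] < m["interregion"]
        assert wins / n_sims >= 0.95


class TestRegionDendrogram:
    def test_single_sample_is_trivial(self):
        X = np.random.default_rng(0).lognormal(0, 1, (4, 6))
        a = make_adata(X, patient=["P1"] * 4, region=["T1"] * 4)
        a.obs["is_malignant"] = True
        Z, labels = region_dendrogram(a, a.obs, a.var_names)
        assert Z is None and labels == ["P1_T1"]

    def test_duplicated_sample_merges_at_height_zero(self):
        base = np.random.default_rng(1).lognormal(0, 1, 10)
        X = np.vstack([base, base, base * 2 + 7])
        a = make_adata(
            X, patient=["P1", "P1", "P2"], region=["T1", "T2", "T1"]
        )
        a.obs["is_malignant"] = True
        Z, labels = region_dendrogram(a, a.obs, a.var_names)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_patient_programs_cluster_by_patient(self):
        rng = np.random.default_rng(2)
        progs = {"P1": np.zeros(40), "P2": np.zeros(40)}
        progs["P1"][:20] = 5.0
        progs["P2"][20:] = 5.0
        rows, pats, regs = [], [], []
        for p in ("P1", "P2"):
            for r in ("T1", "T2"):
                for _ in range(5):
                    rows.append(progs[p] + rng.normal(0, 0.3, 40))
                    pats.append(p)
                    regs.append(r)
        a = make_adata(np.array(rows), patient=pats, region=regs)
        a.obs["is_malignant"] = True
        Z, labels = region_dendrogram(a, a.obs, a.var_names)
        cut = fcluster(Z, 2, criterion="maxclust")
        by_patient = {lab.split("_")[0] for lab in labels}
        for p in by_patient:
            members = {cut[i] for i, lab in enumerate(labels)
                       if lab.startswith(p)}
            assert len(members) == 1

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, (12, 15))
        pats = ["P1"] * 6 + ["P2"] * 6
        regs = (["T1"] * 3 + ["T2"] * 3) * 2
        a = make_adata(X, patient=pats, region=regs)
        a.obs["is_malignant"] = True
        Z1, l1 = region_dendrogram(a, a.obs, a.var_names)
        perm = rng.permutation(12)
        b = a[perm].copy()
        Z2, l2 = region_dendrogram(b, b.obs, a.var_names)
        assert l1 == l2
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)


class TestCovariateAssociation:
    def test_identity_covariate_gives_r_one(self):
        stat = [1.0, 2.0, 5.0, 3.0]
        r, p = covariate_association(stat, stat)
        assert r == pytest.approx(1.0)

    def test_two_patients_is_an_error(self):
        with pytest.raises(ValueError):
            covariate_association([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_covariate_is_an_error(self):
        with pytest.raises(ValueError):
            covariate_association([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_independent_covariate_rarely_correlates(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            r, _ = covariate_association(
                rng.normal(size=200), rng.normal(size=200)
            )
            hits += abs(r) < 0.2
        assert hits >= 95


class TestImmuneScores:
    @staticmethod
    def _signatures():
        return {
            "immune": ["g0", "g1"],
            "cytotoxic": ["g2", "g3"],
            "exhaustion": ["g4", "g5"],
        }

    def test_ratio_of_uniform_signatures(self):
        X = np.ones((6, 6))
        X[:, [2, 3]] = 2.0  # cytotoxic genes at 2x
        a = make_adata(X, patient=["P1"] * 3 + ["P2"] * 3)
        out = immune_scores(a, a.obs, self._signatures())
        np.testing.assert_allclose(
            out["cytotoxic_exhaustion_ratio"], 2.0, rtol=1e-6
        )

    def test_missing_signature_genes_flagged(self):
        X = np.ones((4, 6))
        a = make_adata(X, patient=["P1"] * 4)
        sigs = self._signatures()
        sigs["exhaustion"] = ["absent1", "absent2"]
        out = immune_scores(a, a.obs, sigs)
        assert out["undefined"].all()
        assert out["exhaustion"].isna().all()

    def test_pseudobulk_matches_per_gene_mean_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.lognormal(0, 1, (10, 6))
        a = make_adata(X, patient=["P1"] * 4 + ["P2"] * 6)
        out = immune_scores(a, a.obs, self._signatures())
        expected_p1 = X[:4, [2, 3]].mean()
        assert out.loc["P1", "cytotoxic"] == pytest.approx(expected_p1)


class TestCelltypeRegionCorrelation:
    def test_identical_profiles_give_unit_ratio(self):
        X = np.tile([1.0, 3.0, 2.0, 5.0, 4.0], (12, 1))
        a = make_adata(
            X,
            cell_types=["T"] * 12,
            patient=["P1"] * 12,
            region=["T1"] * 4 + ["T2"] * 4 + ["B"] * 4,
        )
        res = celltype_region_correlation(a, a.obs, {"T": list(a.var_names)})
        np.testing.assert_allclose(res["region_pairs"]["r"], 1.0, rtol=1e-9)
        np.testing.assert_allclose(res["border_core_ratio"]["ratio"], 1.0)

    def test_single_region_yields_no_pairs(self):
        X = np.random.default_rng(8).lognormal(0, 1, (5, 6))
        a = make_adata(
            X, cell_types=["T"] * 5, patient=["P1"] * 5, region=["T1"] * 5
        )
        res = celltype_region_correlation(a, a.obs, {"T": list(a.var_names)})
        assert len(res["region_pairs"]) == 0

    def test_border_shift_moves_ratio_from_one(self):
        # 1 SD border program shift, 100 cells/region: power >= 0.9
        detections = 0
        n_sims = 10
        for s in range(n_sims):
            rng = np.random.default_rng(300 + s)
            n, g = 100, 60
            shift = rng.normal(0, 1.0, g)
            rows, regs = [], []
            for region in ("T1", "T2", "B"):
                mu = shift if region == "B" else np.zeros(g)
                rows.append(rng.normal(mu, 1.0, (n, g)))
                regs += [region] * n
            a = make_adata(
                np.abs(np.vstack(rows)),
                cell_types=["T"] * 3 * n,
                patient=["P1"] * 3 * n,
                region=regs,
            )
            res = celltype_region_correlation(
                a, a.obs, {"T": list(a.var_names)}
            )
            ratio = res["border_core_ratio"]["ratio"].iloc[0]
            detections += abs(ratio - 1.0) > 0.05
        assert detections >= 9
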