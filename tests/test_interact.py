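"""Ligand-receptor permutation test, filters, and the experiments on it."""

import itertools

import numpy as np
import pandas as pd
import pytest
from conftest import make_adata

import ecofinger as ef
from ecofinger.config import PlantedPair
from ecofinger.interact import (
    _derangement,
    filter_pairs,
    interaction_overlap,
    lr_permutation_test,
    regional_stability,
    significant_keys,
    subsample_accuracy,
    switching_experiment,
)


def _db(pairs):
    return pd.DataFrame(
        {
            "pair_id": [f"{l}_{r}" for l, r in pairs],
            "ligand": [p[0] for p in pairs],
            "receptor": [p[1] for p in pairs],
        }
    )


def _two_type_adata(X, n_a, n_b, genes=("LIG", "REC")):
    a = make_adata(X, cell_types=["malignant"] * n_a + ["TAM"] * n_b)
    a.var_names = list(genes) + [
        f"g{j}" for j in range(X.shape[1] - len(genes))
    ]
    return a


class TestPermutationTest:
    def test_exact_mode_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.lognormal(0, 1, (8, 2))
        a = _two_type_adata(X, 4, 4)
        rec = lr_permutation_test(
            a, _db([("LIG", "REC")]), method="exact", min_cells=2,
            min_expr_frac=0.0,
        )
        lig, recg = X[:, 0], X[:, 1]
        for direction, src_rows in (("tumor->TME", True), ("TME->tumor", False)):
            if src_rows:
                obs = 0.5 * (lig[:4].mean() + recg[4:].mean())
            else:
                obs = 0.5 * (lig[4:].mean() + recg[:4].mean())
            null = []
            for combo in itertools.combinations(range(8), 4):
                m = np.zeros(8, bool)
                m[list(combo)] = True
                if src_rows:
                    null.append(0.5 * (lig[m].mean() + recg[~m].mean()))
                else:
                    null.append(0.5 * (lig[~m].mean() + recg[m].mean()))
            expected = float(np.sum(np.array(null) >= obs)) / 70.0
            got = rec.loc[rec["direction"] == direction, "p_value"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_uniform_expression_gives_p_one(self):
        X = np.ones((8, 2))
        a = _two_type_adata(X, 4, 4)
        rec = lr_permutation_test(
            a, _db([("LIG", "REC")]), method="exact", min_cells=2
        )
        assert (rec["p_value"] == 1.0).all()

    def test_all_zero_expression_gives_statistic_zero_p_one(self):
        X = np.zeros((8, 2))
        a = _two_type_adata(X, 4, 4)
        rec = lr_permutation_test(
            a, _db([("LIG", "REC")]), n_permutations=200, min_cells=2,
            min_expr_frac=0.0,
        )
        assert (rec["pair_mean"] == 0.0).all()
        assert (rec["p_value"] == 1.0).all()

    def test_add_one_rule_bounds_minimum_p(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(0, 0.2, (60, 2))
        X[:30, 0] += 50  # ligand huge in malignant
        X[30:, 1] += 50  # receptor huge in TAM
        a = _two_type_adata(X, 30, 30)
        n_perm = 250
        rec = lr_permutation_test(
            a, _db([("LIG", "REC")]), n_permutations=n_perm, seed=3
        )
        row = rec[rec["direction"] == "tumor->TME"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0 / (n_perm + 1))

    def test_expression_gate_skips_sparse_genes(self):
        X = np.ones((40, 2))
        X[:, 1] = 0.0
        X[20, 1] = 1.0  # receptor in 1/20 TAM cells: below the 10% gate
        a = _two_type_adata(X, 20, 20)
        rec = lr_permutation_test(
            a, _db([("LIG", "REC")]), n_permutations=100
        )
        assert len(rec) == 0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(9)
        X = rng.lognormal(0, 1, (40, 6))
        a = _two_type_adata(X, 20, 20)
        db = _db([("LIG", "REC"), ("g0", "g1")])
        r1 = lr_permutation_test(a, db, n_permutations=300, seed=11)
        r2 = lr_permutation_test(a, db, n_permutations=300, seed=11)
        pd.testing.assert_frame_equal(r1, r2)


class TestFilterPairs:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "pair_id", "ligand", "receptor", "direction",
                "partner_celltype", "p_value", "pair_mean",
            ],
        )

    def test_boundary_p_and_mean_are_strict(self):
        rec = self._records(
            [
                ("c1", "A_B", "A", "B", "tumor->TME", "TAM", 0.01, 2.0),
                ("c1", "C_D", "C", "D", "tumor->TME", "TAM", 0.005, 0.5),
                ("c1", "E_F", "E", "F", "tumor->TME", "TAM", 0.005, 0.6),
            ]
        )
        out = filter_pairs(rec, drop_ubiquitous=False)
        assert out["pair_id"].tolist() == ["E_F"]

    def test_key_significant_in_every_case_removed(self):
        rows = [
            (c, "A_B", "A", "B", "tumor->TME", "TAM", 0.001, 2.0)
            for c in ("c1", "c2", "c3")
        ]
        rows.append(("c1", "C_D", "C", "D", "tumor->TME", "TAM", 0.001, 2.0))
        out = filter_pairs(self._records(rows))
        assert set(out["pair_id"]) == {"C_D"}

    def test_same_pair_different_partners_retained(self):
        rows = [
            ("c1", "A_B", "A", "B", "tumor->TME", "TAM", 0.001, 2.0),
            ("c2", "A_B", "A", "B", "tumor->TME", "CAF", 0.001, 2.0),
        ]
        out = filter_pairs(self._records(rows))
        assert len(out) == 2

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(1)
        rows = [
            (
                f"c{rng.integers(3)}", f"P{rng.integers(6)}", "L", "R",
                "tumor->TME", "TAM", float(rng.random() * 0.02),
                float(rng.random() * 2),
            )
            for _ in range(60)
        ]
        rec = self._records(rows)
        cases = sorted(set(rec["sample_id"]))
        once = filter_pairs(rec, cases=cases)
        twice = filter_pairs(once, cases=cases)
        assert len(once) <= len(rec)
        pd.testing.assert_frame_equal(once, twice)


class TestStabilityAndOverlap:
    def test_regional_stability_proportions(self):
        rows = []
        for region in ("T1", "T2", "T3", "B"):
            rows.append(("A_B", "tumor->TME", "TAM", region))
        for region in ("T1", "T2", "T3"):
            rows.append(("C_D", "TME->tumor", "CAF", region))
        rec = pd.DataFrame(
            rows,
            columns=["pair_id", "direction", "partner_celltype", "region"],
        )
        out = regional_stability(rec, regions=["T1", "T2", "T3", "B"])
        got = out.set_index("pair_id")["proportion"]
        assert got["A_B"] == 1.0
        assert got["C_D"] == 0.75

    def test_overlap_identities(self):
        a = {("p1", "d", "t"), ("p2", "d", "t")}
        b = {("p3", "d", "t")}
        assert interaction_overlap(a, a) == 1.0
        assert interaction_overlap(a, b) == 0.0
        assert interaction_overlap(set(), set()) == 0.0
        assert interaction_overlap(
            {("p1", "d", "t")}, a | b | {("p4", "d", "t")}
        ) == 0.25

    def test_derangement_has_no_fixed_point(self):
        rng = np.random.default_rng(0)
        for n in (3, 4, 7):
            for _ in range(20):
                perm = _derangement(rng, n)
                assert not np.any(perm == np.arange(n))
                assert sorted(perm) == list(range(n))


@pytest.fixture(scope="module")
def switching_cohort():
    """Four cases with case-specific tumor ligands, receptors uniform."""
    pats = [f"P{i + 1}" for i in range(4)]
    pairs = [
        PlantedPair(
            f"LIG{k}", f"REC{k}", "TAM", (pats[k],), 2.5, "tumor_to_tme",
            partner_patients=(),
        )
        for k in range(4)
    ]
    cfg = ef.SimulationConfig(
        seed=11, n_patients=4, n_per_celltype=20,
        n_malignant_per_region=40, planted_pairs=pairs,
    )
    a = ef.simulate.generate_cohort(cfg)
    norm = ef.cells.qc_and_normalize(a, min_genes_per_cell=50)
    norm.obs["cell_type"] = np.where(
        norm.obs["true_malignant"], "malignant", norm.obs["true_type"]
    )
    db = _db([(f"LIG{k}", f"REC{k}") for k in range(4)])
    return norm, db


class TestSwitching:
    def test_exchangeable_cases_keep_matched_proportion_high(self):
        # identical generation across cases: chimeras look like originals
        cfg = ef.SimulationConfig(
            seed=21, n_patients=3, n_per_celltype=15,
            n_malignant_per_region=30,
        )
        a = ef.simulate.generate_cohort(cfg)
        norm = ef.cells.qc_and_normalize(a, min_genes_per_cell=50)
        norm.obs["cell_type"] = np.where(
            norm.obs["true_malignant"], "malignant", norm.obs["true_type"]
        )
        db = _db([("SPP1", "PTGER4"), ("LGALS9", "SLC1A5")])
        res, _ = switching_experiment(
            norm, db, n_shuffles=3, seed=5, n_permutations=300,
            partner_types=["TAM"],
        )
        assert res["matched_proportion"].mean() >= 0.9

    def test_patient_specific_ligands_decay_faster_under_tumor_switch(
        self, switching_cohort
    ):
        norm, db = switching_cohort
        res, summary = switching_experiment(
            norm, db, n_shuffles=5, seed=3, n_permutations=300,
            partner_types=["TAM"],
        )
        assert summary["mean_switch_tumor"] < summary["mean_switch_tme"]
        assert summary["p_tumor_decays_faster"] < 0.05
        # derangement contract: no chimera pairs a tumor with its own TME
        assert (res["tumor_case"] != res["tme_case"]).all()

    def test_too_few_cases_rejected(self):
        a = make_adata(
            np.ones((40, 3)),
            cell_types=["malignant"] * 20 + ["TAM"] * 20,
            patient=["P1"] * 20 + ["P2"] * 20,
        )
        with pytest.raises(ValueError):
            switching_experiment(a, _db([("g0", "g1")]), n_shuffles=2)


class TestSubsampling:
    def test_identity_subsample_and_monotone_trend(self, switching_cohort):
        norm, db = switching_cohort
        one_case = norm[norm.obs["patient"] == "P1"]
        res, means = subsample_accuracy(
            one_case, db, cell_counts=(160, 20, 10), n_reps=2, seed=9,
            n_permutations=300, partner_types=["TAM"],
        )
        n_mal = int((one_case.obs["cell_type"] == "malignant").sum())
        assert n_mal == 160
        assert means[160] == pytest.approx(1.0)
        assert means[10] <= means[160]

    def test_fixed_seed_reproducible(self, switching_cohort):
        norm, db = switching_cohort
        one_case = norm[norm.obs["patient"] == "P2"]
        kw = dict(
            cell_counts=(40, 10), n_reps=2, seed=4, n_permutations=200,
            partner_types=["TAM"],
        )
        r1, _ = subsample_accuracy(one_case, db, **kw)
        r2, _ = subsample_accuracy(one_case, db, **kw)
        pd.testing.assert_frame_equal(r1, r2)

    def test_oversized_count_skipped(self, switching_cohort):
        norm, db = switching_cohort
        one_case = norm[norm.obs["patient"] == "P1"]
        res, means = subsample_accuracy(
            one_case, db, cell_counts=(10_000, 20), n_reps=1, seed=2,
            n_permutations=200, partner_types=["TAM"],
        )
        assert set(res["n_cells"]) == {20}
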