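"""Carrier-phenotype regression, pathway filters, and the cohort comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecascade import (
    SimConfig,
    any_significant_filter,
    build_gene_sets,
    carrier_regression,
    cohort_compare,
    inflammation_filter,
    lipid_filter,
    phenotype_scan,
    simulate_cohort,
    thrombosis_filter,
)
from rarecascade.config import PlantedEffect, PlantedGene
from rarecascade.phenotypes import DegenerateFitWarning


class TestCarrierRegression:
    def test_beta_is_mean_difference(self):
        beta, p = carrier_regression([110, 130, 80, 90, 100], [1, 1, 0, 0, 0])
        assert beta == pytest.approx(30.0)
        assert 0 < p <= 1

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        y = rng.normal(50, 10, size=60)
        x = rng.random(60) < 0.3
        if not x.any() or x.all():
            x[:2] = [True, False]
        beta, p = carrier_regression(y, x)
        fit = sm.OLS(y, sm.add_constant(x.astype(float))).fit()
        assert beta == pytest.approx(fit.params[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    @given(
        data=st.lists(
            st.tuples(st.floats(-1e4, 1e4), st.booleans()), min_size=3, max_size=40
        ).filter(lambda d: 0 < sum(x for _, x in d) < len(d))
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_equals_group_mean_gap_always(self, data):
        y = np.array([v for v, _ in data])
        x = np.array([c for _, c in data])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            beta, _ = carrier_regression(y, x)
        assert beta == pytest.approx(y[x].mean() - y[~x].mean(), abs=1e-10)

    def test_constant_phenotype_degenerates_to_p_one(self):
        with pytest.warns(DegenerateFitWarning):
            beta, p = carrier_regression([5.0, 5.0, 5.0, 5.0], [1, 0, 1, 0])
        assert beta == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            carrier_regression([1.0, 2.0], [1, 1])

    def test_missing_values_dropped(self):
        beta, _ = carrier_regression([np.nan, 110.0, 130.0, 90.0], [1, 1, 0, 0])
        assert beta == pytest.approx(110.0 - (130.0 + 90.0) / 2)


def scan_rows(*rows):
    return pd.DataFrame(
        rows, columns=["gene", "set", "phenotype", "beta", "p", "n_carriers"]
    )


class TestFilters:
    def test_any_significant_boundary(self):
        res = scan_rows(
            ("A", "broad", "TC", 1.0, 0.049, 5),
            ("B", "broad", "TC", 1.0, 0.05, 5),
            ("LDLR", "broad", "LDL_C", 31.4, 0.013, 9),
        )
        assert any_significant_filter(res) == ["A", "LDLR"]

    def test_lipid_filter_direction_and_p(self):
        res = scan_rows(
            ("CABP1", "broad", "LDL_C", 73.87, 0.03, 5),
            ("TP53BP1", "strict", "LDL_C", -32.51, 0.1, 6),
            ("X", "broad", "LDL_C", 10.0, 0.07, 5),
        )
        kept = lipid_filter(res)
        assert list(kept["gene"]) == ["CABP1"]
        assert "broad:LDL_C" in kept.iloc[0]["driving"]

    def test_thrombosis_requires_joint_reduction(self):
        res = scan_rows(
            ("T1", "broad", "PT", -2.1, 0.01, 5),
            ("T1", "broad", "APTT", -3.0, 0.02, 5),
            ("FGB", "broad", "PT", 2.0, 0.01, 5),
            ("FGB", "broad", "APTT", 1.5, 0.01, 5),
            ("T3", "broad", "PT", -2.0, 0.01, 5),
            ("T3", "broad", "APTT", -1.0, 0.3, 5),
        )
        got = thrombosis_filter(res)
        assert got["thrombosis"] == ["T1"]
        assert got["bleeding"] == ["FGB"]

    def test_inflammation_pattern(self):
        klhl8 = [
            ("KLHL8", "broad", "fibrinogen", 9.94, 0.003, 6),
            ("KLHL8", "broad", "WBC", 4.91, 0.01, 6),
            ("KLHL8", "broad", "neutrophil_pct", 16.9, 0.04, 6),
            ("KLHL8", "broad", "monocyte_pct", -5.17, 0.002, 6),
        ]
        bad_monocyte = [
            ("M", "broad", "fibrinogen", 5.0, 0.01, 6),
            ("M", "broad", "WBC", 2.0, 0.01, 6),
            ("M", "broad", "neutrophil_pct", 3.0, 0.01, 6),
            ("M", "broad", "monocyte_pct", 2.0, 0.01, 6),
        ]
        weak_wbc = [
            ("W", "broad", "fibrinogen", 5.0, 0.01, 6),
            ("W", "broad", "WBC", 2.0, 0.2, 6),
            ("W", "broad", "neutrophil_pct", 3.0, 0.01, 6),
            ("W", "broad", "monocyte_pct", -1.0, 0.01, 6),
        ]
        res = scan_rows(*klhl8, *bad_monocyte, *weak_wbc)
        assert inflammation_filter(res, anchor="fibrinogen") == ["KLHL8"]

    def test_filters_return_subsets_and_are_idempotent(self):
        res = scan_rows(
            ("A", "broad", "LDL_C", 40.0, 0.01, 5),
            ("B", "broad", "LDL_C", -40.0, 0.01, 5),
        )
        kept = lipid_filter(res)
        again = lipid_filter(res[res["gene"].isin(kept["gene"])])
        assert list(again["gene"]) == list(kept["gene"])


class TestPhenotypeScan:
    def make(self, seed=31):
        cfg = SimConfig(
            n_cases=60, n_controls=60, n_genes=8,
            planted_burden_genes=[PlantedGene("CABP1", 0.3, 0.0)],
            planted_phenotype_effects=[PlantedEffect("CABP1", "LDL_C", 60.0)],
            seed=seed,
        )
        cohort = simulate_cohort(cfg)
        cells = build_gene_sets(cohort.annotations)
        return cohort, cells

    def test_planted_gene_has_largest_ldl_beta_in_most_replicates(self):
        wins = 0
        for s in range(20):
            cohort, cells = self.make(seed=600 + s)
            genes = sorted({g for g, _ in cells})
            scan = phenotype_scan(
                genes, cells, cohort.genotype_frame, cohort.phenotypes, cohort.case_mask
            )
            ldl = scan[scan["phenotype"] == "LDL_C"]
            if not ldl.empty and ldl.loc[ldl["beta"].idxmax(), "gene"] == "CABP1":
                wins += 1
        assert wins > 10

    def test_control_only_gene_yields_no_rows(self):
        cohort, cells = self.make()
        # restrict scan to a gene whose carriers are forced into controls only
        geno = cohort.genotype_frame.copy()
        gene = "GENE0000"
        ids = [v for v in geno.columns if v.startswith(gene)]
        geno.loc[cohort.case_mask, ids] = 0
        geno.loc[~cohort.case_mask, ids[0]] = 1
        scan = phenotype_scan(
            [gene], cells, geno, cohort.phenotypes, cohort.case_mask
        )
        assert scan.empty

    def test_rows_restricted_to_candidates(self):
        cohort, cells = self.make()
        scan = phenotype_scan(
            ["CABP1"], cells, cohort.genotype_frame, cohort.phenotypes, cohort.case_mask
        )
        assert set(scan["gene"]) == {"CABP1"}
        assert (scan["n_carriers"] >= 1).all()


class TestCohortCompare:
    def test_exact_wilcoxon_small_sets(self):
        pheno = pd.DataFrame({"m": [1, 2, 3, 4, 5, 6]},
                             index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["case"] * 3 + ["control"] * 3, index=pheno.index)
        out = cohort_compare(pheno, labels)
        assert out.loc[0, "p"] == pytest.approx(0.1)

    def test_symmetric_arms_give_p_one(self):
        pheno = pd.DataFrame({"m": [1, 4, 2, 3]}, index=list("abcd"))
        labels = pd.Series(["case", "case", "control", "control"], index=pheno.index)
        out = cohort_compare(pheno, labels)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_categorical_fisher_matches_carrier_example(self):
        idx = [f"s{i}" for i in range(194)]
        flag = ["yes"] * 5 + ["no"] * 87 + ["no"] * 102
        pheno = pd.DataFrame({"ACS": flag}, index=idx)
        labels = pd.Series(["case"] * 92 + ["control"] * 102, index=idx)
        out = cohort_compare(pheno, labels)
        row = out[out["type"] == "categorical"].iloc[0]
        # modal category is "no"; same 2x2 table as 5-carriers-vs-0
        assert row["p"] == pytest.approx(0.0226, abs=5e-5)

    def test_too_small_arm_rejected(self):
        pheno = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=list("abc"))
        labels = pd.Series(["case", "control", "control"], index=pheno.index)
        with pytest.raises(ValueError):
            cohort_compare(pheno, labels)
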