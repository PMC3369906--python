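"""Twin-cohort QC, pair-averaged encoding, GLS, and auxiliary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painscreen.errors import DataError
from painscreen.simulate import SimulationConfig, simulate_twin_cohort
from painscreen.twin import (
    TwinCohort,
    associate_snp,
    bonferroni,
    censored_max_rule,
    cohens_d,
    encode_units,
    gls_fit,
    hwe_test,
    impute_missing,
    ld_r2,
    quantile_normalize,
    snp_qc,
    welch_t,
)


def tiny_cohort(genotypes: dict, individuals: list) -> TwinCohort:
    ind = pd.DataFrame(
        individuals,
        columns=["individual_id", "pair_id", "zygosity", "sex"],
    )
    ind["heat_c"] = 46.0
    ind["cold_thresh_s"] = 20.0
    ind["cold_tol_s"] = 60.0
    ind["depression"] = 5.0
    geno = pd.DataFrame(genotypes).T
    geno.columns = ind["individual_id"]
    return TwinCohort(individuals=ind, genotypes=geno)


class TestHwe:
    def test_perfect_hwe_gives_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_departure_gives_tiny_p(self):
        assert hwe_test(100, 0, 100) < 1e-30

    def test_hand_computed_chi_square_case(self):
        # counts (50, 50, 0): allele freq 0.75 -> expected (56.25, 37.5, 6.25),
        # chi2 = 0.694 + 4.167 + 6.25 = 11.11, p(df=1) ~ 8.6e-4
        p = hwe_test(50, 50, 0)
        assert p == pytest.approx(stats.chi2.sf(11.111111, 1), rel=1e-4)
        assert p < 0.01

    def test_monomorphic_convention(self):
        assert hwe_test(40, 0, 0) == 1.0


class TestSnpQc:
    def test_filters_remove_exactly_the_designed_snps(self):
        # 20 individuals, 4 SNPs: one bad call rate, one zero MAF, one HWE
        # failure (the hand-computed chi2 ~ 11.1 case), one clean
        rng = np.random.default_rng(0)
        n = 100
        clean = rng.binomial(2, 0.4, n).astype(float)
        low_call = clean.copy()
        low_call[: int(0.15 * n)] = np.nan  # 85% call rate
        mono = np.zeros(n)
        hwe_bad = np.array([0.0] * 50 + [1.0] * 50)  # (50, 50, 0)
        individuals = [(f"i{k}", None, "NA", "M") for k in range(n)]
        cohort = tiny_cohort(
            {"clean": clean, "lowcall": low_call, "mono": mono, "hwebad": hwe_bad},
            individuals,
        )
        passing, report = snp_qc(cohort)
        assert passing == ["clean"]
        assert report.loc["lowcall", "removed_for"] == "call_rate"
        assert "maf" in report.loc["mono", "removed_for"]
        assert report.loc["hwebad", "removed_for"] == "hwe"
        assert report.loc["lowcall", "call_rate"] == pytest.approx(0.85)

    def test_hwe_uses_one_member_per_mz_pair(self):
        # duplicated MZ genomes would fake an HWE excess of homozygotes
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, 60).astype(float)
        individuals = []
        geno = []
        for k in range(60):
            individuals += [(f"p{k}_1", f"p{k}", "MZ", "F"), (f"p{k}_2", f"p{k}", "MZ", "F")]
            geno += [g[k], g[k]]
        cohort = tiny_cohort({"s": np.array(geno)}, individuals)
        _, report = snp_qc(cohort)
        n_aa = int((g == 0).sum()); n_ab = int((g == 1).sum()); n_bb = int((g == 2).sum())
        assert report.loc["s", "hwe_p"] == pytest.approx(hwe_test(n_aa, n_ab, n_bb))


class TestImpute:
    def test_missing_becomes_homozygous_wildtype(self):
        geno = pd.DataFrame([[0.0, 1.0, 2.0, np.nan]], index=["s"], columns=list("abcd"))
        completed, n_imp = impute_missing(geno)
        assert completed.loc["s"].tolist() == [0.0, 1.0, 2.0, 0.0]
        assert n_imp["s"] == 1

    def test_no_missing_unchanged(self):
        geno = pd.DataFrame([[0.0, 1.0]], index=["s"], columns=["a", "b"])
        completed, n_imp = impute_missing(geno)
        pd.testing.assert_frame_equal(completed, geno)
        assert n_imp["s"] == 0

    def test_mz_cotwin_rule_applied_verbatim_with_warning(self, caplog):
        individuals = [("a", "p1", "MZ", "M"), ("b", "p1", "MZ", "M")]
        cohort = tiny_cohort({"s": np.array([2.0, np.nan])}, individuals)
        with caplog.at_level("WARNING"):
            completed, _ = impute_missing(cohort.genotypes, cohort)
        assert completed.loc["s", "b"] == 0.0  # the stated rule, not the co-twin copy
        assert any("disagrees" in r.message for r in caplog.records)


class TestEncodeUnits:
    def cohort(self):
        individuals = [
            ("m1", "pA", "MZ", "M"), ("m2", "pA", "MZ", "M"),
            ("d1", "pB", "DZ", "M"), ("d2", "pB", "DZ", "F"),
            ("s1", None, "NA", "F"),
        ]
        return tiny_cohort(
            {"s": np.array([2.0, 2.0, 0.0, 1.0, 1.0])}, individuals
        )

    def test_paper_coding_examples(self):
        units, g_bar = encode_units(self.cohort(), "heat_c")
        mz = units.loc["pA"]
        assert g_bar.loc["s", "pA"] == 2.0
        assert mz["sex_code"] == -1.0
        assert mz["var_group"] == "MZ-M"
        dz = units.loc["pB"]
        assert g_bar.loc["s", "pB"] == 0.5
        assert dz["sex_code"] == 0.0
        assert dz["var_group"] == "DZ-mixed"
        single = units.loc["s1"]
        assert g_bar.loc["s", "s1"] == 1.0
        assert single["sex_code"] == 1.0
        assert single["var_group"] == "singleton-F"

    def test_transform_applied_before_averaging(self):
        c = self.cohort()
        c.individuals.loc[0, "cold_thresh_s"] = 10.0
        c.individuals.loc[1, "cold_thresh_s"] = 40.0
        units, _ = encode_units(c, "cold_thresh_s", transform="log")
        assert units.loc["pA", "y_bar"] == pytest.approx(
            (np.log(10) + np.log(40)) / 2
        )

    def test_ceiling_observation_excluded(self):
        c = self.cohort()
        c.individuals.loc[4, "cold_thresh_s"] = 180.0
        units, _ = encode_units(c, "cold_thresh_s", transform="log")
        assert "s1" not in units.index


class TestCensoredRule:
    def test_strict_equality_boundary(self):
        v = pd.Series([10.0, 179.9, 180.0])
        flagged = censored_max_rule(v)
        assert flagged.tolist() == [False, False, True]


class TestGls:
    def test_homoscedastic_reduction_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 80
        x = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n), rng.choice([-1.0, 1.0], n)])
        y = 1.0 + 0.4 * x[:, 1] + rng.normal(0, 1, n)
        beta, se, p, gv, _ = gls_fit(y, x, ["all"] * n)
        ols = sm.OLS(y, x).fit()
        assert beta == pytest.approx(ols.params, abs=1e-10)

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(3)
        n = 300
        groups = np.repeat(["a", "b", "c"], 100)
        sd = np.repeat([0.5, 1.0, 1.5], 100)
        g = rng.binomial(2, 0.3, n).astype(float)
        x = np.column_stack([np.ones(n), g])
        y = 2.0 + 0.5 * g + rng.normal(0, sd)
        beta, se, p, gv, _ = gls_fit(y, x, groups)
        assert beta[1] == pytest.approx(0.5, abs=3 * se[1])
        assert gv["a"] < gv["b"] < gv["c"]

    def test_permuted_genotype_pvalues_are_uniform(self):
        # calibration: with g randomly permuted, p-values must be null
        rng = np.random.default_rng(4)
        pvals = []
        n = 150
        groups = np.repeat(["a", "b", "c"], 50)
        sd = np.repeat([0.7, 1.0, 1.3], 50)
        for _ in range(200):
            g = rng.permutation(np.repeat([0.0, 1.0, 2.0], 50))
            x = np.column_stack([np.ones(n), g])
            y = 1.0 + rng.normal(0, sd)
            _, _, p, _, _ = gls_fit(y, x, groups)
            pvals.append(p[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_design_rejected(self):
        cfg = SimulationConfig(seed=9, n_pairs=20, n_snps=1, maf_vector=(0.3,))
        cohort, _ = simulate_twin_cohort(cfg)
        units, g_bar = encode_units(cohort, "heat_c")
        const = pd.Series(1.0, index=g_bar.columns)
        with pytest.raises(DataError):
            associate_snp(units, const, "snp", "heat_c")

    def test_small_variance_groups_are_merged(self):
        cfg = SimulationConfig(seed=10, n_pairs=60, n_snps=1, maf_vector=(0.3,),
                               singleton_fraction=0.02)
        cohort, _ = simulate_twin_cohort(cfg)
        units, g_bar = encode_units(cohort, "heat_c")
        res = associate_snp(units, g_bar.loc["rs000000"], "rs000000", "heat_c")
        # singleton groups of size 1 cannot keep their own variance
        assert all(
            v not in res.group_variances or units["var_group"].value_counts()[v] >= 2
            for v in ("singleton-M", "singleton-F")
        )


class TestBonferroni:
    def test_scales_and_clips(self):
        out = bonferroni([0.0001, 0.5, 0.001], m=207)
        assert out[0] == pytest.approx(0.0207)
        assert out[1] == 1.0
        assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)


class TestEffectSizes:
    def test_cohens_d_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_cohens_d_hand_formula(self):
        # means 2 vs 3, both variances 1 -> pooled SD 1 -> d = -1
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_cohens_d_unit_pooled_sd(self):
        a = np.array([1.0, 3.0]); b = np.array([0.0, 2.0])  # means 2, 1
        d = cohens_d(a, b)
        pooled = np.sqrt(((1) * a.var(ddof=1) + (1) * b.var(ddof=1)) / 2)
        assert d == pytest.approx(1.0 / pooled)

    def test_welch_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_equal_variance_equal_n_df_reduction(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = a + 0.3  # identical sample variance
        _, df, _ = welch_t(a, b)
        assert df == pytest.approx(2 * 20 - 2)

    def test_welch_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0]); b = np.array([10.0, 20.0, 30.0, 40.0])
        t, df, p = welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        t_hand = (a.mean() - b.mean()) / se
        df_hand = se**4 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3
        )
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))


class TestQuantileNormalize:
    def test_blom_scores_for_three_values(self):
        scores = quantile_normalize([5.0, 1.0, 3.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        assert scores == pytest.approx(expected)

    def test_order_preserving_and_centered(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=101)
        s = quantile_normalize(v)
        assert (np.argsort(s) == np.argsort(v)).all()
        assert abs(s.sum()) < 1e-8

    def test_all_tied_maps_to_zero(self):
        assert quantile_normalize([2.0, 2.0, 2.0]) == pytest.approx([0.0, 0.0, 0.0])


class TestLd:
    def test_self_and_duplicate_r2_is_one(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.4, 50).astype(float)
        individuals = [(f"i{k}", None, "NA", "M") for k in range(50)]
        cohort = tiny_cohort({"a": g, "b": g.copy(), "c": rng.binomial(2, 0.4, 50).astype(float)}, individuals)
        ld = ld_r2(cohort)
        assert ld.loc["a", "a"] == pytest.approx(1.0)
        assert ld.loc["a", "b"] == pytest.approx(1.0)  # perfect LD proxy
        assert 0 <= ld.loc["a", "c"] <= 1

    def test_independent_snps_have_near_zero_mean_r2(self):
        rng = np.random.default_rng(8)
        n = 500
        individuals = [(f"i{k}", None, "NA", "F") for k in range(n)]
        geno = {f"s{j}": rng.binomial(2, 0.3, n).astype(float) for j in range(8)}
        ld = ld_r2(tiny_cohort(geno, individuals))
        off = ld.to_numpy()[~np.eye(8, dtype=bool)]
        # E[r^2] under independence is ~ 1/(n-1)
        assert off.mean() == pytest.approx(1 / (n - 1), abs=3 / n)

    def test_monomorphic_snp_gets_missing_entries(self):
        individuals = [(f"i{k}", None, "NA", "M") for k in range(10)]
        g = np.arange(10) % 3 * 1.0
        cohort = tiny_cohort({"poly": g, "mono": np.ones(10)}, individuals)
        ld = ld_r2(cohort)
        assert np.isnan(ld.loc["poly", "mono"])
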