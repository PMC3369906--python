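"""The synthetic generators: determinism and the structure they promise."""

import numpy as np
import pandas as pd
import pytest

from painscreen.errors import ConfigError
from painscreen.rankprod import fold_change
from painscreen.screen import gene_index_correlation
from painscreen.simulate import (
    SimulationConfig,
    simulate_citations,
    simulate_expression_studies,
    simulate_fold_change_matrix,
    simulate_index,
    simulate_twin_cohort,
)
from painscreen.twin import hwe_test
from conftest import make_index


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_diseases": 1},
            {"missing_fraction": 1.0},
            {"n_planted_genes": 10, "n_genes": 5},
            {"pair_env_corr": 1.0},
            {"n_snps": 2, "maf_vector": (0.3,)},
            {"n_snps": 1, "maf_vector": (0.7,)},
            {"causal_snps": (5,), "n_snps": 2},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestCitations:
    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(seed=1, n_diseases=100)
        pd.testing.assert_frame_equal(simulate_citations(cfg), simulate_citations(cfg))

    def test_different_seed_differs(self):
        a = simulate_citations(SimulationConfig(seed=1, n_diseases=100))
        b = simulate_citations(SimulationConfig(seed=2, n_diseases=100))
        assert not a.equals(b)

    def test_forced_propensity_one_gives_all_ratio_one(self):
        cfg = SimulationConfig(seed=3, n_diseases=50, propensity_const=1.0)
        c = simulate_citations(cfg)
        assert (c["n_phenotype"] == c["n_total"]).all()

    def test_counts_are_valid_and_some_are_zero(self):
        c = simulate_citations(SimulationConfig(seed=4, n_diseases=300))
        assert (c["n_total"] >= 1).all()
        assert ((c["n_phenotype"] >= 0) & (c["n_phenotype"] <= c["n_total"])).all()
        assert (c["n_phenotype"] == 0).any()  # exercises the inclusion rule

    def test_mean_ratio_matches_closed_form_of_the_mixture(self):
        # oracle: E[n_phen/n_total] = E[propensity] of the zero-inflated Beta
        cfg = SimulationConfig(seed=7, n_diseases=1000)
        c = simulate_citations(cfg)
        ratios = c["n_phenotype"] / c["n_total"]
        mc_se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert ratios.mean() == pytest.approx(cfg.mean_ratio(), abs=3 * mc_se)


class TestExpression:
    def test_matrix_deterministic_and_missingness_near_nominal(self, index40):
        cfg = SimulationConfig(seed=5, n_genes=200, n_planted_genes=10)
        m1, r1 = simulate_fold_change_matrix(cfg, index40)
        m2, r2 = simulate_fold_change_matrix(cfg, index40)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(r1, r2)
        assert m1.isna().to_numpy().mean() == pytest.approx(0.10, abs=0.02)

    def test_slope_zero_makes_planted_and_null_exchangeable(self, index40):
        cfg = SimulationConfig(seed=6, n_genes=400, n_planted_genes=200,
                               planted_slope=0.0, missing_fraction=0.0)
        with pytest.warns(UserWarning):
            m, reg = simulate_fold_change_matrix(cfg, index40)
        planted = m.loc[reg["gene_id"]].to_numpy().ravel()
        null = m.drop(index=reg["gene_id"]).to_numpy().ravel()
        from scipy import stats

        assert stats.ks_2samp(planted, null).pvalue > 0.01

    def test_noiseless_planted_genes_are_perfectly_monotone(self, index40):
        cfg = SimulationConfig(seed=8, n_genes=50, n_planted_genes=25,
                               noise_sd=0.0, missing_fraction=0.0)
        m, reg = simulate_fold_change_matrix(cfg, index40)
        sc = gene_index_correlation(m.loc[reg["gene_id"]], index40)
        assert np.abs(sc["rho"]).to_numpy() == pytest.approx(1.0)
        signs = np.sign(sc["rho"].to_numpy())
        assert signs == pytest.approx(reg.set_index("gene_id").loc[sc.index, "sign"])

    def test_planted_genes_outcorrelate_null_at_snr_two(self, index40):
        cfg = SimulationConfig(seed=11, n_genes=500, n_planted_genes=25)
        m, reg = simulate_fold_change_matrix(cfg, index40)
        sc = gene_index_correlation(m, index40)
        planted = sc.loc[reg["gene_id"], "rho"].abs().mean()
        null = sc.drop(index=reg["gene_id"])["rho"].abs().mean()
        assert planted > null + 0.3

    def test_studies_embed_the_fold_changes(self, index20):
        cfg = SimulationConfig(seed=12, n_genes=60, n_planted_genes=30,
                               planted_slope=0.5, noise_sd=0.05, missing_fraction=0.0,
                               n_case=6, n_control=6)
        studies, reg = simulate_expression_studies(cfg, index20)
        assert set(studies) == set(index20.disease_ids)
        # estimated fold changes correlate with the index for planted genes
        fc = pd.DataFrame({d: fold_change(s) for d, s in studies.items()})[
            index20.disease_ids
        ]
        sc = gene_index_correlation(fc.loc[reg["gene_id"]], index20)
        assert np.abs(sc["rho"]).min() > 0.9


class TestTwinCohort:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=13, n_pairs=50)
        c1, t1 = simulate_twin_cohort(cfg)
        c2, t2 = simulate_twin_cohort(cfg)
        pd.testing.assert_frame_equal(c1.individuals, c2.individuals)
        pd.testing.assert_frame_equal(c1.genotypes, c2.genotypes)

    def test_mz_cotwins_share_genotypes_exactly(self):
        cfg = SimulationConfig(seed=14, n_pairs=80, n_snps=6)
        cohort, _ = simulate_twin_cohort(cfg)
        mz = cohort.individuals[cohort.individuals["zygosity"] == "MZ"]
        for pid, grp in mz.groupby("pair_id"):
            a, b = grp["individual_id"]
            assert cohort.genotypes[a].equals(cohort.genotypes[b])

    def test_dz_cotwin_dosage_correlation_near_half(self):
        cfg = SimulationConfig(seed=15, n_pairs=500, prop_mz=0.0, n_snps=4)
        cohort, _ = simulate_twin_cohort(cfg)
        dz = cohort.individuals[cohort.individuals["zygosity"] == "DZ"]
        first, second = [], []
        for pid, grp in dz.groupby("pair_id"):
            ids = grp["individual_id"].tolist()
            first.append(cohort.genotypes[ids[0]].to_numpy())
            second.append(cohort.genotypes[ids[1]].to_numpy())
        first, second = np.array(first), np.array(second)
        for j in range(4):
            r = np.corrcoef(first[:, j], second[:, j])[0, 1]
            assert r == pytest.approx(0.5, abs=0.1)

    def test_genotypes_consistent_with_hwe(self):
        # one member per pair across many replicates: HWE test should
        # almost never reject at 0.01
        pvals = []
        for s in range(20):
            cfg = SimulationConfig(seed=100 + s, n_pairs=150, n_snps=5)
            cohort, _ = simulate_twin_cohort(cfg)
            keep = cohort.one_per_mz_pair()
            geno = cohort.genotypes[keep]
            # also drop the second DZ twin
            firsts = cohort.individuals.groupby("pair_id")["individual_id"].first()
            geno = geno[[c for c in geno.columns if c in set(firsts)]]
            for snp in geno.index:
                g = geno.loc[snp].to_numpy()
                pvals.append(hwe_test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())))
        assert np.mean(np.array(pvals) >= 0.01) >= 0.95

    def test_sex_specific_effect_only_in_males(self):
        cfg = SimulationConfig(seed=16, n_pairs=800, n_snps=1, maf_vector=(0.4,),
                               beta_snp=1.0, sex_specific=True, pair_env_corr=0.0)
        cohort, truth = simulate_twin_cohort(cfg)
        ind = cohort.individuals
        g = cohort.genotypes.loc[truth["snp_id"].iloc[0]]
        y = ind.set_index("individual_id")["heat_c"]
        males = ind.loc[ind["sex"] == "M", "individual_id"]
        females = ind.loc[ind["sex"] == "F", "individual_id"]
        slope_m = np.polyfit(g[males], y[males], 1)[0]
        slope_f = np.polyfit(g[females], y[females], 1)[0]
        assert slope_m == pytest.approx(1.0, abs=0.25)
        assert slope_f == pytest.approx(0.0, abs=0.25)

    def test_singletons_generated_when_requested(self):
        cfg = SimulationConfig(seed=17, n_pairs=100, singleton_fraction=0.1)
        cohort, _ = simulate_twin_cohort(cfg)
        assert (cohort.individuals["pair_id"].isna()).sum() == 10


class TestIndexHelper:
    def test_simulate_index_round_trip(self):
        idx = simulate_index(SimulationConfig(seed=18, n_diseases=200))
        assert len(idx) > 0
        assert idx.midranks.sum() == pytest.approx(len(idx) * (len(idx) + 1) / 2)
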