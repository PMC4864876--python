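"""Synthetic-cohort generator: LD structure, Mendelian transmission,
liability calibration, training-GWAS noise model."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from polycog.errors import ConfigError
from polycog.simulate import (
    SimulationConfig,
    gwas_standard_error,
    liability_to_logodds_scale,
    make_cohort,
    make_reference_haplotypes,
    simulate_cad_architecture,
    simulate_gwas_sumstats,
    simulate_phenotypes,
)


def _hap_dosage_r2(haps, i, j):
    r = np.corrcoef(haps[:, i], haps[:, j])[0, 1]
    return r * r


class TestReferenceHaplotypes:
    def test_variant_count(self):
        cfg = SimulationConfig(n_blocks=4, snps_per_block=5, n_causal=3, seed=1)
        ref = make_reference_haplotypes(cfg)
        assert ref.n_variants == 20
        assert len(ref.variants) == 20

    def test_zero_rho_gives_independence(self):
        cfg = SimulationConfig(n_blocks=5, snps_per_block=8, within_block_rho=0.0,
                               n_causal=10, maf_low=0.2, seed=2)
        ref = make_reference_haplotypes(cfg, n_samples=1000)
        r2s = []
        for b in range(cfg.n_blocks):
            base = b * cfg.snps_per_block
            for k in range(cfg.snps_per_block - 1):
                r2s.append(_hap_dosage_r2(ref.haplotypes, base + k, base + k + 1))
        assert np.mean(r2s) < 0.05

    def test_perfect_rho_collapses_blocks(self):
        cfg = SimulationConfig(n_blocks=3, snps_per_block=6, within_block_rho=1.0,
                               n_causal=5, seed=3)
        ref = make_reference_haplotypes(cfg, n_samples=400)
        for b in range(cfg.n_blocks):
            base = b * cfg.snps_per_block
            for k in range(cfg.snps_per_block - 1):
                assert _hap_dosage_r2(ref.haplotypes, base + k, base + k + 1) == pytest.approx(1.0)

    def test_invalid_maf_bounds_rejected(self):
        with pytest.raises(ConfigError, match="MAF"):
            SimulationConfig(maf_low=0.3, maf_high=0.1)
        with pytest.raises(ConfigError, match="MAF"):
            SimulationConfig(maf_low=0.0)

    def test_draw_tags_share_variants_but_not_haplotypes(self):
        cfg = SimulationConfig(n_blocks=3, snps_per_block=4, n_causal=4, seed=9)
        a = make_reference_haplotypes(cfg, n_samples=50, draw_tag=0)
        b = make_reference_haplotypes(cfg, n_samples=50, draw_tag=1)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert not np.array_equal(a.haplotypes, b.haplotypes)


class TestCohort:
    def test_mendelian_expectation(self):
        # expected child dose given parents is the mid-parent dose
        cfg = SimulationConfig(n_blocks=6, snps_per_block=10, n_founder_couples=500,
                               offspring_per_couple=1, n_causal=20, seed=4)
        ref = make_reference_haplotypes(cfg)
        panel, ped = make_cohort(ref, cfg)
        idx = {s: i for i, s in enumerate(panel.samples)}
        kids = ped[ped["father"] != "0"]
        assert len(kids) >= 500
        dev = []
        for rec in kids.itertuples(index=False):
            child = panel.dosages[idx[rec.id]]
            mid = (panel.dosages[idx[rec.father]] + panel.dosages[idx[rec.mother]]) / 2
            dev.append(child - mid)
        dev = np.concatenate(dev)
        se = dev.std(ddof=1) / np.sqrt(dev.size)
        assert abs(dev.mean()) < 3 * se

    def test_no_offspring_means_no_parent_links(self):
        cfg = SimulationConfig(n_blocks=2, snps_per_block=5, n_founder_couples=20,
                               offspring_per_couple=0, n_causal=3, seed=5)
        ref = make_reference_haplotypes(cfg)
        panel, ped = make_cohort(ref, cfg)
        assert (ped["father"] == "0").all() and (ped["mother"] == "0").all()
        assert panel.n_samples == 40

    def test_same_seed_identical_outputs(self, small_cfg):
        ref = make_reference_haplotypes(small_cfg)
        p1, ped1 = make_cohort(ref, small_cfg)
        p2, ped2 = make_cohort(ref, small_cfg)
        assert np.array_equal(p1.dosages, p2.dosages)
        pd.testing.assert_frame_equal(ped1, ped2)

    def test_offspring_without_couples_rejected(self):
        cfg = SimulationConfig(n_blocks=2, snps_per_block=5, n_founder_couples=0,
                               offspring_per_couple=2, n_causal=3, seed=6)
        ref = make_reference_haplotypes(cfg, n_samples=20)
        with pytest.raises(ConfigError, match="founder couples"):
            make_cohort(ref, cfg)


class TestArchitecture:
    def test_zero_heritability_zero_effects(self, small_cohort, small_cfg):
        panel, _ = small_cohort
        eff = simulate_cad_architecture(panel, replace(small_cfg, h2_liability=0.0))
        assert (eff.betas == 0).all()

    def test_causal_count_capped(self, small_cohort, small_cfg):
        panel, _ = small_cohort
        with pytest.raises(ConfigError, match="n_causal"):
            simulate_cad_architecture(
                panel, replace(small_cfg, n_blocks=1000, n_causal=100000)
            )

    def test_liability_variance_transfers_across_cohorts(self):
        # effects scaled on one cohort must give ~h2 genetic variance on a
        # fresh cohort from the same population (within 10%)
        cfg = SimulationConfig(n_blocks=20, snps_per_block=10, n_founder_couples=2000,
                               offspring_per_couple=0, n_causal=100,
                               h2_liability=0.4, seed=7)
        ref_a = make_reference_haplotypes(cfg, draw_tag=0)
        ref_b = make_reference_haplotypes(cfg, draw_tag=1)
        panel_a, _ = make_cohort(ref_a, cfg)
        panel_b, _ = make_cohort(ref_b, cfg)
        eff = simulate_cad_architecture(panel_a, cfg)
        D = panel_b.dosages
        Z = (D - D.mean(0)) / D.std(0)
        g = Z @ eff.betas
        assert 0.36 <= g.var() <= 0.44


class TestGwasSumstats:
    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(n_blocks=100, snps_per_block=20, n_founder_couples=250,
                               offspring_per_couple=0, n_causal=0,
                               h2_liability=0.0, seed=8)
        ref = make_reference_haplotypes(cfg)
        panel, _ = make_cohort(ref, cfg)
        eff = simulate_cad_architecture(panel, cfg)
        ss = simulate_gwas_sumstats(eff, panel.allele_frequencies(), cfg,
                                    variants=panel.variants)
        assert len(ss) == 2000
        ks = stats.kstest(ss.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_noise_free_limit_preserves_ranking(self):
        cfg = SimulationConfig(n_blocks=6, snps_per_block=20, n_founder_couples=300,
                               offspring_per_couple=0, n_causal=120,
                               gwas_n=10**9, seed=9)
        ref = make_reference_haplotypes(cfg)
        panel, _ = make_cohort(ref, cfg)
        eff = simulate_cad_architecture(panel, cfg)
        ss = simulate_gwas_sumstats(eff, panel.allele_frequencies(), cfg,
                                    variants=panel.variants)
        rho = stats.spearmanr(np.abs(ss.table["log_or"]), np.abs(eff.betas)).statistic
        assert rho > 0.99

    def test_se_scales_inverse_sqrt_n(self):
        se1 = gwas_standard_error(0.3, 20000, 0.25)
        se4 = gwas_standard_error(0.3, 80000, 0.25)
        assert se1 / se4 == pytest.approx(2.0, rel=1e-12)

    def test_scale_constant_matches_closed_form(self):
        K = 0.25
        t = stats.norm.ppf(1 - K)
        assert liability_to_logodds_scale(K) == pytest.approx(
            stats.norm.pdf(t) / (K * (1 - K))
        )


class TestPhenotypes:
    def test_prevalence_matches_K(self):
        cfg = SimulationConfig(n_blocks=10, snps_per_block=12, n_founder_couples=1000,
                               offspring_per_couple=2, n_causal=40,
                               prevalence_K=0.25, seed=10)
        ref = make_reference_haplotypes(cfg)
        panel, ped = make_cohort(ref, cfg)
        eff = simulate_cad_architecture(panel, cfg)
        ph = simulate_phenotypes(panel, ped, eff, cfg)
        n = panel.n_samples
        assert n == 4000
        tol = 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(ph["CVD"].mean() - 0.25) <= tol

    def test_midparent_regression_recovers_h2_cog(self):
        cfg = SimulationConfig(n_blocks=12, snps_per_block=20, n_founder_couples=600,
                               offspring_per_couple=2, n_causal=60,
                               sigma_family=0.0, h2_cog=0.5, seed=11)
        ref = make_reference_haplotypes(cfg)
        panel, ped = make_cohort(ref, cfg)
        eff = simulate_cad_architecture(panel, cfg)
        ph = simulate_phenotypes(panel, ped, eff, cfg).set_index("sample_id")
        kids = ped[ped["father"] != "0"]
        mp, off = [], []
        for (f, m), grp in kids.groupby(["father", "mother"]):
            mp.append((ph.loc[f, "latent_factor"] + ph.loc[m, "latent_factor"]) / 2)
            off.append(ph.loc[grp["id"], "latent_factor"].mean())
        slope = np.polyfit(mp, off, 1)[0]
        assert abs(slope - cfg.h2_cog) <= 0.1

    def test_cog_architecture_orthogonal_to_disease(self, small_world):
        # r_g alone must control pleiotropy: the cognition-specific genetic
        # value is decorrelated from the disease genetic value
        panel = small_world["panel"]
        D = panel.dosages
        Z = (D - D.mean(0)) / np.where(D.std(0) == 0, 1, D.std(0))
        g_cad = Z @ small_world["effects"].betas
        g2 = Z @ small_world["cog_effects"].betas
        assert abs(np.corrcoef(g_cad, g2)[0, 1]) < 0.1

    def test_mismatched_samples_rejected(self, small_world):
        ped = small_world["pedigree"].iloc[::-1].reset_index(drop=True)
        with pytest.raises(ConfigError, match="samples"):
            simulate_phenotypes(
                small_world["panel"], ped, small_world["effects"], small_world["cfg"]
            )

    def test_deterministic_given_config(self, small_world):
        ph2 = simulate_phenotypes(
            small_world["panel"], small_world["pedigree"],
            small_world["effects"], small_world["cfg"],
            cog_effects=small_world["cog_effects"],
        )
        pd.testing.assert_frame_equal(small_world["phenotypes"], ph2)
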