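"""Generator checks: frequencies, LD structure, liability model, base stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from extremescan import simdata
from extremescan.prscore import ld_r2

from conftest import pairwise_r2


class TestGenotypes:
    def test_frequency_and_independence_at_rho_zero(self):
        spec = simdata.LDBlockSpec(n_variants=10, rho=0.0, freq_range=(0.3, 0.3))
        G = simdata.simulate_ld_genotypes([spec], 10_000, seed=1)
        freq = G.allele_freq()
        assert np.all(np.abs(freq - 0.3) < 0.02)
        r2 = pairwise_r2(G.dosage)
        off = r2[np.triu_indices_from(r2, k=1)]
        assert off.max() < 0.01

    def test_ar1_r2_decays_with_lag(self):
        spec = simdata.LDBlockSpec(n_variants=15, rho=0.9, freq_range=(0.2, 0.4))
        G = simdata.simulate_ld_genotypes([spec], 4000, seed=2)
        adjacent = np.mean([ld_r2(G, j, j + 1) for j in range(10)])
        lag5 = np.mean([ld_r2(G, j, j + 5) for j in range(10)])
        lag10 = np.mean([ld_r2(G, j, j + 10) for j in range(5)])
        assert adjacent > lag5 > lag10
        assert adjacent > 3 * lag10
        assert adjacent > 0.4

    def test_true_latent_r2_matches_empirical(self):
        spec = simdata.LDBlockSpec(n_variants=5, rho=0.8, freq_range=(0.3, 0.3))
        G = simdata.simulate_ld_genotypes([spec], 20_000, seed=3)
        expected = simdata.latent_ar1_r2(0.8, 1, 0.3, 0.3)
        observed = np.mean([ld_r2(G, j, j + 1) for j in range(4)])
        assert abs(observed - expected) < 0.05

    def test_determinism_and_seed_sensitivity(self):
        spec = simdata.LDBlockSpec(n_variants=10, rho=0.5)
        a = simdata.simulate_ld_genotypes([spec], 50, seed=9)
        b = simdata.simulate_ld_genotypes([spec], 50, seed=9)
        c = simdata.simulate_ld_genotypes([spec], 50, seed=10)
        assert np.array_equal(a.dosage, b.dosage)
        assert not np.array_equal(a.dosage, c.dosage)

    def test_positions_strictly_increase_and_bad_start_raises(self):
        specs = [simdata.LDBlockSpec(n_variants=5, chrom="1", start_bp=1000),
                 simdata.LDBlockSpec(n_variants=5, chrom="1", start_bp=500)]
        with pytest.raises(ValueError, match="non-increasing"):
            simdata.simulate_ld_genotypes(specs, 10, seed=0)
        G = simdata.simulate_ld_genotypes(
            [simdata.LDBlockSpec(n_variants=5, chrom="1"),
             simdata.LDBlockSpec(n_variants=5, chrom="1")], 10, seed=0)
        assert G.variants["pos"].is_monotonic_increasing

    @pytest.mark.parametrize("bad", [
        dict(n_variants=0), dict(rho=1.0), dict(rho=-0.1), dict(freq_range=(0.0, 0.5)),
        dict(freq_range=(0.1, 0.6)),
    ])
    def test_invalid_block_spec(self, bad):
        with pytest.raises(ValueError):
            simdata.LDBlockSpec(**{**dict(n_variants=5), **bad})


class TestLiabilityPhenotype:
    def test_prevalence_matches_target(self):
        blocks = [simdata.LDBlockSpec(n_variants=20, rho=0.5) for _ in range(5)]
        G = simdata.simulate_ld_genotypes(blocks, 20_000, seed=4)
        arch = simdata.ArchitectureSpec(n_causal=30, h2_liability=0.4, prevalence=0.05,
                                        seed=4)
        pheno = simdata.simulate_liability_phenotype(G, arch, n_pcs=0)
        assert abs(pheno.table["status"].mean() - 0.05) < 0.005

    def test_realized_h2_close_to_target(self):
        blocks = [simdata.LDBlockSpec(n_variants=20, rho=0.5) for _ in range(5)]
        G = simdata.simulate_ld_genotypes(blocks, 50_000, seed=5)
        arch = simdata.ArchitectureSpec(n_causal=40, h2_liability=0.3, seed=5)
        pheno = simdata.simulate_liability_phenotype(G, arch, n_pcs=0)
        assert abs(pheno.h2_realized - 0.3) < 0.02

    def test_null_h2_gives_uniform_association_p(self, null_cohort):
        arch = simdata.ArchitectureSpec(n_causal=50, h2_liability=0.0, seed=6)
        pheno = simdata.simulate_liability_phenotype(null_cohort, arch, n_pcs=0)
        y = pheno.table["status"].to_numpy(float)
        ps = []
        for j in range(null_cohort.n_variants):
            r, p = stats.pearsonr(null_cohort.dosage[:, j], y)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_covariates_present_and_pcs_from_genotypes(self, small_cohort):
        arch = simdata.ArchitectureSpec(n_causal=10, seed=7)
        pheno = simdata.simulate_liability_phenotype(small_cohort, arch)
        for col in ["sex", "year_of_birth", "deprivation", "batch", "PC1", "PC10"]:
            assert col in pheno.table.columns
        # PCs are orthogonal directions of the realized genotype matrix
        pcs = pheno.table[[f"PC{i}" for i in range(1, 11)]].to_numpy()
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.diag(gram).max()

    def test_bad_prevalence_rejected(self):
        with pytest.raises(ValueError):
            simdata.ArchitectureSpec(n_causal=1, prevalence=0.0)


@pytest.fixture(scope="module")
def panel():
    blocks = [simdata.LDBlockSpec(n_variants=20, rho=0.7) for _ in range(5)]
    return simdata.simulate_ld_genotypes(blocks, 2000, seed=8)


class TestBaseSumstats:

    def test_noise_off_limits(self, panel):
        null = simdata.ArchitectureSpec(n_causal=0, h2_liability=0.0, seed=1)
        ss0 = simdata.simulate_base_sumstats(panel, null, n_base=10_000, seed=1,
                                             noise=False)
        assert np.allclose(ss0["p"], 1.0)

        arch = simdata.ArchitectureSpec(n_causal=10, h2_liability=0.6, seed=2)
        ss = simdata.simulate_base_sumstats(panel, arch, n_base=10_000, seed=1,
                                            noise=False)
        causal, beta = simdata.draw_architecture(panel.n_variants, arch)
        # variants with a material drawn effect are overwhelmingly significant
        strong = causal[np.abs(beta) > 0.3 * np.abs(beta).max()]
        assert ss["p"].iloc[strong].max() < 1e-8

    def test_null_architecture_p_fraction(self, panel):
        null = simdata.ArchitectureSpec(n_causal=0, h2_liability=0.0, seed=3)
        blocks = [simdata.LDBlockSpec(n_variants=100, rho=0.0) for _ in range(50)]
        big = simdata.simulate_ld_genotypes(blocks, 300, seed=9)
        ss = simdata.simulate_base_sumstats(big, null, n_base=5000, seed=2)
        frac = (ss.loc[~ss["monomorphic"], "p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.01

    def test_se_scales_inverse_sqrt_n(self, panel):
        arch = simdata.ArchitectureSpec(n_causal=5, seed=4)
        s1 = simdata.simulate_base_sumstats(panel, arch, n_base=10_000, seed=3)
        s2 = simdata.simulate_base_sumstats(panel, arch, n_base=20_000, seed=3)
        ratio = np.nanmedian(s1["se"]) / np.nanmedian(s2["se"])
        assert ratio == pytest.approx(np.sqrt(2.0), rel=1e-6)

    def test_monomorphic_flagged(self):
        G = simdata.simulate_ld_genotypes(
            [simdata.LDBlockSpec(n_variants=5, freq_range=(0.01, 0.01))], 60, seed=10)
        G.dosage[:, 0] = 0.0
        arch = simdata.ArchitectureSpec(n_causal=1, seed=5)
        ss = simdata.simulate_base_sumstats(G, arch, n_base=1000, seed=4)
        assert bool(ss["monomorphic"].iloc[0])
        assert np.isnan(ss["se"].iloc[0])


class TestTraitsAndAnnotation:
    def _groups(self, n_per=1000):
        from extremescan.prscore import ExtremeGroups
        labels = np.array(["low"] * n_per + ["high"] * n_per, dtype=object)
        return ExtremeGroups([f"S{i}" for i in range(2 * n_per)], labels, 0.5, n_per)

    def test_binary_effect_recovered(self):
        import statsmodels.api as sm
        groups = self._groups(2000)
        table, manifest = simdata.simulate_trait_table(
            groups, [simdata.TraitSpec("t", "binary", effect=1.0)], seed=1)
        y = table["t"].to_numpy(float)
        x = (np.asarray(groups.labels) == "high").astype(float)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(fit.params[1] - 1.0) < 3 * fit.bse[1]

    def test_null_trait_uniform_p(self):
        groups = self._groups(250)
        ps = []
        for s in range(200):
            table, _ = simdata.simulate_trait_table(
                groups, [simdata.TraitSpec("t", "continuous", effect=0.0)], seed=s)
            x = (np.asarray(groups.labels) == "high").astype(float)
            ps.append(stats.ttest_ind(table["t"][x == 1], table["t"][x == 0]).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missingness_rate_and_manifest(self):
        groups = self._groups(2000)
        table, manifest = simdata.simulate_trait_table(
            groups, [simdata.TraitSpec("t", "continuous", missingness=0.25)], seed=2)
        assert abs(table["t"].isna().mean() - 0.25) < 0.03
        assert manifest.loc[0, "missingness"] == 0.25

    def test_effect_on_unassigned_only_rejected(self):
        from extremescan.prscore import ExtremeGroups
        labels = np.array(["unassigned"] * 10, dtype=object)
        groups = ExtremeGroups([f"S{i}" for i in range(10)], labels, 0.1, 0)
        with pytest.raises(ValueError):
            simdata.simulate_trait_table(
                groups, [simdata.TraitSpec("t", "continuous", effect=1.0)], seed=3)

    def test_annotation_tiling_and_determinism(self):
        span = [("1", 1, 2_000_000)]
        genes, catalog = simdata.simulate_annotation(span, 50, 5, seed=4)
        genes2, catalog2 = simdata.simulate_annotation(span, 50, 5, seed=4)
        pd.testing.assert_frame_equal(genes, genes2)
        assert catalog == catalog2
        assert len(genes) == 50
        # non-overlapping
        assert (genes["start_bp"].shift(-1).dropna().to_numpy()
                > genes["end_bp"].to_numpy()[:-1]).all()
        with pytest.raises(ValueError, match="too small"):
            simdata.simulate_annotation([("1", 1, 1000)], 50, 1, seed=4)
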