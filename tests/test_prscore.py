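"""C+T scoring: LD, greedy clumping vs oracle, region exclusion, extremes."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from extremescan import dataio, prscore, simdata
from extremescan.prscore import ClumpParams, assign_extremes, clump, exclude_region, ld_r2, score

from conftest import greedy_clump_oracle, make_matrix, pairwise_r2


class TestLdR2:
    def test_identical_and_flipped_columns(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 200).astype(float)
        G = make_matrix(np.column_stack([col, col, 2.0 - col]))
        assert ld_r2(G, 0, 1) == pytest.approx(1.0)
        assert ld_r2(G, 0, 2) == pytest.approx(1.0)  # r^2 ignores orientation
        assert ld_r2(G, 0, 0) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(1)
        G = make_matrix(rng.binomial(2, 0.3, size=(10_000, 2)).astype(float))
        assert ld_r2(G, 0, 1) < 0.01

    def test_monomorphic_returns_nan(self):
        G = make_matrix(np.column_stack([np.zeros(50), np.arange(50) % 3]))
        assert np.isnan(ld_r2(G, 0, 1))


def _aligned_frame(p, g_idx):
    return pd.DataFrame({"p": p, "beta": np.ones(len(p))},
                        index=pd.Index(g_idx, name="g_idx"))


class TestClump:
    def test_three_snp_hand_trace(self):
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, 500).astype(float)
        # SNP2 tightly linked to SNP1; SNP3 independent
        noisy = base.copy()
        flip = rng.random(500) < 0.05
        noisy[flip] = rng.binomial(2, 0.4, int(flip.sum()))
        indep = rng.binomial(2, 0.4, 500).astype(float)
        G = make_matrix(np.column_stack([base, noisy, indep]),
                        positions=[1000, 2000, 3000])
        assert ld_r2(G, 0, 1) > 0.5 and ld_r2(G, 0, 2) < 0.1
        ss = _aligned_frame([1e-10, 1e-8, 1e-4], [0, 1, 2])
        kept = clump(ss, G, ClumpParams(p_threshold=1.0, clump_r2=0.1, clump_kb=250))
        assert kept == [0, 2]

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(3)
        G = make_matrix(rng.binomial(2, 0.3, (2000, 8)).astype(float))
        p = rng.uniform(0.001, 0.04, 8)
        kept = clump(_aligned_frame(p, range(8)), G, ClumpParams())
        assert kept == list(range(8))

    def test_duplicate_variant_keeps_smaller_p(self):
        rng = np.random.default_rng(4)
        col = rng.binomial(2, 0.3, 300).astype(float)
        G = make_matrix(np.column_stack([col, col]), positions=[1000, 1100])
        kept = clump(_aligned_frame([1e-3, 1e-5], [0, 1]), G, ClumpParams())
        assert kept == [1]

    def test_empty_candidates_error(self):
        G = make_matrix(np.random.default_rng(5).binomial(2, 0.3, (50, 2)).astype(float))
        with pytest.raises(ValueError, match="pass p threshold"):
            clump(_aligned_frame([0.5, 0.9], [0, 1]), G, ClumpParams(p_threshold=0.05))

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_bruteforce_oracle_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = int(rng.integers(10, 50))
        blocks = [simdata.LDBlockSpec(n_variants=m // 2, rho=0.9, block_gap_bp=50_000),
                  simdata.LDBlockSpec(n_variants=m - m // 2, rho=0.9)]
        G = simdata.simulate_ld_genotypes(blocks, 400, seed=200 + trial)
        p = rng.uniform(0, 0.2, m)
        params = ClumpParams(p_threshold=0.1, clump_r2=0.2, clump_kb=30)
        kept = clump(_aligned_frame(p, range(m)), G, params)

        r2 = pairwise_r2(G.dosage)
        pos = G.variants["pos"].to_numpy()
        chrom = G.variants["chrom"].to_numpy()
        expect = [i for i in greedy_clump_oracle(p, chrom, pos, r2, 0.2, 30_000)
                  if p[i] < 0.1]
        assert sorted(kept) == sorted(expect)
        # retained-set validity: no pair violates the exclusion predicate
        for a in kept:
            for b in kept:
                if a < b and abs(pos[a] - pos[b]) <= 30_000:
                    assert r2[a, b] < 0.2


class TestExcludeRegion:
    def _df(self, positions, chrom="19"):
        return pd.DataFrame({"chrom": chrom, "pos": positions,
                             "p": np.linspace(0.01, 0.5, len(positions))})

    def test_fixed_window_inclusive_ends(self):
        df = self._df([45_236_728, 45_236_729, 45_500_000, 45_618_959, 45_618_960])
        out, n = exclude_region(df, "19", 45_236_729, 45_618_959)
        assert n == 3
        assert list(out["pos"]) == [45_236_728, 45_618_960]

    def test_anchor_radius_boundary(self):
        df = pd.DataFrame({
            "chrom": "19",
            "pos": [44_411_940, 44_411_941, 45_411_941, 46_411_941, 46_411_942],
            "p": [0.5, 0.5, 1e-300, 0.5, 0.5],
        })
        out, n = exclude_region(df, "19", anchor_locus=(45_000_000, 46_000_000),
                                radius_bp=1_000_000)
        assert n == 3
        assert list(out["pos"]) == [44_411_940, 46_411_942]

    def test_empty_region_is_identity(self):
        df = self._df([100, 200])
        out, n = exclude_region(df, "1", 1000, 2000)
        assert n == 0 and len(out) == 2

    def test_anchor_without_variants_errors(self):
        with pytest.raises(ValueError, match="no variants"):
            exclude_region(self._df([100]), "19", anchor_locus=(10**6, 2 * 10**6))


class TestScore:
    def test_single_variant_raw_and_rescaled(self):
        G = make_matrix(np.array([[0.0], [1.0], [2.0]]))
        w = pd.DataFrame({"beta": [1.0]}, index=[0])
        res = score(G, w)
        assert np.allclose(res.raw, [0, 1, 2])
        assert np.allclose(res.rescaled, [0, 0.5, 1])
        assert res.n_variants_used == 1

    def test_linearity_over_weight_partition(self, small_cohort):
        rng = np.random.default_rng(6)
        beta = rng.normal(size=20)
        idx = rng.choice(small_cohort.n_variants, 20, replace=False)
        w = pd.DataFrame({"beta": beta}, index=np.sort(idx))
        full = score(small_cohort, w, rescale=False)
        half1 = score(small_cohort, w.iloc[:10], rescale=False)
        half2 = score(small_cohort, w.iloc[10:], rescale=False)
        assert np.allclose(full.raw, half1.raw + half2.raw, atol=1e-9)

    def test_allele_flip_invariance_end_to_end(self, small_cohort):
        """Flipping allele labels + beta signs in the input file shifts raw
        scores by a constant and leaves rescaled scores and rankings alike."""
        G = small_cohort
        rng = np.random.default_rng(7)
        beta = rng.normal(size=G.n_variants)
        ss = pd.DataFrame({
            "chrom": G.variants["chrom"], "pos": G.variants["pos"],
            "id": G.variants["id"], "effect_allele": G.variants["a1"],
            "other_allele": G.variants["a2"], "beta": beta,
            "p": rng.uniform(size=G.n_variants),
        })
        flipped = ss.assign(effect_allele=ss["other_allele"],
                            other_allele=ss["effect_allele"], beta=-ss["beta"])
        w_a = dataio.apply_harmonization(ss, G, dataio.harmonize_alleles(ss, G))
        res_a = score(G, w_a)
        res_b = score(G, dataio.apply_harmonization(flipped, G,
                                                    dataio.harmonize_alleles(flipped, G)))
        # harmonization re-orients betas, so even raw scores agree
        assert np.allclose(res_a.raw, res_b.raw, atol=1e-6)
        assert np.allclose(res_a.rescaled, res_b.rescaled, atol=1e-6)
        assert np.array_equal(np.argsort(res_a.raw), np.argsort(res_b.raw))

    def test_sign_flip_column_shifts_raw_by_constant(self):
        G = make_matrix(np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]))
        w = pd.DataFrame({"beta": [0.5, -0.25]}, index=[0, 1])
        w_flip = pd.DataFrame({"beta": [-0.5, 0.25], "sign_flip": [True, True]},
                              index=[0, 1])
        a, b = score(G, w, rescale=False), score(G, w_flip, rescale=False)
        shift = b.raw - a.raw
        assert np.allclose(shift, shift[0])
        assert shift[0] == pytest.approx(-2 * (0.5 - 0.25))

    def test_missing_imputed_at_twice_frequency(self):
        d = np.array([[0.0], [1.0], [2.0], [np.nan]])
        G = make_matrix(d)
        res = score(G, pd.DataFrame({"beta": [1.0]}, index=[0]), rescale=False)
        assert res.raw[3] == pytest.approx(1.0)  # 2 * freq = mean dosage

    def test_degenerate_rescale(self, caplog):
        G = make_matrix(np.array([[1.0], [1.0]]))
        with caplog.at_level(logging.WARNING):
            res = score(G, pd.DataFrame({"beta": [1.0]}, index=[0]))
        assert np.allclose(res.rescaled, 0.5)
        assert "degenerate" in caplog.text


class TestEndToEndTails:
    def test_liability_gap_grows_with_heritability(self):
        """Tails of a score built from base effects separate liability, and
        the separation grows with the heritability of the architecture."""
        blocks = [simdata.LDBlockSpec(n_variants=20, rho=0.6) for _ in range(10)]
        G = simdata.simulate_ld_genotypes(blocks, 2000, seed=21)
        panel = simdata.simulate_ld_genotypes(blocks, 500, seed=22)
        gaps = []
        for h2 in (0.1, 0.3, 0.5):
            arch = simdata.ArchitectureSpec(n_causal=40, h2_liability=h2, seed=23)
            pheno = simdata.simulate_liability_phenotype(G, arch, n_pcs=0)
            ss = simdata.simulate_base_sumstats(panel, arch, n_base=50_000, seed=23)
            ss = ss[~ss["monomorphic"]].reset_index(drop=True)
            aligned = dataio.apply_harmonization(ss, G,
                                                 dataio.harmonize_alleles(ss, G))
            retained = clump(aligned, G, ClumpParams())
            prs = score(G, aligned.loc[aligned.index.intersection(retained)])
            g = assign_extremes(prs, 0.1)
            liab = pheno.table["liability"].to_numpy()
            gaps.append(liab[g.labels == "high"].mean()
                        - liab[g.labels == "low"].mean())
        assert gaps[0] > 0
        assert gaps[0] < gaps[1] < gaps[2]


class TestAssignExtremes:
    @pytest.mark.parametrize("N,q,k", [(377_834, 0.05, 18_892), (100, 0.05, 5),
                                       (11, 0.3, 4)])
    def test_ceil_rule(self, N, q, k):
        rng = np.random.default_rng(8)
        groups = assign_extremes(rng.normal(size=N), q)
        assert groups.k == k
        assert (groups.labels == "low").sum() == k
        assert (groups.labels == "high").sum() == k

    def test_tails_disjoint_and_ordered(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=1000)
        g = assign_extremes(s, 0.1)
        low, high = s[g.labels == "low"], s[g.labels == "high"]
        assert low.max() <= high.min()
        assert set(np.flatnonzero(g.labels == "low")).isdisjoint(
            np.flatnonzero(g.labels == "high"))

    def test_all_equal_scores_stable_order(self, caplog):
        with caplog.at_level(logging.WARNING):
            g = assign_extremes(np.zeros(10), 0.2)
        assert list(g.labels[:2]) == ["low", "low"]
        assert list(g.labels[-2:]) == ["high", "high"]
        assert "ties" in caplog.text

    def test_overlapping_tails_error(self):
        with pytest.raises(ValueError, match="q must be in"):
            assign_extremes(np.arange(10.0), 0.6)
        with pytest.raises(ValueError, match="overlap"):
            assign_extremes(np.arange(3.0), 0.45)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=200),
           st.floats(0.01, 0.49))
    def test_invariants_hold_for_arbitrary_scores(self, scores, q):
        import math
        N = len(scores)
        k = math.ceil(q * N)
        if 2 * k > N:
            return
        g = assign_extremes(np.asarray(scores), q)
        assert (g.labels == "low").sum() == (g.labels == "high").sum() == k
        s = np.asarray(scores)
        assert s[g.labels == "low"].max() <= s[g.labels == "high"].min()
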