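"""Shared fixtures: small synthetic cohorts and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from extremescan import simdata
from extremescan.dataio import GenotypeMatrix


def make_matrix(dosage: np.ndarray, positions=None, chrom="1", a1="A", a2="G",
                sample_prefix="S") -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.float32)
    n, m = dosage.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    variants = pd.DataFrame({
        "chrom": [chrom] * m if isinstance(chrom, str) else list(chrom),
        "pos": list(positions),
        "id": [f"v{j}" for j in range(m)],
        "a1": [a1] * m, "a2": [a2] * m,
    })
    return GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)], variants, dosage)


@pytest.fixture(scope="session")
def small_cohort() -> GenotypeMatrix:
    """500 samples x 100 variants in 5 AR(1) blocks (rho 0.8)."""
    blocks = [simdata.LDBlockSpec(n_variants=20, rho=0.8) for _ in range(5)]
    return simdata.simulate_ld_genotypes(blocks, 500, seed=11)


@pytest.fixture(scope="session")
def null_cohort() -> GenotypeMatrix:
    """2,000 samples x 300 independent variants (for calibration checks)."""
    blocks = [simdata.LDBlockSpec(n_variants=30, rho=0.0) for _ in range(10)]
    return simdata.simulate_ld_genotypes(blocks, 2000, seed=5)


# ---------------------------------------------------------------------------
# independent oracles (deliberately simple, quadratic implementations)
# ---------------------------------------------------------------------------

def pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """Full r^2 matrix via numpy.corrcoef (mean-imputing missing)."""
    d = np.asarray(dosage, dtype=float)
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d)
    sd = d.std(axis=0)
    d = d[:, sd > 0] if (sd == 0).any() else d
    r = np.corrcoef(d, rowvar=False)
    return r * r


def greedy_clump_oracle(p, chrom, pos, r2, r2_threshold, window_bp, max_p=1.0):
    """Reference greedy clumping: explicit loop over the sorted candidates."""
    order = sorted(range(len(p)), key=lambda i: (p[i], chrom[i], pos[i]))
    removed = set(i for i in range(len(p)) if p[i] >= max_p)
    kept = []
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        removed.add(i)
        for j in range(len(p)):
            if j in removed or chrom[j] != chrom[i]:
                continue
            if window_bp is not None and abs(pos[j] - pos[i]) > window_bp:
                continue
            if not np.isnan(r2[i, j]) and r2[i, j] >= r2_threshold:
                removed.add(j)
    return kept


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Full enumeration of het counts given fixed allele totals."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # one allele's total; test is symmetric
    probs = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        if hom_A < 0:
            continue
        # P(het | allele counts) = n! 2^het / (hom_A! het! hom_a!) * nA! na! / (2n)!
        logp = (
            math.lgamma(n + 1) - math.lgamma(hom_A + 1) - math.lgamma(het + 1)
            - math.lgamma(hom_a + 1) + het * math.log(2.0)
        )
        probs[het] = logp
    mx = max(probs.values())
    total = sum(math.exp(v - mx) for v in probs.values())
    p_obs = math.exp(probs[n_Aa] - mx)
    return min(1.0, sum(math.exp(v - mx) for v in probs.values()
                        if math.exp(v - mx) <= p_obs * (1 + 1e-12)) / total)


def hypergeom_oracle(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by direct enumeration with exact binomial coefficients."""
    denom = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / denom


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
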