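"""Synthetic cohorts with known ground truth.

Genotypes are simulated per LD block from a latent Gaussian AR(1) process:
each haplotype draws a latent vector with corr(z_i, z_j) = rho^|i-j| and
carries the alternate allele at variant ``j`` when the latent value falls
below the allele-frequency quantile.  This model was chosen because the true
haplotype correlation (and hence r^2 and LD scores) has a closed form, which
the oracle tests exploit.  Disease status follows a liability-threshold
model: a standardized polygenic score plus Gaussian noise, thresholded so
the expected prevalence matches the target.

A base GWAS is emulated analytically rather than by resampling genotypes:
the marginal (LD-smeared) effect of every variant is computed from a
reference panel, and Gaussian noise with the theoretical standard error
1/sqrt(2 N f (1-f)) is added.  This keeps the cost O(variants) while
producing summary statistics with realistic LD structure and winner's-curse
noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from extremescan._rng import child_rng
from extremescan.dataio import GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlockSpec:
    """One LD block of the synthetic genome.

    ``rho`` is the latent AR(1) correlation between adjacent variants (so the
    latent correlation at lag L is rho^L); ``freq_range`` is the interval the
    per-variant alternate-allele frequencies are drawn from; ``start_bp=None``
    places the block ``block_gap_bp`` after the previous block on the same
    chromosome.
    """

    n_variants: int
    rho: float = 0.0
    freq_range: tuple[float, float] = (0.05, 0.5)
    block_gap_bp: int = 100_000
    chrom: str = "1"
    start_bp: int | None = None
    spacing_bp: int = 1_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("freq_range must lie within (0, 0.5]")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Polygenic liability-threshold disease architecture.

    ``h2_liability`` is the fraction of liability variance explained by the
    causal variants; ``prevalence`` sets the liability threshold; per-causal
    effects are N(0, effect_dist_sd^2) before rescaling to ``h2_liability``.
    The ``seed`` pins the causal-set draw so a cohort phenotype and a base
    GWAS built on the same variant panel share their architecture.
    """

    n_causal: int
    h2_liability: float = 0.5
    prevalence: float = 0.1
    effect_dist_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError("h2_liability must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass(frozen=True)
class TraitSpec:
    """One synthetic phenome trait.

    ``kind`` is one of continuous/binary/ordered/unordered; ``effect`` is the
    group effect of high-vs-low extreme membership on the model scale of the
    trait (mean shift, log-OR, latent shift, or level-1 log-odds shift
    respectively); ``missingness`` is the MCAR missing rate.
    """

    name: str
    kind: str = "continuous"
    effect: float = 0.0
    missingness: float = 0.0
    n_levels: int = 4
    baseline: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "binary", "ordered", "unordered"}:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")


@dataclass(frozen=True)
class EnrichedSetSpec:
    """Gene set seeded at given genomic positions (typically causal loci)."""

    name: str = "seeded_set"
    positions: tuple = ()
    n_extra: int = 0


@dataclass
class PhenotypeTable:
    """Simulated phenotype with its ground truth.

    ``table`` holds status, liability and covariates per sample; ``causal``
    the causal variant indices with standardized and per-allele effects.
    """

    table: pd.DataFrame
    causal: pd.DataFrame
    threshold: float
    h2_realized: float


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def latent_ar1_r2(rho: float, lag: int, f_i: float, f_j: float) -> float:
    """True haplotype r^2 between two block variants under the AR(1) model.

    The haplotype alleles are indicators of a bivariate normal with
    correlation rho^lag falling below the frequency quantiles; r^2 follows
    from the bivariate-normal orthant probability.
    """
    r = rho ** lag
    if r > 1 - 1e-12:
        return 1.0
    ti, tj = stats.norm.ppf(f_i), stats.norm.ppf(f_j)
    joint = stats.multivariate_normal.cdf([ti, tj], mean=[0, 0], cov=[[1, r], [r, 1]])
    cov = joint - f_i * f_j
    return float(cov ** 2 / (f_i * (1 - f_i) * f_j * (1 - f_j)))


def _block_haplotypes(rng: np.random.Generator, n_hap: int, spec: LDBlockSpec,
                      freqs: np.ndarray) -> np.ndarray:
    m = spec.n_variants
    eps = rng.standard_normal((n_hap, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    c = np.sqrt(1.0 - spec.rho ** 2)
    for j in range(1, m):
        z[:, j] = spec.rho * z[:, j - 1] + c * eps[:, j]
    thresholds = stats.norm.ppf(freqs)
    return (z < thresholds).astype(np.int8)


def simulate_ld_genotypes(
    blocks: Sequence[LDBlockSpec], n_samples: int, seed: int
) -> GenotypeMatrix:
    """Draw a diploid dosage matrix from independent latent-AR(1) LD blocks.

    Each sample is the sum of two independent haplotypes.  Variant metadata
    records the target frequency and block index as ground truth.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not blocks:
        raise ValueError("need at least one LD block")
    rng = child_rng(seed, "genotypes")
    cursors: dict[str, int] = {}
    cols, rows = [], []
    vid = 0
    for b, spec in enumerate(blocks):
        cursor = cursors.get(spec.chrom, 0)
        start = spec.start_bp if spec.start_bp is not None else cursor + spec.block_gap_bp
        if start <= cursor:
            raise ValueError(
                f"block {b} on chromosome {spec.chrom} starts at {start} "
                f"<= previous end {cursor}: non-increasing positions"
            )
        freqs = rng.uniform(*spec.freq_range, size=spec.n_variants)
        hap1 = _block_haplotypes(rng, n_samples, spec, freqs)
        hap2 = _block_haplotypes(rng, n_samples, spec, freqs)
        cols.append((hap1 + hap2).astype(np.float32))
        for j in range(spec.n_variants):
            pos = start + j * spec.spacing_bp
            rows.append(dict(chrom=spec.chrom, pos=pos, id=f"sv{vid}", a1="A", a2="G",
                             true_freq=freqs[j], block=b))
            vid += 1
        cursors[spec.chrom] = start + (spec.n_variants - 1) * spec.spacing_bp
    variants = pd.DataFrame(rows)
    return GenotypeMatrix([f"S{i:06d}" for i in range(n_samples)], variants,
                          np.concatenate(cols, axis=1))


# ---------------------------------------------------------------------------
# architecture and phenotype
# ---------------------------------------------------------------------------

def draw_architecture(n_variants: int, arch: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Causal variant indices and raw (unscaled) standardized effects.

    Deterministic in ``(n_variants, arch)`` so phenotype simulation and base
    summary statistics on the same panel share one architecture.
    """
    if arch.n_causal > n_variants:
        raise ValueError("n_causal exceeds number of variants")
    rng = child_rng(arch.seed, "architecture")
    causal = np.sort(rng.choice(n_variants, size=arch.n_causal, replace=False))
    beta = rng.normal(0.0, arch.effect_dist_sd, size=arch.n_causal)
    return causal, beta


def _standardize(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute missing dosages, centre and unit-scale columns."""
    mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), mean, dosage)
    sd = filled.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (filled - mean) / safe, mean, sd


def simulate_liability_phenotype(
    G: GenotypeMatrix, arch: ArchitectureSpec, n_pcs: int = 10
) -> PhenotypeTable:
    """Liability-threshold disease status plus covariates for a cohort.

    Liability is the standardized polygenic score scaled to variance
    ``h2_liability`` plus N(0, 1 - h2) noise; status is liability above the
    normal quantile of ``1 - prevalence``.  Covariates mirror a typical
    biobank adjustment set: sex, year of birth, a deprivation index,
    genotyping batch, and the first ``n_pcs`` principal components computed
    from the realized genotype matrix (so PC adjustment is meaningful).
    """
    causal, beta_raw = draw_architecture(G.n_variants, arch)
    rng = child_rng(arch.seed, "phenotype")
    Z, _, sd = _standardize(G.dosage[:, causal]) if len(causal) else (
        np.zeros((G.n_samples, 0)), None, np.ones(0))
    g = Z @ beta_raw if len(causal) else np.zeros(G.n_samples)
    vg = g.var()
    h2 = arch.h2_liability
    scale = np.sqrt(h2 / vg) if (vg > 0 and h2 > 0) else 0.0
    genetic = g * scale
    eps = rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)) if scale > 0 else 1.0,
                     size=G.n_samples)
    liability = genetic + eps
    threshold = stats.norm.isf(arch.prevalence)
    status = (liability > threshold).astype(np.int8)

    vl = liability.var()
    h2_realized = float(genetic.var() / vl) if vl > 0 else 0.0

    table = pd.DataFrame({
        "sample_id": G.sample_ids,
        "status": status,
        "liability": liability,
        "sex": rng.integers(0, 2, G.n_samples),
        "year_of_birth": rng.integers(1940, 1971, G.n_samples),
        "deprivation": rng.normal(0.0, 1.0, G.n_samples),
        "batch": rng.integers(0, 10, G.n_samples),
    })
    for k, pc in enumerate(genotype_pcs(G, n_pcs, seed=arch.seed).T):
        table[f"PC{k + 1}"] = pc

    beta_std = beta_raw * scale
    causal_df = pd.DataFrame({
        "variant_idx": causal,
        "id": G.variants["id"].to_numpy()[causal],
        "beta_std": beta_std,
        "beta_allele": np.divide(beta_std, sd, out=np.zeros_like(beta_std), where=sd > 0),
    })
    return PhenotypeTable(table, causal_df, float(threshold), h2_realized)


def genotype_pcs(G: GenotypeMatrix, n_pcs: int = 10, seed: int = 0) -> np.ndarray:
    """Principal components of the standardized genotype matrix (n x n_pcs)."""
    if n_pcs == 0:
        return np.zeros((G.n_samples, 0))
    from scipy.sparse.linalg import svds

    Z, _, _ = _standardize(G.dosage)
    k = min(n_pcs, min(Z.shape) - 1)
    u, s, _ = svds(Z.astype(np.float64), k=k,
                   v0=child_rng(seed, "pca").standard_normal(min(Z.shape)))
    order = np.argsort(s)[::-1]
    pcs = (u * s)[:, order]
    if k < n_pcs:
        pcs = np.pad(pcs, ((0, 0), (0, n_pcs - k)))
    return pcs


# ---------------------------------------------------------------------------
# base summary statistics
# ---------------------------------------------------------------------------

def simulate_base_sumstats(
    G_panel: GenotypeMatrix,
    arch: ArchitectureSpec,
    n_base: int,
    seed: int,
    noise: bool = True,
) -> pd.DataFrame:
    """Emulate an external base GWAS on the panel's variant set.

    The marginal effect of variant j is sum_k r_jk * beta_k over the causal
    set, with correlations r taken from the reference panel; the reported
    estimate adds N(0, SE^2) noise with SE = 1/sqrt(2 n_base f (1-f)).
    Monomorphic variants are emitted with missing statistics and flagged.
    """
    if n_base < 100:
        raise ValueError("n_base must be >= 100")
    causal, beta_raw = draw_architecture(G_panel.n_variants, arch)
    rng = child_rng(seed, "base_sumstats")

    Z, mean, sd = _standardize(G_panel.dosage)
    n = G_panel.n_samples
    h2 = arch.h2_liability
    if len(causal) and h2 > 0:
        vg = (Z[:, causal] @ beta_raw).var()
        scale = np.sqrt(h2 / vg) if vg > 0 else 0.0
    else:
        scale = 0.0
    beta_std = beta_raw * scale
    # LD smear: corr(j, k) over the panel; blocks are independent so distant
    # entries are O(1/sqrt(n)) noise, which a finite panel would also carry.
    if len(causal):
        R = Z.T @ Z[:, causal] / n
        marginal_std = R @ beta_std
    else:
        marginal_std = np.zeros(G_panel.n_variants)

    freq = mean / 2.0
    het = 2.0 * freq * (1.0 - freq)
    poly = het > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_allele = np.where(poly, marginal_std / np.sqrt(het), np.nan)
        se = np.where(poly, 1.0 / np.sqrt(n_base * het), np.nan)
    est = beta_allele.copy()
    if noise:
        est[poly] = est[poly] + rng.normal(0.0, se[poly])
    with np.errstate(invalid="ignore"):
        z = np.where(poly, est / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(poly, np.clip(p, 1e-300, 1.0), np.nan)

    out = pd.DataFrame({
        "chrom": G_panel.variants["chrom"],
        "pos": G_panel.variants["pos"],
        "id": G_panel.variants["id"],
        "effect_allele": G_panel.variants["a1"],
        "other_allele": G_panel.variants["a2"],
        "beta": est,
        "se": se,
        "p": p,
        "freq": freq,
        "n": n_base,
        "monomorphic": ~poly,
    })
    n_mono = int((~poly).sum())
    if n_mono:
        log.warning("%d monomorphic panel variants emitted with missing stats", n_mono)
    return out


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def simulate_trait_table(
    groups,
    trait_specs: Sequence[TraitSpec],
    missingness: float = 0.0,
    seed: int = 0,
):
    """Mixed-type phenome table over the assigned extreme-group samples.

    Traits are generated with the declared association against high-vs-low
    membership and missingness is injected completely at random (a spec-level
    rate overrides the global ``missingness``... the larger of the two is not
    taken: the per-spec value wins when non-zero).  The returned manifest
    records the ground-truth type, effect and missing rate per trait.
    Declaring a non-zero effect when the group object contains no assigned
    samples is an error.
    """
    labels = np.asarray(groups.labels)
    assigned = labels != "unassigned"
    if not assigned.any():
        if any(s.effect != 0 for s in trait_specs):
            raise ValueError("non-zero trait effect declared but no samples are assigned to groups")
        raise ValueError("no assigned samples")
    sample_ids = np.asarray(groups.sample_ids)[assigned]
    x = (labels[assigned] == "high").astype(float)
    rng = child_rng(seed, "traits")
    n = len(x)

    values: dict[str, np.ndarray] = {}
    for spec in trait_specs:
        if spec.kind == "continuous":
            v = spec.effect * x + rng.normal(0.0, 1.0, n)
        elif spec.kind == "binary":
            logit = np.log(spec.baseline / (1 - spec.baseline)) + spec.effect * x
            v = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))).astype(float)
        elif spec.kind == "ordered":
            latent = spec.effect * x + rng.normal(0.0, 1.0, n)
            cuts = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            v = np.searchsorted(cuts, latent).astype(float)
        else:  # unordered
            logits = np.zeros((n, spec.n_levels))
            logits[:, 1] = spec.effect * x
            pmat = np.exp(logits)
            pmat /= pmat.sum(axis=1, keepdims=True)
            draws = np.array([rng.choice(spec.n_levels, p=row) for row in pmat])
            v = draws.astype(object)
        rate = spec.missingness if spec.missingness > 0 else missingness
        if rate > 0:
            mask = rng.random(n) < rate
            v = np.asarray(v, dtype=object if spec.kind == "unordered" else float)
            v[mask] = np.nan
        if spec.kind == "unordered":
            v = np.array([f"cat{int(e)}" if not (isinstance(e, float) and np.isnan(e)) else np.nan
                          for e in v], dtype=object)
        values[spec.name] = v

    table = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"))
    manifest = pd.DataFrame({
        "trait": [s.name for s in trait_specs],
        "type": [s.kind for s in trait_specs],
        "effect": [s.effect for s in trait_specs],
        "missingness": [s.missingness if s.missingness > 0 else missingness for s in trait_specs],
    })
    return table, manifest


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    chrom_span: Sequence[tuple[str, int, int]],
    n_genes: int,
    n_sets: int,
    enriched_set_spec: EnrichedSetSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Tile non-overlapping genes over chromosome spans and draw gene sets.

    One designated enriched set (if requested) contains the genes nearest to
    the given positions plus random extras; the remaining sets are uniform
    draws, so the enriched set is the only one with built-in signal.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = child_rng(seed, "annotation")
    total = sum(end - start for _, start, end in chrom_span)
    slot = total // n_genes
    if slot < 200:
        raise ValueError("chromosome span too small for requested gene count")
    gene_len = max(int(slot * 0.6), 100)
    rows = []
    g = 0
    for chrom, start, end in chrom_span:
        n_here = (end - start) // slot
        for i in range(n_here):
            if g >= n_genes:
                break
            s = start + i * slot
            rows.append(dict(id=f"GENE{g:04d}", chrom=str(chrom), start_bp=s,
                             end_bp=s + gene_len - 1))
            g += 1
    genes = pd.DataFrame(rows)
    if len(genes) < n_genes:
        raise ValueError("chromosome span too small for requested gene count")

    all_ids = genes["id"].tolist()
    catalog: dict[str, list[str]] = {}
    if enriched_set_spec is not None:
        members: list[str] = []
        for chrom, pos in enriched_set_spec.positions:
            sub = genes[genes["chrom"] == str(chrom)]
            if sub.empty:
                continue
            mid = (sub["start_bp"] + sub["end_bp"]) / 2
            members.append(sub["id"].iloc[int(np.argmin(np.abs(mid - pos)))])
        members = list(dict.fromkeys(members))
        extra_pool = [i for i in all_ids if i not in members]
        if enriched_set_spec.n_extra:
            members += list(rng.choice(extra_pool, size=min(enriched_set_spec.n_extra,
                                                            len(extra_pool)), replace=False))
        catalog[enriched_set_spec.name] = members
    for s in range(n_sets):
        size = int(rng.integers(5, max(6, min(30, n_genes // 2))))
        catalog[f"SET{s:03d}"] = list(rng.choice(all_ids, size=min(size, n_genes), replace=False))
    return genes, catalog
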