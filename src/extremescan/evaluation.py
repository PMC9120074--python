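"""Simulation studies that characterise the extremes design.

Each function builds its own synthetic inputs with :mod:`extremescan.simdata`,
runs the relevant pipeline stages and returns the measured quantities.  They
are the package's calibration/benchmark suite: null calibration of the
extremes GWAS, the inflation a polygenic architecture induces over
score-included variants, the power advantage of the extremes design over an
equal-size case-control design, LD-score-regression parameter recovery, the
phenome-scan family-wise error rate, and a closed worked example comparing a
logistic fit to the 2x2 allele-table odds ratio.

Problem sizes are desk-scale analogues of the design's study conditions
(thousands of samples, thousands of variants in block LD) chosen so the whole
suite runs on a laptop; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from extremescan import assoc, dataio, ldsc, phewas as phewas_mod, prscore, simdata
from extremescan._rng import child_rng


def _standard_blocks(n_blocks: int, variants_per_block: int, rho: float = 0.8):
    return [simdata.LDBlockSpec(n_variants=variants_per_block, rho=rho)
            for _ in range(n_blocks)]


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_variants: int = 10_000, samples_per_tail: int = 2000,
                     variants_per_block: int = 50, rho: float = 0.0) -> dict:
    """Extremes GWAS under a null (h2 = 0) architecture.

    With zero heritability the liability is pure noise, so tail groups drawn
    from it are independent of every genotype and the association scan must
    be calibrated: uniform p-values and lambda ~ 1.  (Tails of a
    genotype-built score would *not* be a null for the score's own variants —
    that mechanical enrichment is the design's point and is measured by
    :func:`polygenic_inflation` instead.)  The default cohort uses
    independent variants: LD cannot affect the calibration of marginal
    tests, and independence keeps the KS uniformity check exact and the
    Monte-Carlo error of the median-based lambda as small as the variant
    count allows.
    """
    n_samples = 4 * samples_per_tail
    blocks = _standard_blocks(n_variants // variants_per_block, variants_per_block, rho)
    G = simdata.simulate_ld_genotypes(blocks, n_samples, seed=seed)
    arch = simdata.ArchitectureSpec(n_causal=0, h2_liability=0.0, seed=seed)
    pheno = simdata.simulate_liability_phenotype(G, arch, n_pcs=0)
    groups = prscore.assign_extremes(pheno.table["liability"].to_numpy(), q=0.25,
                                     sample_ids=G.sample_ids)
    run = assoc.run_gwas(G, groups, covariates=None, qc=assoc.QCParams(0.01, 1e-15, 0.05))
    p = run.records.loc[run.records["status"] == "ok", "p"].to_numpy()
    ks_p = float(stats.kstest(p, "uniform").pvalue)
    return dict(lambda_gc=float(run.lambda_gc), ks_p=ks_p, n_tested=int(len(p)),
                type1_at_05=float((p < 0.05).mean()))


# ---------------------------------------------------------------------------
# polygenic inflation over score-included variants
# ---------------------------------------------------------------------------

def polygenic_inflation(seed: int, n_samples: int = 10_000, n_variants: int = 5000,
                        n_causal: int = 500, h2: float = 0.5, tail_q: float = 0.05,
                        n_panel: int = 800, n_base: int = 100_000) -> dict:
    """Genomic inflation of the extremes GWAS restricted to PRS variants.

    Runs the full chain — base summary statistics from a reference panel,
    C+T clumping, scoring, tail assignment — then associates only the
    score-included variants between the tails.  Because the groups are
    separated *by* those variants, the median test statistic is far above
    its null, which is the qualitative signature the design expects.
    """
    blocks = _standard_blocks(n_variants // 50, 50)
    G = simdata.simulate_ld_genotypes(blocks, n_samples, seed=seed)
    panel = simdata.simulate_ld_genotypes(blocks, n_panel, seed=seed + 1)
    arch = simdata.ArchitectureSpec(n_causal=n_causal, h2_liability=h2, seed=seed)
    ss = simdata.simulate_base_sumstats(panel, arch, n_base=n_base, seed=seed)
    ss = ss[~ss["monomorphic"]].reset_index(drop=True)

    pair = dataio.harmonize_alleles(ss, G)
    aligned = dataio.apply_harmonization(ss, G, pair)
    retained = prscore.clump(aligned, G, prscore.ClumpParams())
    weights = aligned.loc[aligned.index.intersection(retained)]
    prs = prscore.score(G, weights)
    groups = prscore.assign_extremes(prs, tail_q)

    G_prs = G.take_variants(np.asarray(sorted(weights.index)))
    labels = prscore.ExtremeGroups(groups.sample_ids, groups.labels, groups.q, groups.k)
    run = assoc.run_gwas(G_prs, labels, covariates=None,
                         qc=assoc.QCParams(0.01, 1e-15, 0.05))
    return dict(lambda_gc=float(run.lambda_gc), n_prs_variants=int(len(weights)),
                tail_k=int(groups.k))


# ---------------------------------------------------------------------------
# extremes vs case-control power
# ---------------------------------------------------------------------------

def power_comparison(seed: int, n_seeds: int = 50, n_samples: int = 6000,
                     per_arm: int = 1000) -> dict:
    """Median chi-square of a sub-significant causal variant: extremes design
    vs an equal-size random case-control design.

    Per replicate a fresh cohort (200 variants in block LD, 50 causal,
    h2 = 0.5, prevalence 0.2) and base study are simulated; the focal variant
    is the causal variant with the smallest base p that misses genome-wide
    significance while passing the score's p < 0.05 inclusion rule.  Both
    designs test 2 x ``per_arm`` samples: the score tails, and a random draw
    of ``per_arm`` cases plus ``per_arm`` controls.
    """
    chi2_ext, chi2_cc = [], []
    r = -1
    while len(chi2_ext) < n_seeds and (r := r + 1) < 2 * n_seeds:
        s = int(child_rng(seed, "power", r).integers(0, 2**31 - 1))
        blocks = _standard_blocks(20, 10)
        G = simdata.simulate_ld_genotypes(blocks, n_samples, seed=s)
        panel = simdata.simulate_ld_genotypes(blocks, 600, seed=s + 1)
        arch = simdata.ArchitectureSpec(n_causal=50, h2_liability=0.5, prevalence=0.2,
                                        seed=s)
        pheno = simdata.simulate_liability_phenotype(G, arch, n_pcs=0)
        ss = simdata.simulate_base_sumstats(panel, arch, n_base=2000, seed=s)
        ss = ss[~ss["monomorphic"]].reset_index(drop=True)

        causal_ids = set(pheno.causal["id"])
        sub = ss[(ss["id"].isin(causal_ids)) & (ss["p"] > 5e-8) & (ss["p"] < 0.05)]
        if sub.empty:
            continue
        focal_id = sub.loc[sub["p"].idxmin(), "id"]
        focal = int(np.flatnonzero(G.variants["id"] == focal_id)[0])

        pair = dataio.harmonize_alleles(ss, G)
        aligned = dataio.apply_harmonization(ss, G, pair)
        retained = prscore.clump(aligned, G, prscore.ClumpParams())
        prs = prscore.score(G, aligned.loc[aligned.index.intersection(retained)])
        groups = prscore.assign_extremes(prs, q=per_arm / n_samples)
        low, high = groups.index("low"), groups.index("high")
        d = G.dosage[:, focal]
        y = np.r_[np.zeros(len(low)), np.ones(len(high))]
        rec = assoc.logistic_assoc(np.r_[d[low], d[high]], y)
        if rec.status == "ok":
            chi2_ext.append((rec.beta / rec.se) ** 2)

        status = pheno.table["status"].to_numpy()
        rng = child_rng(s, "casecontrol")
        cases = rng.choice(np.flatnonzero(status == 1), per_arm, replace=False)
        ctrls = rng.choice(np.flatnonzero(status == 0), per_arm, replace=False)
        rec_cc = assoc.logistic_assoc(np.r_[d[ctrls], d[cases]], y)
        if rec_cc.status == "ok":
            chi2_cc.append((rec_cc.beta / rec_cc.se) ** 2)
    return dict(median_chi2_extremes=float(np.median(chi2_ext)),
                median_chi2_casecontrol=float(np.median(chi2_cc)),
                n_replicates=min(len(chi2_ext), len(chi2_cc)))


# ---------------------------------------------------------------------------
# LD score regression recovery
# ---------------------------------------------------------------------------

def ldsc_recovery(seed: int, n_reps: int = 20, M: int = 5000, N: int = 20_000,
                  h2: float = 0.3, n_panel: int = 500) -> dict:
    """Heritability recovery under the LD-score model, plus self-rg.

    LD scores come from an AR(1)-block panel; per replicate, z-scores are
    drawn with variance 1 + N*h2*l_j/M (the model's null-intercept form) and
    h2 is re-estimated.  Reports the replicate mean, mean jackknife SE and
    the genetic correlation of a trait with itself.
    """
    panel = simdata.simulate_ld_genotypes(_standard_blocks(M // 50, 50), n_panel,
                                          seed=seed)
    lds = ldsc.ld_scores(panel)
    l2 = lds["l2"].to_numpy()
    rng = child_rng(seed, "ldsc_reps")
    estimates, ses = [], []
    z = None
    for _ in range(n_reps):
        z = rng.standard_normal(len(l2)) * np.sqrt(1.0 + N * h2 * l2 / len(l2))
        est = ldsc.h2_regression(z ** 2, N, lds)
        estimates.append(est.h2)
        ses.append(est.se_h2)
    rg_self = ldsc.rg_regression(z, z, N, N, lds)
    return dict(h2_true=h2, h2_mean=float(np.mean(estimates)),
                se_mean=float(np.mean(ses)), n_reps=n_reps,
                rg_self=float(rg_self.rg))


# ---------------------------------------------------------------------------
# phenome scan: FWER and effect recovery
# ---------------------------------------------------------------------------

def phewas_null_fwer(seed: int, n_replicates: int = 200, n_traits: int = 30,
                     per_tail: int = 500, alpha: float = 0.05) -> dict:
    """Family-wise error of the Bonferroni-corrected scan on all-null traits."""
    labels = np.array(["low"] * per_tail + ["high"] * per_tail, dtype=object)
    groups = prscore.ExtremeGroups([f"S{i}" for i in range(2 * per_tail)], labels,
                                   q=0.5, k=per_tail)
    specs = [simdata.TraitSpec(f"null{i}", "continuous" if i % 2 else "binary",
                               effect=0.0) for i in range(n_traits)]
    hits = 0
    for r in range(n_replicates):
        s = int(child_rng(seed, "fwer", r).integers(0, 2**31 - 1))
        traits, manifest = simdata.simulate_trait_table(groups, specs, seed=s)
        scan = phewas_mod.phewas_scan(groups, traits, manifest=manifest,
                                      min_category=20, alpha=alpha)
        hits += int(scan.records["passes_bonferroni"].any())
    return dict(fwer=hits / n_replicates, n_replicates=n_replicates, alpha=alpha)


def phewas_effect_recovery(seed: int, per_tail: int = 2000, log_or: float = 1.0) -> dict:
    """Recovery of a known binary-trait group effect (log-odds scale)."""
    labels = np.array(["low"] * per_tail + ["high"] * per_tail, dtype=object)
    groups = prscore.ExtremeGroups([f"S{i}" for i in range(2 * per_tail)], labels,
                                   q=0.5, k=per_tail)
    traits, manifest = simdata.simulate_trait_table(
        groups, [simdata.TraitSpec("t", "binary", effect=log_or)], seed=seed)
    scan = phewas_mod.phewas_scan(groups, traits, manifest=manifest, min_category=20)
    row = scan.records.iloc[0]
    return dict(beta=float(row["beta"]), se=float(row["se"]), true=log_or,
                z_error=float(abs(row["beta"] - log_or) / row["se"]))


# ---------------------------------------------------------------------------
# worked example: rare-variant frequencies between tails
# ---------------------------------------------------------------------------

def rare_variant_or_example(freq_high: float = 4.9e-3, freq_low: float = 2.2e-3,
                            n_per_group: int = 18_892) -> dict:
    """Logistic OR vs the 2x2 allele-table OR for tail frequency difference.

    Builds the Hardy-Weinberg-expected genotype table for an effect-allele
    frequency in the high tail roughly twice that in the low tail (the
    situation of a rare risk variant enriched among high-score individuals)
    and compares the logistic-regression odds ratio with the allele-count
    odds ratio.
    """
    def hwe_counts(f: float, n: int) -> tuple[int, int, int]:
        n_hom = int(round(n * f * f))
        n_het = int(round(n * 2 * f * (1 - f)))
        return n_hom, n_het, n - n_hom - n_het

    dosage, y = [], []
    alleles = {}
    for grp, f in (("low", freq_low), ("high", freq_high)):
        n_hom, n_het, n_ref = hwe_counts(f, n_per_group)
        dosage += [2.0] * n_hom + [1.0] * n_het + [0.0] * n_ref
        y += [1.0 if grp == "high" else 0.0] * n_per_group
        alleles[grp] = 2 * n_hom + n_het
    rec = assoc.logistic_assoc(np.asarray(dosage), np.asarray(y))
    tot = 2 * n_per_group
    allele_or = (alleles["high"] / (tot - alleles["high"])) / (alleles["low"] / (tot - alleles["low"]))
    return dict(logistic_or=float(rec.or_), allele_or=float(allele_or),
                p=float(rec.p), n=2 * n_per_group,
                rel_diff=float(abs(rec.or_ - allele_or) / allele_or))
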