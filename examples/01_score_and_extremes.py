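"""Build a C+T polygenic score and assign the 5% tails.

Simulates a small cohort with block LD and a polygenic disease, emulates an
external base GWAS, clumps and scores, then assigns extreme groups.  The
printed numbers are the variant counts surviving each stage and the tail
size k = ceil(q * N).
"""

import numpy as np

from extremescan import dataio, prscore, simdata

blocks = [simdata.LDBlockSpec(n_variants=25, rho=0.8) for _ in range(40)]
cohort = simdata.simulate_ld_genotypes(blocks, n_samples=2000, seed=1)
panel = simdata.simulate_ld_genotypes(blocks, n_samples=500, seed=2)
arch = simdata.ArchitectureSpec(n_causal=50, h2_liability=0.5, prevalence=0.1, seed=1)
sumstats = simdata.simulate_base_sumstats(panel, arch, n_base=50_000, seed=1)
sumstats = sumstats[~sumstats["monomorphic"]].reset_index(drop=True)

pair = dataio.harmonize_alleles(sumstats, cohort)
aligned = dataio.apply_harmonization(sumstats, cohort, pair)
print(f"harmonized variants: {len(pair)} (dropped {len(pair.dropped)})")

retained = prscore.clump(aligned, cohort, prscore.ClumpParams(p_threshold=0.05))
print(f"variants after clumping at p<0.05: {len(retained)}")

weights = aligned.loc[aligned.index.intersection(retained)]
prs = prscore.score(cohort, weights)
groups = prscore.assign_extremes(prs, q=0.05)
print(f"tail size k = ceil(0.05 * {cohort.n_samples}) = {groups.k} per tail")
print(f"rescaled score range: [{prs.rescaled.min():.3f}, {prs.rescaled.max():.3f}]")

# the high tail should carry more disease liability than the low tail
pheno = simdata.simulate_liability_phenotype(cohort, arch, n_pcs=0)
liab = pheno.table["liability"].to_numpy()
print(f"mean liability, high vs low tail: "
      f"{liab[groups.index('high')].mean():+.3f} vs {liab[groups.index('low')].mean():+.3f}")
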