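"""LD score regression: heritability and genetic correlation.

Computes LD scores from a reference panel, estimates SNP-heritability from
model-consistent z-scores, and the genetic correlation between two traits
constructed to share half their genetic covariance.  Also reruns the
heritability fit with a dominant region excised, the standard robustness
check when one locus dominates a trait.
"""

import numpy as np

from extremescan import ldsc, simdata
from extremescan._rng import child_rng

panel = simdata.simulate_ld_genotypes(
    [simdata.LDBlockSpec(n_variants=50, rho=0.8) for _ in range(40)], 500, seed=1)
scores = ldsc.ld_scores(panel, window_kb=1000)
l2 = scores["l2"].to_numpy()
M, N, h2 = len(l2), 20_000, 0.3
print(f"LD scores: M={M}, mean l2 = {l2.mean():.2f}")

rng = child_rng(1, "example")
z1 = rng.standard_normal(M) * np.sqrt(1 + N * h2 * l2 / M)
est = ldsc.h2_regression(z1 ** 2, N, scores)
print(f"h2 estimate: {est.h2:.3f} (true 0.30), intercept {est.intercept:.3f}, "
      f"jackknife se {est.se_h2:.3f}")

# two traits sharing half their genetic covariance
rho_g = 0.5
v = 1 + N * h2 * l2 / M
cov = N * rho_g * h2 * l2 / M
z2 = cov / v * z1 + rng.standard_normal(M) * np.sqrt(v - cov ** 2 / v)
rg = ldsc.rg_regression(z1, z2, N, N, scores)
print(f"genetic correlation rg = {rg.rg:.3f} (constructed 0.50), se {rg.se_rg:.3f}")

full, without, n_removed = ldsc.region_exclude_rerun(
    scores.assign(z=z1), "1", 1, int(scores["pos"].quantile(0.1)))
est_wo = ldsc.h2_regression(without["z"] ** 2, N, without)
print(f"excluding {n_removed} variants in the region: h2 {est.h2:.3f} -> {est_wo.h2:.3f}")
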