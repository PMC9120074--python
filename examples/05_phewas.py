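"""Phenome-wide scan of extreme-group membership.

Generates a mixed-type trait table (two traits genuinely associated with the
high tail, one over-missing trait, the rest null) and scans every trait
against group membership with Bonferroni family-wise control.  The printed
report shows which traits pass the threshold and the |beta| >= 0.5
magnitude filter.
"""

import numpy as np

from extremescan import phewas, simdata
from extremescan.prscore import ExtremeGroups

per_tail = 1000
labels = np.array(["low"] * per_tail + ["high"] * per_tail, dtype=object)
groups = ExtremeGroups([f"S{i}" for i in range(2 * per_tail)], labels, 0.5, per_tail)

specs = [
    simdata.TraitSpec("family_history", "binary", effect=1.2),
    simdata.TraitSpec("symptom_score", "continuous", effect=0.6),
    simdata.TraitSpec("poorly_recorded", "continuous", effect=0.0, missingness=0.3),
] + [simdata.TraitSpec(f"null_trait_{i}", "continuous") for i in range(20)]
traits, manifest = simdata.simulate_trait_table(groups, specs, seed=1)

scan = phewas.phewas_scan(groups, traits, manifest=manifest, min_category=200,
                          max_missing=0.20, alpha=0.05)
print(f"performed {scan.n_tests} tests; Bonferroni threshold "
      f"{scan.threshold:.2e} = 0.05/{scan.n_tests}")
hits = scan.records[scan.records["passes_bonferroni"]]
print(hits[["trait", "type", "beta", "ci_low", "ci_high", "p"]].to_string(index=False))
excluded = scan.records[scan.records["status"] != "tested"]
print("excluded:", dict(zip(excluded["trait"], excluded["status"])))
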