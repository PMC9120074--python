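"""Run the extremes GWAS, measure inflation, and define risk loci.

Continues the scoring example: the score tails become pseudo case/control
groups, every QC-passing variant is tested by covariate-adjusted logistic
regression, and genome-wide significant signals are organised into
independent significant SNPs, lead SNPs and merged genomic risk loci.
Because the groups were separated *by* a genotype-built score, the genomic
inflation factor lambda is expected to be far above 1 — that is the design's
signature, not a defect.
"""

from extremescan import assoc, dataio, loci, prscore, simdata

blocks = [simdata.LDBlockSpec(n_variants=25, rho=0.8) for _ in range(40)]
cohort = simdata.simulate_ld_genotypes(blocks, n_samples=2000, seed=1)
panel = simdata.simulate_ld_genotypes(blocks, n_samples=500, seed=2)
arch = simdata.ArchitectureSpec(n_causal=50, h2_liability=0.5, prevalence=0.1, seed=1)
sumstats = simdata.simulate_base_sumstats(panel, arch, n_base=50_000, seed=1)
sumstats = sumstats[~sumstats["monomorphic"]].reset_index(drop=True)

aligned = dataio.apply_harmonization(sumstats, cohort,
                                     dataio.harmonize_alleles(sumstats, cohort))
retained = prscore.clump(aligned, cohort, prscore.ClumpParams())
prs = prscore.score(cohort, aligned.loc[aligned.index.intersection(retained)])
groups = prscore.assign_extremes(prs, q=0.1)

pheno = simdata.simulate_liability_phenotype(cohort, arch)
covars = pheno.table.set_index("sample_id").drop(columns=["status", "liability"])
run = assoc.run_gwas(cohort, groups, covariates=covars,
                     qc=assoc.QCParams.gwas_stage())
ok = run.records[run.records["status"] == "ok"]
print(f"tested {len(ok)} variants between {run.n_cases} high and "
      f"{run.n_controls} low individuals")
print(f"genomic inflation lambda = {run.lambda_gc:.3f} (inflation is expected here)")

params = loci.LocusParams()
ind = loci.independent_significant(run, cohort, params)
leads, risk_loci = loci.lead_and_loci(ind, run, cohort, params)
print(f"independent significant SNPs: {len(ind)}; lead SNPs: {len(leads)}; "
      f"genomic risk loci: {len(risk_loci)}")
if len(risk_loci):
    top = risk_loci.iloc[0]
    print(f"locus 1: chr{top.chrom}:{top.start_bp}-{top.end_bp}, "
          f"top SNP {top.top_snp} (p={top.top_p:.2e})")
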