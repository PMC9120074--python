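# extremescan

**GWAS of polygenic-score extremes** — a phenotype-agnostic association design,
implemented as a tested Python library with a synthetic-cohort generator.

## The problem

Case-control GWAS of late-onset diseases is limited by how many well
characterised cases a biobank contains.  An alternative is to drop the
clinical phenotype entirely: build a polygenic risk score (PRS) for every
individual from an external *base* GWAS, take the top and bottom tails of the
score distribution, and run a GWAS *between the tails*.  Selecting on the
score enriches both tails for risk alleles of the same phenotype, so variants
too weak to reach significance in the base study can surface — at the price
of strong, *expected*, genomic inflation, because the tested groups were
separated by genotype in the first place.

`extremescan` implements that design end to end:

1. **C+T scoring** (`prscore`) — greedy LD clumping of base summary
   statistics (index variants by ascending p, pruning neighbours within a
   window at r² ≥ threshold), score
   `PRS_i = Σ_j β_j d_ij`, optional exclusion of a dominant locus
   (±1 Mb around its top signal, or a fixed window), min–max rescaling for
   display, and tail assignment with `k = ceil(q·N)` per tail.
2. **Extremes GWAS** (`assoc`) — per-variant QC (MAF, Hardy–Weinberg exact
   test, missingness), maximum-likelihood logistic regression (IRLS) of
   high-vs-low membership on dosage plus covariates with the Wald test, and
   the genomic inflation factor `λ = median(χ²)/0.4549`.
3. **Risk loci** (`loci`) — the three-tier clumping hierarchy: independent
   significant SNPs (r² 0.6), lead SNPs (r² 0.1), loci merged at ≤ 250 kb;
   nearest-gene labels; classification of loci against the base study's
   reported variants (±500 kb flanks).
4. **Enrichment** (`enrich`) — positional gene mapping (±10 kb) and the
   one-sided hypergeometric overlap test with Benjamini–Hochberg FDR.
5. **LD score regression** (`ldsc`) — LD scores with the small-sample
   adjustment `r²_adj = r² − (1−r²)/(n−2)`, two-pass weighted regression of
   χ² on ℓ for SNP-heritability (`E[χ²] = 1 + Na + Nh²ℓ/M`), cross-trait
   genetic correlation from z-score products, block-jackknife SEs.
6. **PheWAS** (`phewas`) — typed scan of a mixed trait table (linear /
   logistic / proportional-odds / one-vs-rest) against group membership with
   Bonferroni control, missingness (>20%) and category-size (<200) filters.
7. **Synthetic cohorts** (`simdata`) — block-LD genotypes from a latent
   Gaussian AR(1) model (true r² has a closed form), a liability-threshold
   disease, analytically emulated base summary statistics, gene/gene-set
   annotations and mixed-type trait tables — all with ground truth, so every
   stage above is testable.

`pipeline.run_pipeline` chains all stages from one config (YAML-loadable) and
writes TSV outputs plus a JSON run manifest; the `extremescan` CLI wraps it
(`extremescan run --config cfg.yaml`, plus `clump`, `score`, `gwas`
subcommands).

## Worked example

`examples/` contains one short script per capability.  For instance,
`python examples/02_extremes_gwas_and_loci.py` simulates a 2,000-sample
cohort (1,000 variants, 50 causal, liability h² = 0.5), scores it against an
emulated base study, and runs the GWAS between the 10% tails:

```
tested 996 variants between 200 high and 200 low individuals
genomic inflation lambda = 2.607 (inflation is expected here)
independent significant SNPs: 14; lead SNPs: 10; genomic risk loci: 6
locus 1: chr1:1092000-1092000, top SNP sv200 (p=3.09e-16)
```

The λ far above 1 is the design's signature — the tails were separated *by*
the score, so score-correlated variants genuinely differ between them.  The
locus list is the FUMA-style summary of where those differences cluster.

Other examples: `01` scoring and tail assignment, `03` gene-set enrichment
(the generator's seeded set ranks first), `04` heritability and genetic
correlation by LD score regression, `05` the PheWAS with its filters, `06`
the full pipeline with and without a dominant-locus exclusion.

## Layout

```
src/extremescan/    simdata, dataio, prscore, assoc, loci, enrich, ldsc,
                    phewas, pipeline, evaluation, cli
examples/           one narrative script per capability
tests/              unit + property tests, plus test_acceptance.py
docs/methods.md     model assumptions, parameter choices, limitations
```
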