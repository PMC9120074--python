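# Methods

This note records the models the package implements, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical choices that were genuinely open.

## The design

The analysis treats extreme polygenic risk as a surrogate phenotype.  A
clumping+thresholding (C+T) score is built for every cohort member from
external base-GWAS summary statistics; the top and bottom `q` tails of the
score distribution become pseudo case/control groups; a covariate-adjusted
logistic GWAS between the tails, locus definition, gene-set enrichment,
LD-score genetic correlation and a phenome scan characterise what separates
them.  Variants found this way are associated with *polygenic risk* of the
phenotype, not necessarily with the phenotype itself; the package never uses
the score to predict disease status.

## Scoring and tails

* **Clumping** is the greedy index-SNP algorithm: candidates sorted by
  ascending p (ties by chromosome, position); each index removes
  not-yet-clumped variants within ±`clump_kb` whose r² with it reaches
  `clump_r2`.  Defaults `clump_kb=250`, `clump_r2=0.1`, `clump_p=1` are the
  conventional C+T tool defaults; the score-inclusion threshold is
  `p_threshold=0.05`.  All four are configurable and logged.
* **Tail size** is `k = ceil(q·N)` per tail (at `q=0.05`, `N=377,834` this
  gives 18,892; floor would give 18,891).  Boundary ties are resolved by
  stable sample order, with a warning.
* **Missing dosages** are mean-imputed as `2·f` from the cohort itself; the
  documented alternative (drop-and-renormalise) is off by default.
* **Min–max rescaling** of the score is display-only; group assignment and
  all statistics use raw scores.
* **Dominant-locus exclusion** supports both conventions: an anchor mode
  (±1 Mb around the most significant variant in a named window — the
  scoring-stage convention) and a fixed window (the correlation-stage
  convention, e.g. 19:45236729–45618959 on GRCh37 for APOE).  Region ends
  are inclusive.

## Association and QC

* Two QC presets reflect the two stages of the design: scoring-stage
  (MAF ≥ 0.1%, HWE exact p > 1e-15, missingness < 1%) and GWAS-stage
  (MAF ≥ 5%, HWE p ≥ 1e-6, missingness ≤ 1%).  HWE genotype counts come
  from rounding dosages; the test is the standard conditional exact test
  (probabilities accumulated over heterozygote counts no more probable than
  observed, computed by the mode-anchored recurrence so biobank-scale counts
  neither under- nor overflow).  HWE is evaluated on the combined two-tail
  sample by default.
* The per-variant model is maximum-likelihood logistic regression
  (Newton/IRLS, relative log-likelihood tolerance 1e-8, 100 iterations),
  Wald test on the dosage coefficient, 95% CI as `exp(β ± 1.96·se)`.
  Separation is declared at |β| > 20 or non-convergence and reported as a
  status, not an estimate.  The engine is an in-package IRLS because the
  genome scan calls it once per variant; tests verify it against
  statsmodels' independent optimiser to 1e-6.
* `λ = median(χ²)/χ²₀.₅(1)` with `χ² = F⁻¹(1−p; 1)` over ok-status tests.

### Calibration nulls and expected inflation

Two distinct regimes matter and are easy to conflate:

* Under a **null architecture** (h² = 0) with groups drawn from the
  (genotype-free) liability, every variant is independent of group
  membership: p-values must be uniform and λ ≈ 1.  This is the package's
  calibration null.  The calibration cohort uses LD-free variants — LD
  cannot change the calibration of marginal tests, and independence keeps
  the KS uniformity check exact and the Monte-Carlo error of the
  median-based λ minimal.  The default uses 10,000 variants and 2,000
  samples per tail, where λ's Monte-Carlo standard error is ≈ 0.02.
* Tails selected on a **genotype-built score** are mechanically associated
  with the score's variants even under h² = 0, and strongly so under a
  polygenic architecture.  λ well above 1 over score-included variants is
  therefore the design's expected signature, not confounding; the
  benchmark (`evaluation.polygenic_inflation`, h² = 0.5, 500 causal
  variants) measures it directly.

## Loci

Three-tier hierarchy with defaults `sig_p=5e-8`, `cand_p=0.05`,
`r2_independent=0.6`, `r2_lead=0.1`, `merge_kb=250`: greedy clump of
significant SNPs at r² 0.6 (chromosome-wide window — only LD separates
independent signals), a second clump of the survivors at r² 0.1 for leads,
envelopes from candidate SNPs (p ≤ 0.05, r² ≥ 0.6 with a member), and a
merge of envelopes separated by ≤ `merge_kb`.  The LD panel defaults to the
analysis cohort itself (a flag accepts an external panel file).  Envelope
and merge tie rules are fixed and tested against a brute-force oracle; they
are our own rules, not claimed bit-identical to any external tool.
Nearest-gene ties break by smaller gene start, then id.  Locus-vs-base
classification uses ±500 kb flanks around reported variants; `novel_strict`
additionally requires top p ≤ 1e-15.  Zero joins between the reported list
and the tested variants raise an error (the usual cause is a genome-build
mismatch).

## Enrichment

Positional mapping includes a gene when a significant SNP lies within
±10 kb of its boundaries (inclusive at exactly 10,000 bp).  The test is
one-sided hypergeometric on the overlap; BH FDR is applied across **all**
sets with ≥ 1 background gene, while the ≥ 2-overlap rule filters
*reporting* only — the conservative reading of a reporting filter, since
dropping tested sets from the family would understate the correction.  The
background defaults to all annotated genes and is configurable.

## LD score regression

LD scores sum adjusted squared correlations `r²_adj = r² − (1−r²)/(n−2)`
within a 1 Mb window (a kb window, not cM: the synthetic genomes carry no
genetic map).  Heritability uses a two-pass weighted fit — unweighted first,
then weights `1/(ℓ·(1+Nh²ℓ/M)²)` from the first pass; full iteration adds
nothing at these scales.  `h² = slope·M/N` with a free intercept; negative
estimates are reported and flagged, never clamped.  Genetic correlation
regresses `z₁z₂` on `sqrt(N₁N₂)·ℓ/M` with a free intercept (absorbing
sample overlap) and cross-weights `sqrt(w₁w₂)`, so a trait against itself
returns rg = 1 identically.  Standard errors are delete-one block jackknives
over contiguous blocks (200, reduced to ≤ 20 below 2,000 variants); the rg
jackknife re-estimates all three regressions per deleted block so the ratio's
variability is captured.

## PheWAS

Traits are typed by declared manifest or inference (two distinct values →
binary; numeric with > 20 distinct → continuous, else ordered; non-numeric →
unordered; the 20-value cutoff is our rule).  The trait is the response and
group membership the exposure.  Models: OLS, IRLS logistic,
proportional-odds (statsmodels OrderedModel), and one-vs-rest logistic per
level for unordered traits, reporting the best level with its own
within-trait Bonferroni factor.  Filters: missingness > 20% excludes the
trait; categorical levels with < 200 answers are dropped and the trait
excluded if fewer than two remain.  The family-wise threshold is
`α / (tests actually performed)`.  P-values are clamped at 1e-300 in
estimation; the plotting output additionally floors at 1e-150 (signed
−log10 p, sign of β).

## The synthetic-data generator

* **Genotypes**: per block, each haplotype draws a latent AR(1) Gaussian
  (corr `rho^|i−j|`) and carries the alternate allele below the
  allele-frequency quantile; dosage is the sum of two independent
  haplotypes.  The model was chosen because the true haplotype r² has a
  closed form (`latent_ar1_r2`), giving exact oracles for LD-dependent
  code.  Within-block spacing defaults to 1 kb and inter-block gaps to
  100 kb.
* **Phenotype**: liability = standardized polygenic score scaled to
  variance h² plus N(0, 1−h²) noise, thresholded at the normal quantile of
  1−prevalence.  Covariates mirror a biobank adjustment set (sex, year of
  birth, deprivation index, batch) plus ten PCs computed from the realized
  genotypes, so PC adjustment is meaningful rather than decorative.
* **Base study**: marginal effects `Σ_k r_jk β_k` from a reference panel
  plus noise with SE `1/sqrt(2·N_base·f(1−f))` — O(variants) cost instead of
  resampling a second cohort, while preserving LD smear and winner's-curse
  noise.  Note the SE scales as `1/sqrt(N_base)`: quadrupling the base
  cohort halves it.
* **Seeds**: one global integer expands to per-stage generators via
  `SeedSequence([seed, crc32(stage_tag)])`; every operation is
  bit-reproducible under a fixed seed.
* **Not emulated**: demography, recombination maps, imputation uncertainty,
  genotyping batch artefacts, non-random missingness, strand errors.
  Passing tests therefore demonstrate the *statistical machinery* on data
  satisfying its assumptions, not robustness to real-data pathologies.

## Problem sizes

The calibration and benchmark studies in `extremescan.evaluation` are
desk-scale analogues chosen to keep the whole suite runnable on a laptop
while leaving the measured quantities well inside their tolerance bands:
null calibration at 10,000 LD-free variants and 2,000 samples per tail;
polygenic inflation at 10,000 samples × 5,000 variants (500 causal,
h² = 0.5, 5% tails); the power comparison over 50 replicates of 6,000
samples × 200 variants with 1,000 per arm; LDSC recovery at M = 5,000,
N = 20,000, 20 replicates; PheWAS FWER over 200 replicate families of 30
null traits.

## Known limitations

* The locus envelope/merge tie rules at identical positions are our fixed
  choices; other tools may differ at exact boundaries.
* The Wald test shows the usual slight finite-sample deviation from
  uniformity (sup-CDF distance ~0.01 at 4,000 samples); at very large test
  counts a KS test can detect it even though type-I error at α = 0.05 is
  accurate.
* `rg` is undefined (flagged, not fabricated) when a component heritability
  estimate is non-positive.
* The analytic base-study emulation has no sample overlap with the target
  cohort; overlap-induced bias in the extremes design is out of scope.
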