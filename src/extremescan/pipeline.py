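"""End-to-end orchestration of the score-extremes design.

Stage order: harmonize -> scoring-stage QC -> clump -> score -> extremes ->
GWAS-stage QC + extremes GWAS + inflation -> loci -> base comparison ->
optional enrichment / LD-score correlation / PheWAS.  With
``apoe_mode="both"`` the score, extremes and PheWAS are repeated with the
dominant-locus region excluded and paired outputs are written.  Every stage
logs one structured line of counts and persists its table before the next
stage runs, so a failure aborts with the stage name and keeps completed
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from extremescan import assoc, dataio, enrich, ldsc, loci as loci_mod, phewas as phewas_mod, prscore, simdata
from extremescan._rng import child_rng

log = logging.getLogger(__name__)


@dataclass
class SimulateSpec:
    """Synthetic-cohort settings for simulate-mode runs.

    The defaults give a desk-scale analogue of the study conditions: a
    polygenic disease (h2 = 0.5 on the liability scale, 10% prevalence, 50
    causal variants among 5,000 in 100 LD blocks), a separate reference
    panel standing in for the base study's cohort, and a small mixed-type
    phenome with two genuinely associated traits.
    """

    n_samples: int = 2000
    n_panel: int = 500
    n_blocks: int = 100
    variants_per_block: int = 50
    rho: float = 0.8
    n_causal: int = 50
    h2_liability: float = 0.5
    prevalence: float = 0.1
    n_base: int = 50_000
    n_traits: int = 20
    n_genes: int = 200
    n_gene_sets: int = 30


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    out_dir: str = "extremescan_out"
    seed: int = 0
    simulate: SimulateSpec | None = None
    genotypes: str | None = None
    genotype_format: str = "vcf"
    keep_samples: str | None = None
    sumstats: str | None = None
    covariates: str | None = None
    genes_bed: str | None = None
    gene_sets_gmt: str | None = None
    traits_tsv: str | None = None
    trait_manifest_tsv: str | None = None
    clump: prscore.ClumpParams = field(default_factory=prscore.ClumpParams)
    qc_prs: assoc.QCParams = field(default_factory=assoc.QCParams.prs_stage)
    qc_gwas: assoc.QCParams = field(default_factory=assoc.QCParams.gwas_stage)
    tail_q: float = 0.05
    locus: loci_mod.LocusParams = field(default_factory=loci_mod.LocusParams)
    apoe_mode: str = "include"  # include | exclude | both
    exclude_chrom: str | None = None
    exclude_start: int | None = None
    exclude_end: int | None = None
    run_enrich: bool = True
    run_ldsc: bool = True
    run_phewas: bool = True
    phewas_min_category: int = 200
    phewas_max_missing: float = 0.20
    overwrite: bool = False

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimulateSpec(**d["simulate"]) if isinstance(d["simulate"], dict) \
                else d["simulate"]
        for key, typ in (("clump", prscore.ClumpParams), ("qc_prs", assoc.QCParams),
                         ("qc_gwas", assoc.QCParams), ("locus", loci_mod.LocusParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _simulate_inputs(cfg: PipelineConfig) -> dict:
    sim = cfg.simulate
    blocks = [simdata.LDBlockSpec(n_variants=sim.variants_per_block, rho=sim.rho)
              for _ in range(sim.n_blocks)]
    arch = simdata.ArchitectureSpec(n_causal=sim.n_causal, h2_liability=sim.h2_liability,
                                    prevalence=sim.prevalence, seed=cfg.seed)
    G = simdata.simulate_ld_genotypes(blocks, sim.n_samples, seed=cfg.seed)
    panel = simdata.simulate_ld_genotypes(blocks, sim.n_panel, seed=cfg.seed + 1)
    pheno = simdata.simulate_liability_phenotype(G, arch)
    ss = simdata.simulate_base_sumstats(panel, arch, n_base=sim.n_base, seed=cfg.seed)
    ss = ss[~ss["monomorphic"]].reset_index(drop=True)
    causal_pos = [(G.variants["chrom"].iat[j], int(G.variants["pos"].iat[j]))
                  for j in pheno.causal["variant_idx"].head(10)]
    span = [(c, int(G.variants.loc[G.variants["chrom"] == c, "pos"].min()),
             int(G.variants.loc[G.variants["chrom"] == c, "pos"].max()) + 50_000)
            for c in pd.unique(G.variants["chrom"])]
    genes, catalog = simdata.simulate_annotation(
        span, sim.n_genes, sim.n_gene_sets,
        simdata.EnrichedSetSpec(positions=tuple(causal_pos), n_extra=5), seed=cfg.seed)
    covars = pheno.table.set_index("sample_id").drop(columns=["status", "liability"])
    return dict(G=G, panel=panel, sumstats=ss, covariates=covars, genes=genes,
                catalog=catalog, pheno=pheno, arch=arch)


def _load_inputs(cfg: PipelineConfig) -> dict:
    keep = None
    if cfg.keep_samples:
        keep = [l.strip() for l in open(cfg.keep_samples) if l.strip()]
    G = dataio.read_genotypes(cfg.genotypes, cfg.genotype_format, keep)
    out: dict = dict(G=G, panel=G, sumstats=dataio.read_sumstats(cfg.sumstats))
    out["covariates"] = (pd.read_csv(cfg.covariates, sep="\t", index_col=0)
                         if cfg.covariates else None)
    out["genes"] = dataio.read_bed(cfg.genes_bed) if cfg.genes_bed else None
    out["catalog"] = dataio.read_gmt(cfg.gene_sets_gmt) if cfg.gene_sets_gmt else None
    if cfg.traits_tsv:
        out["traits"] = pd.read_csv(cfg.traits_tsv, sep="\t", index_col=0)
        out["trait_manifest"] = (pd.read_csv(cfg.trait_manifest_tsv, sep="\t")
                                 if cfg.trait_manifest_tsv else None)
    return out


def _base_reported(ss: pd.DataFrame, sig_p: float = 5e-8, min_gap: int = 1_000_000) -> pd.DataFrame:
    """Distance-pruned genome-wide significant base variants (for comparison)."""
    sig = ss[ss["p"] <= sig_p].sort_values("p", kind="stable")
    rows: list = []
    for r in sig.itertuples(index=False):
        if all(str(r.chrom) != str(q.chrom) or abs(int(r.pos) - int(q.pos)) > min_gap
               for q in rows):
            rows.append(r)
    return pd.DataFrame([dict(chrom=r.chrom, pos=r.pos, id=r.id) for r in rows],
                        columns=["chrom", "pos", "id"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full design; returns a result bundle plus the run manifest."""
    stage = "setup"
    bundle: dict[str, Any] = {}
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    try:
        stage = "inputs"
        data = _simulate_inputs(cfg) if cfg.simulate else _load_inputs(cfg)
        G, ss = data["G"], data["sumstats"]
        counts["cohort_samples"] = G.n_samples
        counts["cohort_variants"] = G.n_variants
        log.info("stage=inputs samples=%d variants=%d sumstat_rows=%d",
                 G.n_samples, G.n_variants, len(ss))

        stage = "harmonize"
        pair = dataio.harmonize_alleles(ss, G)
        aligned = dataio.apply_harmonization(ss, G, pair)
        counts["harmonized"] = len(pair)
        log.info("stage=harmonize matched=%d dropped=%d", len(pair), len(pair.dropped))

        stage = "prs_qc"
        mask, _ = assoc.qc_filter(G, None, cfg.qc_prs)
        aligned = aligned[mask[np.asarray(aligned.index, dtype=int)]]
        counts["post_prs_qc"] = len(aligned)
        log.info("stage=prs_qc kept=%d", len(aligned))

        stage = "clump"
        retained = prscore.clump(aligned, G, cfg.clump)
        weights = aligned.loc[aligned.index.intersection(retained)]
        counts["post_clump"] = len(weights)
        log.info("stage=clump retained=%d", len(weights))
        tables["retained_variants"] = G.variants.iloc[retained].reset_index(drop=True)

        stage = "score"
        runs: dict[str, dict] = {}
        modes = {"include": ["with_apoe"], "exclude": ["no_apoe"],
                 "both": ["with_apoe", "no_apoe"]}[cfg.apoe_mode]
        for mode in modes:
            w = weights
            if mode == "no_apoe":
                if cfg.exclude_chrom is None:
                    raise ValueError("apoe_mode requires exclude_chrom/start/end")
                w, n_rm = prscore.exclude_region(weights, cfg.exclude_chrom,
                                                 cfg.exclude_start, cfg.exclude_end)
                counts["excluded_region_variants"] = n_rm
            prs = prscore.score(G, w)
            groups = prscore.assign_extremes(prs, cfg.tail_q)
            runs[mode] = dict(prs=prs, groups=groups)
            tables[f"scores_{mode}"] = pd.DataFrame(
                {"sample_id": prs.sample_ids, "raw": prs.raw, "rescaled": prs.rescaled,
                 "group": groups.labels})
        main = runs[modes[0]]
        counts["tail_k"] = main["groups"].k
        log.info("stage=score tails=%d n_variants_used=%d", main["groups"].k,
                 main["prs"].n_variants_used)
        bundle.update(runs=runs, weights=weights)

        stage = "gwas"
        gwas = assoc.run_gwas(G, main["groups"], data.get("covariates"), cfg.qc_gwas)
        counts["gwas_tested"] = int((gwas.records["status"] == "ok").sum())
        counts["lambda_x1000"] = int(round(gwas.lambda_gc * 1000))
        log.info("stage=gwas tested=%d lambda=%.3f", counts["gwas_tested"], gwas.lambda_gc)
        tables["gwas"] = gwas.records
        tables["qq"] = assoc.qq_data(gwas.records.loc[gwas.records["status"] == "ok", "p"])
        bundle["gwas"] = gwas

        stage = "loci"
        ind_sig = loci_mod.independent_significant(gwas, data["panel"], cfg.locus)
        leads, loci_df = loci_mod.lead_and_loci(ind_sig, gwas, data["panel"], cfg.locus,
                                                genes=data.get("genes"))
        counts["independent_significant"] = len(ind_sig)
        counts["lead_snps"] = len(leads)
        counts["loci"] = len(loci_df)
        log.info("stage=loci ind_sig=%d leads=%d loci=%d", len(ind_sig), len(leads),
                 len(loci_df))
        tables["loci"] = loci_df.drop(columns=["lead_snps", "ind_sig_snps"], errors="ignore")
        bundle.update(ind_sig=ind_sig, leads=leads, loci=loci_df)

        stage = "compare_with_base"
        reported = _base_reported(ss)
        if len(reported) and len(loci_df):
            rep_table, locus_labels = loci_mod.compare_with_base(gwas, loci_df, reported,
                                                                 sig_p=cfg.locus.sig_p)
            tables["base_comparison"] = rep_table
            tables["locus_labels"] = locus_labels
            counts["novel_loci"] = int((locus_labels["label"] == "novel").sum())
        log.info("stage=compare reported=%d", len(reported))

        if cfg.run_enrich and data.get("genes") is not None and data.get("catalog"):
            stage = "enrich"
            sig_snps = gwas.records[(gwas.records["status"] == "ok") &
                                    (gwas.records["p"] <= cfg.locus.sig_p)]
            mapped = enrich.map_genes_positional(sig_snps, data["genes"])
            region_genes = None
            if cfg.exclude_chrom is not None:
                region_genes = enrich.map_genes_positional(
                    pd.DataFrame({"chrom": [cfg.exclude_chrom] * 2,
                                  "pos": [cfg.exclude_start, cfg.exclude_end]}),
                    data["genes"], window_kb=0)
            result = enrich.hypergeom_enrichment(mapped, data["catalog"],
                                                 data["genes"]["id"], region_genes=region_genes)
            tables["enrichment"] = result
            counts["mapped_genes"] = len(mapped)
            bundle["enrichment"] = result
            log.info("stage=enrich mapped_genes=%d sets_tested=%d", len(mapped), len(result))

        if cfg.run_ldsc:
            stage = "ldsc"
            scores_tab = ldsc.ld_scores(data["panel"])
            okrec = gwas.records[gwas.records["status"] == "ok"]
            key = okrec.set_index(["chrom", "pos"])
            merged = scores_tab.merge(okrec[["chrom", "pos", "beta", "se"]],
                                      on=["chrom", "pos"], how="inner")
            z = (merged["beta"] / merged["se"]).to_numpy()
            N = gwas.n_cases + gwas.n_controls
            h2 = ldsc.h2_regression(z ** 2, N, merged)
            bundle["h2"] = h2
            counts["ldsc_variants"] = h2.M
            tables["ldsc_h2"] = pd.DataFrame([dataclasses.asdict(h2)])
            log.info("stage=ldsc h2=%.3f (se %.3f) intercept=%.3f", h2.h2, h2.se_h2,
                     h2.intercept)

        if cfg.run_phewas:
            stage = "phewas"
            traits, manifest = data.get("traits"), data.get("trait_manifest")
            if traits is None and cfg.simulate:
                specs = _default_trait_specs(cfg.simulate.n_traits)
                traits, manifest = simdata.simulate_trait_table(
                    main["groups"], specs, seed=cfg.seed)
            if traits is not None:
                for mode in modes:
                    scan = phewas_mod.phewas_scan(runs[mode]["groups"], traits,
                                                  covariates=data.get("covariates"),
                                                  manifest=manifest,
                                                  min_category=cfg.phewas_min_category,
                                                  max_missing=cfg.phewas_max_missing)
                    tables[f"phewas_{mode}"] = scan.records
                    bundle[f"phewas_{mode}"] = scan
                counts["phewas_tests"] = bundle[f"phewas_{modes[0]}"].n_tests
                log.info("stage=phewas tests=%d", counts["phewas_tests"])

        if len(modes) == 2:
            a = runs["with_apoe"]["groups"].labels
            b = runs["no_apoe"]["groups"].labels
            counts["group_symmetric_difference"] = int((a != b).sum())

        stage = "write"
        cfg_id = cfg.to_dict()
        cfg_id.pop("out_dir", None)  # hash run identity, not output location
        cfg_id.pop("overwrite", None)
        manifest = dataio.write_results(
            tables, cfg.out_dir, seed=cfg.seed, config=cfg_id,
            overwrite=cfg.overwrite, extra={"counts": counts},
        )
        bundle["manifest"] = manifest
        bundle["counts"] = counts
        return bundle
    except Exception as exc:
        if tables:
            try:
                dataio.write_results(tables, cfg.out_dir, seed=cfg.seed,
                                     overwrite=True, extra={"counts": counts,
                                                            "failed_stage": stage})
            except Exception:  # persisting partial output is best-effort
                pass
        log.error("pipeline failed at stage %s", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _default_trait_specs(n_traits: int) -> list[simdata.TraitSpec]:
    """Mixed-type phenome: two associated traits, the rest null, one
    over-missing trait that the 20% filter must drop."""
    specs = [
        simdata.TraitSpec("assoc_continuous", "continuous", effect=0.6),
        simdata.TraitSpec("assoc_binary", "binary", effect=1.0),
        simdata.TraitSpec("too_missing", "continuous", effect=0.0, missingness=0.25),
    ]
    kinds = ["continuous", "binary", "ordered", "unordered"]
    for i in range(max(n_traits - len(specs), 0)):
        specs.append(simdata.TraitSpec(f"null_{kinds[i % 4]}_{i}", kinds[i % 4], effect=0.0,
                                       missingness=0.05))
    return specs
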