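"""Genomic risk-locus definition and comparison with the base study.

Three-tier clumping hierarchy: genome-wide significant SNPs are greedily
clumped at r^2 0.6 into *independent significant* SNPs; a second clump at
r^2 0.1 prioritises *lead* SNPs; candidate SNPs (p <= 0.05, r^2 >= 0.6 with
a member) define each lead's LD-block envelope, and envelopes within 250 kb
on a chromosome merge into one *genomic risk locus*, numbered in genome
order and named by the nearest gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from extremescan.dataio import GenotypeMatrix
from extremescan.prscore import _imputed_standardized, _r2_with, greedy_clump

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusParams:
    """Locus-definition thresholds (defaults follow the FUMA convention)."""

    sig_p: float = 5e-8
    cand_p: float = 0.05
    r2_independent: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0

    def __post_init__(self) -> None:
        if self.r2_lead > self.r2_independent:
            raise ValueError("r2_lead must not exceed r2_independent")


def _gwas_frame(gwas) -> pd.DataFrame:
    df = gwas.records if hasattr(gwas, "records") else gwas
    return df[df["status"] == "ok"].reset_index() if "status" in df.columns else df.reset_index()


def _panel_lookup(df: pd.DataFrame, panel: GenotypeMatrix) -> np.ndarray:
    """Panel column index for each GWAS row, matched on (chrom, pos)."""
    key = {(str(c), int(p)): j for j, (c, p) in
           enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))}
    idx = np.array([key.get((str(c), int(p)), -1) for c, p in zip(df["chrom"], df["pos"])])
    if (idx < 0).any():
        raise ValueError("GWAS variants missing from LD panel")
    return idx


def independent_significant(gwas, panel: GenotypeMatrix,
                            params: LocusParams | None = None) -> pd.DataFrame:
    """Greedy clump of genome-wide significant SNPs at the first r^2 tier.

    Returns the retained rows of the association table (chromosome-wide
    window: only LD, not distance, separates independent signals).
    """
    params = params or LocusParams()
    df = _gwas_frame(gwas)
    sig = df[df["p"] <= params.sig_p].reset_index(drop=True)
    if sig.empty:
        return sig
    panel_idx = _panel_lookup(sig, panel)
    Z = _imputed_standardized(panel.take_variants(panel_idx))
    chrom_codes = pd.factorize(sig["chrom"].astype(str))[0]
    kept = greedy_clump(
        sig["p"].to_numpy(float), chrom_codes, sig["pos"].to_numpy(np.int64),
        lambda i, others: _r2_with(Z, i, others),
        params.r2_independent, window_bp=None,
    )
    return sig.iloc[sorted(kept)].reset_index(drop=True)


def lead_and_loci(
    ind_sig: pd.DataFrame,
    gwas,
    panel: GenotypeMatrix,
    params: LocusParams | None = None,
    genes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lead SNPs (second clump) and merged genomic risk loci.

    Returns ``(leads, loci)``.  Candidate SNPs — association rows with
    p <= ``cand_p`` and r^2 >= ``r2_independent`` with any independent
    significant member — set each lead group's LD-block envelope; envelopes
    separated by at most ``merge_kb`` on one chromosome merge.  When a gene
    annotation is given each locus is named by the gene nearest its top lead.
    """
    params = params or LocusParams()
    loci_cols = ["locus_id", "chrom", "start_bp", "end_bp", "top_snp", "top_p",
                 "n_lead", "n_ind_sig", "lead_snps", "ind_sig_snps", "nearest_gene",
                 "gene_distance"]
    if ind_sig.empty:
        return ind_sig.copy(), pd.DataFrame(columns=loci_cols)
    df = _gwas_frame(gwas)
    ind_sig = ind_sig.reset_index(drop=True)

    # --- second clump: leads among independent significant SNPs
    panel_idx_ind = _panel_lookup(ind_sig, panel)
    Z_ind = _imputed_standardized(panel.take_variants(panel_idx_ind))
    chrom_codes = pd.factorize(ind_sig["chrom"].astype(str))[0]
    p_ind = ind_sig["p"].to_numpy(float)
    pos_ind = ind_sig["pos"].to_numpy(np.int64)

    lead_of = np.full(len(ind_sig), -1)
    order = np.lexsort((pos_ind, chrom_codes, p_ind))
    for i in order:
        if lead_of[i] >= 0:
            continue
        lead_of[i] = i
        others = np.flatnonzero((lead_of < 0) & (chrom_codes == chrom_codes[i]))
        if len(others):
            r2 = _r2_with(Z_ind, i, others)
            r2 = np.where(np.isnan(r2), 0.0, r2)
            lead_of[others[r2 >= params.r2_lead]] = i
    leads = ind_sig.iloc[sorted(set(lead_of))].reset_index(drop=True)

    # --- candidate SNPs define each group's envelope
    cand = df[df["p"] <= params.cand_p].reset_index(drop=True)
    panel_idx_cand = _panel_lookup(cand, panel)
    Z_cand = _imputed_standardized(panel.take_variants(panel_idx_cand))
    cand_chrom = cand["chrom"].astype(str).to_numpy()
    cand_pos = cand["pos"].to_numpy(np.int64)

    groups: dict[int, dict] = {}
    for i in range(len(ind_sig)):
        g = groups.setdefault(int(lead_of[i]), dict(members=[], start=np.inf, end=-np.inf))
        g["members"].append(i)
    for li, g in groups.items():
        member_chrom = str(ind_sig["chrom"].iat[g["members"][0]])
        lo, hi = np.inf, -np.inf
        same = np.flatnonzero(cand_chrom == member_chrom)
        for mi in g["members"]:
            lo = min(lo, pos_ind[mi]); hi = max(hi, pos_ind[mi])
            if len(same):
                # r^2 of candidates against this member over the panel
                r = Z_cand[:, same].T @ _imputed_standardized(
                    panel.take_variants([panel_idx_ind[mi]]))[:, 0] / Z_cand.shape[0]
                hits = same[np.nan_to_num(r * r) >= params.r2_independent]
                if len(hits):
                    lo = min(lo, cand_pos[hits].min()); hi = max(hi, cand_pos[hits].max())
        g["chrom"] = member_chrom
        g["start"], g["end"] = int(lo), int(hi)

    # --- merge envelopes within merge_kb on a chromosome
    items = sorted(groups.items(), key=lambda kv: (kv[1]["chrom"], kv[1]["start"]))
    merged: list[dict] = []
    for li, g in items:
        if merged and merged[-1]["chrom"] == g["chrom"] and \
                g["start"] - merged[-1]["end"] <= params.merge_kb * 1000:
            m = merged[-1]
            m["end"] = max(m["end"], g["end"])
            m["lead_ids"].append(li)
            m["members"].extend(g["members"])
        else:
            merged.append(dict(chrom=g["chrom"], start=g["start"], end=g["end"],
                               lead_ids=[li], members=list(g["members"])))

    rows = []
    for k, m in enumerate(merged):
        mem = m["members"]
        top = mem[int(np.argmin(p_ind[mem]))]
        row = dict(
            locus_id=k + 1, chrom=m["chrom"], start_bp=m["start"], end_bp=m["end"],
            top_snp=ind_sig["id"].iat[top], top_p=float(p_ind[top]),
            n_lead=len(m["lead_ids"]), n_ind_sig=len(mem),
            lead_snps=",".join(ind_sig["id"].iat[i] for i in sorted(m["lead_ids"])),
            ind_sig_snps=",".join(ind_sig["id"].iat[i] for i in sorted(mem)),
            nearest_gene="none", gene_distance=np.nan,
        )
        if genes is not None and not genes.empty:
            label, dist = nearest_gene(m["chrom"], int(ind_sig["pos"].iat[top]), genes)
            row["nearest_gene"], row["gene_distance"] = label, dist
        rows.append(row)
    loci = pd.DataFrame(rows, columns=loci_cols)
    return leads, loci


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> tuple[str, float]:
    """Nearest gene label and distance (0 inside the gene body).

    Ties broken by smaller gene start, then lexicographic id; no gene on the
    chromosome yields ("none", nan).
    """
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return "none", float("nan")
    start = sub["start_bp"].to_numpy(np.int64)
    end = sub["end_bp"].to_numpy(np.int64)
    dist = np.maximum(0, np.maximum(start - pos, pos - end))
    order = np.lexsort((sub["id"].to_numpy(), start, dist))
    best = order[0]
    return str(sub["id"].iloc[best]), float(dist[best])


def compare_with_base(
    gwas,
    loci: pd.DataFrame,
    reported: pd.DataFrame,
    flank_kb: float = 500.0,
    sig_p: float = 5e-8,
    strict_p: float = 1e-15,
    qc_reasons: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify extremes-GWAS loci against the base study's reported variants.

    ``reported`` needs columns chrom, pos (and optionally id).  Each reported
    variant gets the lowest-p extremes variant within ``flank_kb`` and a
    status: *replicated* (flank hit at p <= sig_p), *not_tested(<reason>)*
    (the variant itself failed cohort QC — reasons from ``qc_reasons``
    keyed by (chrom, pos)), or *not_significant*.  Each extremes locus is
    *replicated* when it overlaps some reported variant's flank, else
    *novel*; ``novel_strict`` additionally requires top p <= ``strict_p``.
    """
    df = _gwas_frame(gwas)
    full = gwas.records if hasattr(gwas, "records") else df
    if not len(df) and not len(full):
        raise ValueError("empty association table")
    flank = flank_kb * 1000.0
    chrom_arr = df["chrom"].astype(str).to_numpy()
    pos_arr = df["pos"].to_numpy(np.int64)
    p_arr = df["p"].to_numpy(float)

    joined = 0
    rep_rows = []
    for r in reported.itertuples(index=False):
        rchrom, rpos = str(r.chrom), int(r.pos)
        rid = getattr(r, "id", f"{rchrom}:{rpos}")
        near = np.flatnonzero((chrom_arr == rchrom) & (np.abs(pos_arr - rpos) <= flank))
        best_id, best_p = None, np.nan
        if len(near):
            joined += 1
            b = near[np.argmin(p_arr[near])]
            best_id, best_p = df["id"].iat[b], float(p_arr[b])
        reason = (qc_reasons or {}).get((rchrom, rpos))
        if reason is None and hasattr(gwas, "records"):
            hit = full[(full["chrom"].astype(str) == rchrom) & (full["pos"] == rpos)]
            if len(hit) and str(hit["status"].iat[0]).startswith("filtered("):
                reason = str(hit["status"].iat[0])[len("filtered("):-1]
        if reason is not None:
            status = f"not_tested({reason})"
        elif len(near) and best_p <= sig_p:
            status = "replicated"
        else:
            status = "not_significant"
        rep_rows.append(dict(chrom=rchrom, pos=rpos, id=rid, best_variant=best_id,
                             best_p=best_p, status=status))
    reported_table = pd.DataFrame(rep_rows)
    if joined == 0 and len(reported):
        raise ValueError("no reported variant joined any tested variant (build mismatch?)")

    locus_rows = []
    for l in loci.itertuples(index=False):
        overlaps = any(
            str(r.chrom) == str(l.chrom) and
            l.start_bp - flank <= int(r.pos) <= l.end_bp + flank
            for r in reported.itertuples(index=False)
        )
        label = "replicated" if overlaps else "novel"
        locus_rows.append(dict(locus_id=l.locus_id, chrom=l.chrom, top_snp=l.top_snp,
                               top_p=l.top_p, label=label,
                               novel_strict=(label == "novel" and l.top_p <= strict_p)))
    return reported_table, pd.DataFrame(locus_rows)
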