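"""Positional gene mapping and gene-set overlap enrichment.

Significant SNPs are mapped to genes whose boundaries (+/- a 10 kb window)
contain them; the mapped gene list is tested against a catalog of gene sets
with the one-sided hypergeometric overlap test and Benjamini-Hochberg FDR
across all tested sets.  Sets overlapping fewer than ``min_overlap`` genes
are excluded from *reporting* but still count toward the multiple-testing
family (the conservative reading of a reporting-only filter).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def map_genes_positional(
    snps: pd.DataFrame, genes: pd.DataFrame, window_kb: float = 10.0
) -> list[str]:
    """Genes with a SNP within or +/- ``window_kb`` of their boundaries.

    ``snps`` needs chrom and pos columns; inclusion is inclusive at exactly
    the window edge.  Returns unique gene ids sorted by genomic position.
    """
    w = int(window_kb * 1000)
    hits: list[tuple[str, int, str]] = []
    for chrom, sub in genes.groupby(genes["chrom"].astype(str)):
        pos = snps.loc[snps["chrom"].astype(str) == chrom, "pos"].to_numpy(np.int64)
        if len(pos) == 0:
            continue
        start = sub["start_bp"].to_numpy(np.int64) - w
        end = sub["end_bp"].to_numpy(np.int64) + w
        inside = (pos[None, :] >= start[:, None]) & (pos[None, :] <= end[:, None])
        for k in np.flatnonzero(inside.any(axis=1)):
            hits.append((chrom, int(sub["start_bp"].iloc[k]), str(sub["id"].iloc[k])))
    hits.sort()
    out, seen = [], set()
    for _, _, gid in hits:
        if gid not in seen:
            seen.add(gid)
            out.append(gid)
    return out


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clamped to 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    input_genes: Iterable[str],
    catalog: Mapping[str, Iterable[str]],
    background: Iterable[str],
    min_overlap: int = 2,
    region_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric overlap test per gene set, BH-corrected.

    For a background of N genes, a set of K, and n input genes, the p-value
    is P[X >= k] for the observed overlap k.  Sets with no background gene
    are skipped entirely; sets with overlap below ``min_overlap`` keep their
    test (they stay in the BH family) but are flagged unreported.  When
    ``region_genes`` is given each row records whether its overlap touches
    that region (used to stratify results by a dominant locus).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    inp = set(input_genes) & bg
    dropped = set(input_genes) - bg
    if dropped:
        log.warning("%d input genes outside the background were ignored", len(dropped))
    region = set(region_genes) if region_genes is not None else set()

    rows = []
    for name, members in catalog.items():
        k_set = set(members) & bg
        if not k_set:
            continue
        overlap = sorted(k_set & inp)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, len(bg), len(k_set), len(inp)))
        rows.append(dict(
            set_id=name, overlap_count=k, set_size=len(k_set),
            input_size=len(inp), background_size=len(bg),
            p=min(p, 1.0), overlap_genes=",".join(overlap),
            reported=k >= min_overlap,
            contains_region_gene=bool(region & set(overlap)),
        ))
    result = pd.DataFrame(rows)
    if len(result):
        result["p_adj"] = bh_adjust(result["p"])
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    return result
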