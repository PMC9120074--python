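"""Clumping + thresholding polygenic scores and extreme-group assignment.

The score for sample i is ``sum_j beta_j * d_ij`` over the variants retained
by greedy LD clumping of the base summary statistics at a p-value threshold.
Group assignment takes the k = ceil(q*N) smallest and largest raw scores as
the low/high extremes; the min-max rescaled score is cosmetic (for plotting)
and never feeds statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from extremescan.dataio import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClumpParams:
    """Clumping + thresholding parameters.

    ``p_threshold`` is the base-GWAS inclusion cutoff applied to index
    variants (default 0.05); ``clump_kb`` the window half-width; ``clump_r2``
    the LD pruning threshold; ``clump_p`` the maximum p for a variant to act
    as a clump index at all.  Defaults beyond the inclusion threshold follow
    the conventional C+T tool defaults (250 kb, r2 0.1, clump_p 1).
    """

    p_threshold: float = 0.05
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    clump_p: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_r2", "clump_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")


@dataclass
class PRSResult:
    """Per-sample polygenic score."""

    sample_ids: list[str]
    raw: np.ndarray
    rescaled: np.ndarray | None
    n_variants_used: int
    variant_ids_used: list[str]


@dataclass
class ExtremeGroups:
    """Per-sample extreme-tail assignment: labels in {low, high, unassigned}."""

    sample_ids: list[str]
    labels: np.ndarray
    q: float
    k: int

    def index(self, which: str) -> np.ndarray:
        return np.flatnonzero(self.labels == which)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(G: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples.

    Returns NaN for a monomorphic variant (callers treat that as r2 = 0 when
    clumping).
    """
    a, b = G.dosage[:, i], G.dosage[:, j]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _imputed_standardized(G: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, centred, unit-scaled dosages (monomorphic cols -> 0)."""
    d = G.dosage.astype(np.float64)
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d)
    d -= mean
    sd = d.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, d / sd, 0.0)
    return z


def _r2_with(Z: np.ndarray, index: int, others: np.ndarray) -> np.ndarray:
    """r^2 between column ``index`` and ``others`` of a standardized matrix."""
    n = Z.shape[0]
    r = Z[:, others].T @ Z[:, index] / n
    return r * r


def greedy_clump(
    p: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    r2_fn,
    r2_threshold: float,
    window_bp: float | None,
    max_p: float = 1.0,
) -> list[int]:
    """Generic greedy index-variant clumping.

    Candidates with p < ``max_p`` are visited in ascending (p, chrom, pos)
    order; each index variant removes every not-yet-clumped candidate on the
    same chromosome within ``window_bp`` (no window restriction when None)
    whose r^2 with it reaches ``r2_threshold``.  Returns index-variant
    positions in visit order.
    """
    cand = np.flatnonzero(p < max_p)
    order = cand[np.lexsort((pos[cand], chrom[cand], p[cand]))]
    alive = np.ones(len(p), dtype=bool)
    alive[p >= max_p] = False
    kept: list[int] = []
    for idx in order:
        if not alive[idx]:
            continue
        kept.append(int(idx))
        alive[idx] = False
        near = alive & (chrom == chrom[idx])
        if window_bp is not None:
            near &= np.abs(pos - pos[idx]) <= window_bp
        near_idx = np.flatnonzero(near)
        if len(near_idx):
            r2 = r2_fn(idx, near_idx)
            r2 = np.where(np.isnan(r2), 0.0, r2)
            alive[near_idx[r2 >= r2_threshold]] = False
    return kept


def clump(ss: pd.DataFrame, panel: GenotypeMatrix, params: ClumpParams) -> list[int]:
    """Greedy C+T clumping of harmonized summary statistics.

    ``ss`` must be aligned to ``panel`` (index = panel variant index, as
    produced by :func:`extremescan.dataio.apply_harmonization`).  Returns the
    panel indices of retained variants — index variants with
    p < ``p_threshold`` — in genome order.
    """
    if len(ss) == 0:
        raise ValueError("no variants pass p threshold (empty summary statistics)")
    g_idx = np.asarray(ss.index, dtype=int)
    p = ss["p"].to_numpy(dtype=float)
    chrom = panel.variants["chrom"].to_numpy()[g_idx]
    pos = panel.variants["pos"].to_numpy(dtype=np.int64)[g_idx]
    sub = panel.take_variants(g_idx)
    Z = _imputed_standardized(sub)
    chrom_codes = pd.factorize(chrom)[0]

    kept_local = greedy_clump(
        p, chrom_codes, pos,
        lambda i, others: _r2_with(Z, i, others),
        params.clump_r2, params.clump_kb * 1000.0, params.clump_p,
    )
    retained = [g_idx[i] for i in kept_local if p[i] < params.p_threshold]
    if not retained:
        raise ValueError("no variants pass p threshold")
    return sorted(retained, key=lambda j: (panel.variants["chrom"].iat[j],
                                           panel.variants["pos"].iat[j]))


# ---------------------------------------------------------------------------
# region exclusion
# ---------------------------------------------------------------------------

def exclude_region(
    df: pd.DataFrame,
    chrom: str,
    start: int | None = None,
    end: int | None = None,
    anchor_locus: tuple[int, int] | None = None,
    radius_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, int]:
    """Drop variants inside a genomic region (inclusive ends).

    Fixed mode gives ``chrom:start-end`` directly.  Anchor mode
    (``anchor_locus=(lo, hi)``) finds the most significant variant (needs a
    ``p`` column) within that window and removes everything within
    ``radius_bp`` of it — the usual way a dominant locus such as APOE is
    excised around its top signal.  Returns (subset, n_removed).
    """
    df_chrom = df["chrom"].astype(str)
    if anchor_locus is not None:
        lo, hi = anchor_locus
        window = df[(df_chrom == str(chrom)) & df["pos"].between(lo, hi)]
        if window.empty:
            raise ValueError(f"anchor locus {chrom}:{lo}-{hi} contains no variants")
        top = window.loc[window["p"].idxmin()]
        start, end = int(top["pos"]) - radius_bp, int(top["pos"]) + radius_bp
    if start is None or end is None or start > end:
        raise ValueError("malformed region")
    inside = (df_chrom == str(chrom)) & df["pos"].between(start, end)
    n_removed = int(inside.sum())
    log.info("exclude_region %s:%d-%d removed %d variants", chrom, start, end, n_removed)
    return df[~inside], n_removed


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(
    G: GenotypeMatrix,
    weights: pd.DataFrame,
    rescale: bool = True,
) -> PRSResult:
    """Weighted-sum polygenic score.

    ``weights`` is indexed by cohort variant index with a ``beta`` column (an
    optional boolean ``sign_flip`` column applies the d -> 2-d orientation
    change instead of a pre-negated beta).  Missing dosages are mean-imputed
    as ``2*freq`` from the cohort itself; all-missing variants are excluded
    with a warning.  When ``rescale`` the score is min-max mapped to [0, 1]
    (all-equal scores map to 0.5 with a degeneracy warning).
    """
    if len(weights) == 0:
        raise ValueError("empty weight table")
    idx = np.asarray(weights.index, dtype=int)
    beta = weights["beta"].to_numpy(dtype=float)
    d = G.dosage[:, idx].astype(np.float64)
    if "sign_flip" in weights.columns:
        flip = weights["sign_flip"].to_numpy(dtype=bool)
        d[:, flip] = 2.0 - d[:, flip]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(d, axis=0)
    usable = ~np.isnan(mean)
    if not usable.all():
        log.warning("excluding %d all-missing variants from scoring", int((~usable).sum()))
        d, beta, idx, mean = d[:, usable], beta[usable], idx[usable], mean[usable]
    d = np.where(np.isnan(d), mean, d)  # mean dosage = 2 * effect-allele freq
    raw = d @ beta
    rescaled = None
    if rescale:
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            rescaled = (raw - lo) / (hi - lo)
        else:
            log.warning("degenerate score distribution: all scores equal")
            rescaled = np.full_like(raw, 0.5)
    return PRSResult(list(G.sample_ids), raw, rescaled, int(len(idx)),
                     [G.variants["id"].iat[j] for j in idx])


def assign_extremes(prs: PRSResult | np.ndarray, q: float,
                    sample_ids: list[str] | None = None) -> ExtremeGroups:
    """Label the k = ceil(q*N) smallest/largest raw scores low/high.

    Boundary ties are broken by stable sample order (earlier samples fill the
    low tail first, later samples the high tail); a tie straddling a boundary
    emits a warning.
    """
    if isinstance(prs, PRSResult):
        scores, sample_ids = prs.raw, prs.sample_ids
    else:
        scores = np.asarray(prs, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(len(scores))]
    N = len(scores)
    if not 0.0 < q < 0.5:
        raise ValueError("tail fraction q must be in (0, 0.5)")
    if N < 2:
        raise ValueError("need at least 2 samples")
    k = math.ceil(q * N)
    if 2 * k > N:
        raise ValueError(f"tails overlap: 2*k={2 * k} > N={N}")
    order = np.argsort(scores, kind="stable")
    labels = np.full(N, "unassigned", dtype=object)
    labels[order[:k]] = "low"
    labels[order[-k:]] = "high"
    lo_cut, hi_cut = scores[order[k - 1]], scores[order[N - k]]
    interior = scores[order[k:N - k]]
    if len(interior) and (np.any(interior == lo_cut) or np.any(interior == hi_cut)):
        log.warning("score ties at a tail boundary; assignment used stable sample order")
    return ExtremeGroups(list(sample_ids), labels, q, k)
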