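"""LD score regression: heritability and cross-trait genetic correlation.

The model for a trait with sample size N, M variants and SNP-heritability h2
is E[chi2_j] = 1 + N*a + (N*h2/M) * l_j, where l_j is variant j's LD score —
the sum of adjusted squared correlations with its neighbours (self term
included).  Heritability comes from a two-pass weighted regression of chi2
on l; genetic covariance from the analogous regression of z1*z2 (a free
intercept absorbs sample overlap); standard errors from a delete-one
block jackknife over contiguous variant blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from extremescan.dataio import GenotypeMatrix
from extremescan.prscore import exclude_region

log = logging.getLogger(__name__)


@dataclass
class H2Estimate:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    M: int
    mean_chi2: float
    n_blocks: int
    negative_flag: bool = False


@dataclass
class RgEstimate:
    rg: float
    rho_g: float
    se_rg: float
    h2_1: H2Estimate | None = None
    h2_2: H2Estimate | None = None
    undefined: bool = False


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def ld_scores(panel: GenotypeMatrix, window_kb: float = 1000.0) -> pd.DataFrame:
    """Per-variant LD scores from a reference panel.

    l_j = sum over k within ``window_kb`` (same chromosome, j included) of
    r2_adj(j, k), with the small-sample adjustment
    r2_adj = r2 - (1 - r2)/(n - 2); the self term contributes exactly 1.
    Monomorphic variants get NaN with a warning.  Returns a frame with
    columns chrom, pos, id, l2.
    """
    n = panel.n_samples
    if n < 10:
        raise ValueError("LD-score panel needs at least 10 samples")
    d = panel.dosage.astype(np.float64)
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d)
    sd = d.std(axis=0)
    poly = sd > 0
    if (~poly).any():
        log.warning("%d monomorphic variants excluded from LD scores", int((~poly).sum()))
    Z = np.where(poly, (d - mean) / np.where(poly, sd, 1.0), 0.0)

    window = window_kb * 1000.0
    chrom = panel.variants["chrom"].astype(str).to_numpy()
    pos = panel.variants["pos"].to_numpy(np.int64)
    m = panel.n_variants
    l2 = np.full(m, np.nan)
    adj = lambda r2: r2 - (1.0 - r2) / (n - 2)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        lo = 0
        for a, j in enumerate(idx):
            if not poly[j]:
                continue
            while cpos[a] - cpos[lo] > window:
                lo += 1
            hi = np.searchsorted(cpos, cpos[a] + window, side="right")
            neigh = idx[lo:hi]
            neigh = neigh[poly[neigh]]
            r = Z[:, neigh].T @ Z[:, j] / n
            l2[j] = adj(r * r).sum()
    return pd.DataFrame({"chrom": chrom, "pos": pos, "id": panel.variants["id"],
                         "l2": l2})


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return float(coef[1]), float(coef[0])


def _jackknife(values: np.ndarray) -> float:
    """Delete-one-block jackknife SE from the leave-block-out estimates."""
    B = len(values)
    if B < 2:
        return float("nan")
    mean = values.mean()
    return float(np.sqrt((B - 1) / B * np.sum((values - mean) ** 2)))


def _block_slices(m: int, n_blocks: int) -> list[np.ndarray]:
    return [b for b in np.array_split(np.arange(m), n_blocks) if len(b)]


def _resolve_blocks(m: int, n_blocks: int) -> int:
    if m < 2000 and n_blocks > 20:
        n_blocks = 20
    if n_blocks > m:
        log.warning("fewer variants than jackknife blocks; reducing to %d", max(m // 2, 2))
        n_blocks = max(m // 2, 2)
    return n_blocks


def _h2_weights(l2: np.ndarray, N: float, h2: float, M: int) -> np.ndarray:
    l2c = np.clip(l2, 1.0, None)
    return 1.0 / (l2c * (1.0 + max(N * h2 / M, 0.0) * l2c) ** 2)


def h2_regression(
    chi2: np.ndarray, N: float, ld: pd.DataFrame | np.ndarray, n_blocks: int = 200
) -> H2Estimate:
    """SNP-heritability by two-pass weighted LD score regression.

    Pass one is unweighted; pass two re-weights by
    1 / (l_j * (1 + N*h2*l_j/M)^2) using the pass-one heritability (the
    usual heteroskedasticity + LD-redundancy weighting, without full
    iteration).  The slope converts to h2 = slope * M / N with a free
    intercept; a negative estimate is reported as-is but flagged.
    """
    l2 = np.asarray(ld["l2"] if isinstance(ld, pd.DataFrame) else ld, dtype=float)
    chi2 = np.asarray(chi2, dtype=float)
    if len(chi2) != len(l2):
        raise ValueError("chi2 and LD-score lengths differ")
    if N <= 1:
        raise ValueError("N must exceed 1")
    ok = np.isfinite(l2) & np.isfinite(chi2)
    l2, chi2 = l2[ok], chi2[ok]
    M = len(l2)
    n_blocks = _resolve_blocks(M, n_blocks)

    def fit(mask: np.ndarray) -> tuple[float, float]:
        x, y = l2[mask], chi2[mask]
        slope0, _ = _wls(x, y, np.ones_like(x))
        h2_0 = slope0 * M / N
        slope, intercept = _wls(x, y, _h2_weights(x, N, h2_0, M))
        return slope * M / N, intercept

    h2, intercept = fit(np.ones(M, dtype=bool))
    blocks = _block_slices(M, n_blocks)
    loo = np.empty((len(blocks), 2))
    for b, blk in enumerate(blocks):
        mask = np.ones(M, dtype=bool)
        mask[blk] = False
        loo[b] = fit(mask)
    return H2Estimate(
        h2=h2, intercept=intercept,
        se_h2=_jackknife(loo[:, 0]), se_intercept=_jackknife(loo[:, 1]),
        M=M, mean_chi2=float(chi2.mean()), n_blocks=len(blocks),
        negative_flag=h2 < 0,
    )


def rg_regression(
    z1: np.ndarray, z2: np.ndarray, N1: float, N2: float,
    ld: pd.DataFrame | np.ndarray, n_blocks: int = 200,
) -> RgEstimate:
    """Cross-trait genetic correlation by LD score regression.

    The product z1*z2 regresses on sqrt(N1*N2)*l/M with a free intercept
    (absorbing sample overlap); rg = rho_g / sqrt(h2_1 * h2_2).  The three
    regressions share the jackknife blocks so the ratio's SE is the
    jackknife of the ratio itself.  Either component h2 <= 0 renders rg
    undefined (flagged).
    """
    l2 = np.asarray(ld["l2"] if isinstance(ld, pd.DataFrame) else ld, dtype=float)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if not (len(z1) == len(z2) == len(l2)):
        raise ValueError("aligned z-scores and LD scores required")
    ok = np.isfinite(l2) & np.isfinite(z1) & np.isfinite(z2)
    l2, z1, z2 = l2[ok], z1[ok], z2[ok]
    M = len(l2)
    n_blocks = _resolve_blocks(M, n_blocks)

    def fit_all(mask: np.ndarray) -> tuple[float, float, float]:
        x = l2[mask]
        c1, c2, y12 = z1[mask] ** 2, z2[mask] ** 2, (z1 * z2)[mask]
        s1, _ = _wls(x, c1, np.ones_like(x))
        h2a = s1 * M / N1
        w1 = _h2_weights(x, N1, h2a, M)
        s1, _ = _wls(x, c1, w1)
        h2a = s1 * M / N1
        s2, _ = _wls(x, c2, np.ones_like(x))
        h2b = s2 * M / N2
        w2 = _h2_weights(x, N2, h2b, M)
        s2, _ = _wls(x, c2, w2)
        h2b = s2 * M / N2
        sx, _ = _wls(x, y12, np.sqrt(w1 * w2))
        rho = sx * M / np.sqrt(N1 * N2)
        return h2a, h2b, rho

    h2a, h2b, rho = fit_all(np.ones(M, dtype=bool))
    h2_1 = h2_regression(z1 ** 2, N1, l2, n_blocks)
    h2_2 = h2_regression(z2 ** 2, N2, l2, n_blocks)
    if h2a <= 0 or h2b <= 0:
        log.warning("component heritability <= 0: genetic correlation undefined")
        return RgEstimate(np.nan, rho, np.nan, h2_1, h2_2, undefined=True)
    rg = rho / np.sqrt(h2a * h2b)

    blocks = _block_slices(M, n_blocks)
    loo = np.empty(len(blocks))
    for b, blk in enumerate(blocks):
        mask = np.ones(M, dtype=bool)
        mask[blk] = False
        a, c, r = fit_all(mask)
        loo[b] = r / np.sqrt(a * c) if (a > 0 and c > 0) else np.nan
    loo = loo[np.isfinite(loo)]
    return RgEstimate(rg, rho, _jackknife(loo), h2_1, h2_2)


def region_exclude_rerun(
    sumstats: pd.DataFrame, chrom: str, start: int, end: int,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """With/without-region input pair for paired correlation reporting.

    Returns (full, without_region, n_removed); the caller runs the same
    regression on both to quantify how much a dominant locus drives an
    estimate.
    """
    without, n_removed = exclude_region(sumstats, chrom, start, end)
    return sumstats, without.reset_index(drop=True), n_removed
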