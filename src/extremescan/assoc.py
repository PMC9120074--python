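"""Variant QC, logistic association between score extremes, genomic inflation.

The extremes GWAS treats the high-score tail as cases and the low-score tail
as controls and fits, per variant, a maximum-likelihood logistic regression
(Newton/IRLS) of group membership on dosage plus covariates, reporting the
Wald test on the dosage coefficient.  The genomic inflation factor is the
median observed 1-df chi-square divided by the null median (~0.4549).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from extremescan.dataio import GenotypeMatrix
from extremescan.prscore import ExtremeGroups

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


@dataclass(frozen=True)
class QCParams:
    """Per-variant quality-control thresholds.

    Two presets mirror the two stages of the design: scoring-stage QC is
    permissive (MAF >= 0.1%, HWE p > 1e-15, missingness < 1%) so rare base
    variants can contribute to the score, while the extremes-GWAS stage is
    strict (MAF >= 5%, HWE p >= 1e-6, missingness <= 1%).
    """

    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    miss_max: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if not 0.0 <= self.miss_max <= 1.0:
            raise ValueError("miss_max must be in [0, 1]")

    @classmethod
    def prs_stage(cls) -> "QCParams":
        return cls(maf_min=0.001, hwe_p_min=1e-15, miss_max=0.01)

    @classmethod
    def gwas_stage(cls) -> "QCParams":
        return cls(maf_min=0.05, hwe_p_min=1e-6, miss_max=0.01)


@dataclass
class AssocRecord:
    """Single-variant logistic association result (Wald test)."""

    beta: float = np.nan
    se: float = np.nan
    or_: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)
    p: float = np.nan
    n_used: int = 0
    status: str = "ok"


@dataclass
class GwasRun:
    """Association table for one extremes GWAS plus its inflation factor."""

    records: pd.DataFrame
    lambda_gc: float
    n_cases: int
    n_controls: int
    covariate_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact Hardy-Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the probabilities no larger than the observed configuration's.
    Symmetric under AA <-> aa relabeling; returns 1.0 for a monomorphic
    variant.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0

    # probabilities over het counts via the standard recurrence, same parity
    # as n_rare, starting from the mode
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    het_mode = n_rare * (2 * n - n_rare) / (2.0 * n)
    mid_i = int(np.clip(np.searchsorted(hets, het_mode), 0, len(hets) - 1))
    probs[mid_i] = 1.0
    for i in range(mid_i, len(hets) - 1):  # upward: het -> het + 2
        het = hets[i]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    for i in range(mid_i, 0, -1):  # downward: het -> het - 2
        het = hets[i]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[i - 1] = probs[i] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    G: GenotypeMatrix, sample_idx: np.ndarray | None, params: QCParams
) -> tuple[np.ndarray, list[str | None]]:
    """Variant mask (True = keep) and per-variant reason codes on a subset.

    A variant passes iff MAF >= maf_min, HWE exact p >= hwe_p_min and missing
    fraction <= miss_max, all computed on the given samples.  Failing reasons
    are recorded (semicolon-joined when several apply); HWE genotype counts
    come from rounding dosages to the nearest integer.
    """
    d = G.dosage if sample_idx is None else G.dosage[np.asarray(sample_idx), :]
    if d.shape[0] == 0:
        raise ValueError("empty sample subset")
    n, m = d.shape
    miss = np.isnan(d).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)

    mask = np.ones(m, dtype=bool)
    reasons: list[str | None] = [None] * m
    g_round = np.rint(d)
    with np.errstate(invalid="ignore"):
        n_hom_a = (g_round == 0).sum(axis=0)
        n_het_v = (g_round == 1).sum(axis=0)
        n_hom_A = (g_round == 2).sum(axis=0)
    for j in range(m):
        why = []
        if maf[j] < params.maf_min:
            why.append("maf")
        total = n_hom_a[j] + n_het_v[j] + n_hom_A[j]
        if total and hwe_exact(int(n_hom_A[j]), int(n_het_v[j]), int(n_hom_a[j])) < params.hwe_p_min:
            why.append("hwe")
        if miss[j] > params.miss_max:
            why.append("missingness")
        if why:
            mask[j] = False
            reasons[j] = ";".join(why)
    if not mask.any():
        log.warning("qc_filter removed every variant")
    return mask, reasons


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _logistic_irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns (beta, se, converged); convergence is relative log-likelihood
    change below ``tol``.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


#: |beta| beyond which a fit is treated as (quasi-)separated
SEPARATION_BETA = 20.0


def logistic_assoc(
    dosage: np.ndarray, y: np.ndarray, X: np.ndarray | None = None
) -> AssocRecord:
    """Wald test of a dosage effect on a binary group label.

    Fits ``logit P(y=1) = b0 + b1*dosage + covariates`` by IRLS; reports OR,
    95% CI and the two-sided Wald p for ``b1``.  Samples with missing dosage
    are dropped.  Constant dosage gives status ``filtered(constant)``;
    non-convergence or |b1| > 20 gives ``separated`` with no p.
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(dosage)
    if X is not None:
        X = np.asarray(X, dtype=float)
        ok &= ~np.isnan(X).any(axis=1)
    dosage, y = dosage[ok], y[ok]
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    if dosage.std() == 0:
        return AssocRecord(n_used=int(ok.sum()), status="filtered(constant)")
    cols = [np.ones(len(y)), dosage]
    if X is not None:
        cols.extend(np.asarray(X)[ok].T)
    design = np.column_stack(cols)
    beta, se, converged = _logistic_irls(design, y)
    b1, s1 = float(beta[1]), float(se[1])
    if not converged or abs(b1) > SEPARATION_BETA or not np.isfinite(s1):
        return AssocRecord(beta=b1, n_used=len(y), status="separated")
    z = b1 / s1
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssocRecord(
        beta=b1, se=s1, or_=float(np.exp(b1)),
        ci95=(float(np.exp(b1 - 1.96 * s1)), float(np.exp(b1 + 1.96 * s1))),
        p=max(p, 1e-300), n_used=len(y), status="ok",
    )


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def genomic_lambda(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median 1-df chi-square over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def run_gwas(
    G: GenotypeMatrix,
    groups: ExtremeGroups,
    covariates: pd.DataFrame | None = None,
    qc: QCParams | None = None,
) -> GwasRun:
    """Covariate-adjusted logistic GWAS of high-vs-low extreme membership.

    QC (on the union of both tails) precedes association; per-group allele
    frequencies, genomic lambda over ok-status tests, and a deterministic
    (chrom, pos) output order are reported.  Variants failing QC appear with
    ``filtered(<reason>)`` status and no statistics.
    """
    qc = qc or QCParams.gwas_stage()
    low, high = groups.index("low"), groups.index("high")
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both extreme groups must be non-empty")
    used = np.concatenate([low, high])
    y = np.concatenate([np.zeros(len(low)), np.ones(len(high))])
    Xc = None
    cov_names: list[str] = []
    if covariates is not None:
        cov_names = list(covariates.columns)
        Xc = covariates.to_numpy(dtype=float)[used]
        keep = np.std(Xc, axis=0) > 0  # drop constant covariates to keep full rank
        Xc, cov_names = Xc[:, keep], [c for c, k in zip(cov_names, keep) if k]
        if Xc.shape[1] == 0:
            Xc = None

    mask, reasons = qc_filter(G, used, qc)
    d_all = G.dosage[used, :]
    with np.errstate(invalid="ignore"):
        freq_all = np.nanmean(d_all, axis=0) / 2.0
        freq_low = np.nanmean(G.dosage[low, :], axis=0) / 2.0
        freq_high = np.nanmean(G.dosage[high, :], axis=0) / 2.0

    rows = []
    for j in range(G.n_variants):
        base = dict(
            chrom=G.variants["chrom"].iat[j], pos=int(G.variants["pos"].iat[j]),
            id=G.variants["id"].iat[j],
            a1=G.variants["a1"].iat[j], a2=G.variants["a2"].iat[j],
            maf_all=_maf(freq_all[j]), maf_low=_maf(freq_low[j]), maf_high=_maf(freq_high[j]),
        )
        if not mask[j]:
            rows.append(base | dict(beta=np.nan, se=np.nan, or_=np.nan, ci_low=np.nan,
                                    ci_high=np.nan, p=np.nan, n_used=0,
                                    status=f"filtered({reasons[j]})"))
            continue
        rec = logistic_assoc(d_all[:, j], y, Xc)
        rows.append(base | dict(beta=rec.beta, se=rec.se, or_=rec.or_,
                                ci_low=rec.ci95[0], ci_high=rec.ci95[1], p=rec.p,
                                n_used=rec.n_used, status=rec.status))
    records = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    ok_p = records.loc[records["status"] == "ok", "p"].to_numpy()
    lam = genomic_lambda(ok_p) if len(ok_p) else np.nan
    return GwasRun(records, lam, n_cases=len(high), n_controls=len(low),
                   covariate_names=cov_names)


def _maf(freq: float) -> float:
    return float(min(freq, 1.0 - freq)) if np.isfinite(freq) else np.nan


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"expected_neglog10": -np.log10(expected),
                         "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0))})
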