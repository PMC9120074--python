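"""Phenome-wide scan of extreme-group membership against mixed-type traits.

Each trait is regressed on the high-vs-low group indicator (group as the
exposure) plus covariates, with the model chosen by trait type: linear for
continuous, logistic for binary, proportional-odds for ordered categorical,
and one-vs-rest logistic per level for unordered categorical (reporting the
best level with its own Bonferroni factor).  Traits failing the missingness
or category-size filters are excluded with a reason; family-wise control is
Bonferroni over the tests actually performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from extremescan.assoc import _logistic_irls, SEPARATION_BETA
from extremescan.prscore import ExtremeGroups

log = logging.getLogger(__name__)

#: p-values printed as 0 by the underlying fits are clamped here for plotting
PLOT_P_FLOOR = 1e-150


def infer_trait_type(values: pd.Series) -> str:
    """Simple trait-typing rules.

    Exactly two distinct non-missing values -> binary; numeric with more
    than 20 distinct values -> continuous, otherwise ordered categorical;
    non-numeric -> unordered categorical.  All-missing raises.
    """
    v = pd.Series(values).dropna()
    if v.empty:
        raise ValueError("all values missing: degenerate trait")
    nd = v.nunique()
    if nd <= 1:
        return "degenerate"
    if nd == 2:
        return "binary"
    numeric = pd.to_numeric(v, errors="coerce")
    if numeric.notna().all():
        return "continuous" if nd > 20 else "ordered_categorical"
    return "unordered_categorical"


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


@dataclass
class PhewasResult:
    """Scan output: one row per trait plus the family-wise threshold used."""

    records: pd.DataFrame
    n_tests: int
    threshold: float
    alpha: float

    def plot_data(self) -> pd.DataFrame:
        """Signed -log10 p per tested trait (sign of beta), p floored at 1e-150."""
        ok = self.records[self.records["status"] == "tested"]
        p = np.clip(ok["p"].to_numpy(float), PLOT_P_FLOOR, 1.0)
        return pd.DataFrame({
            "trait": ok["trait"],
            "signed_neglog10_p": -np.log10(p) * np.sign(ok["beta"].to_numpy(float)),
        })


def _linear_fit(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float]:
    """OLS slope for column 1 with classic SE and two-sided t-test p."""
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(y) - design.shape[1]
    if dof <= 0:
        return float("nan"), float("nan"), float("nan")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(cov[1, 1]))
    t = coef[1] / se
    return float(coef[1]), se, float(2.0 * stats.t.sf(abs(t), dof))


def _logistic_p(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float]:
    beta, se, converged = _logistic_irls(design, y)
    b, s = float(beta[1]), float(se[1])
    if not converged or abs(b) > SEPARATION_BETA or not np.isfinite(s):
        return b, float("nan"), float("nan")
    return b, s, float(2.0 * stats.norm.sf(abs(b / s)))


def _ordered_fit(y: np.ndarray, design_nc: np.ndarray) -> tuple[float, float, float]:
    """Proportional-odds (ordinal logistic) fit; exposure is column 0."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    model = OrderedModel(y, design_nc, distr="logit")
    res = model.fit(method="bfgs", disp=False, maxiter=200)
    b = float(res.params[0])
    s = float(res.bse[0])
    if not np.isfinite(s):
        return b, float("nan"), float("nan")
    return b, s, float(2.0 * stats.norm.sf(abs(b / s)))


def phewas_scan(
    groups: ExtremeGroups,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    min_category: int = 200,
    max_missing: float = 0.20,
    alpha: float = 0.05,
) -> PhewasResult:
    """Scan every trait for association with high-vs-low membership.

    ``traits`` is indexed by sample id; a ``manifest`` (trait, type) declares
    types, otherwise they are inferred.  Filters mirror an automated phenome
    scan: traits missing in more than ``max_missing`` of the assigned samples
    are excluded; categorical levels with fewer than ``min_category`` answers
    are dropped and the trait excluded if fewer than two levels survive.
    The report flags each tested trait against the Bonferroni threshold and
    a |beta| >= 0.5 magnitude filter.
    """
    labels = np.asarray(groups.labels)
    assigned = labels != "unassigned"
    if not assigned.any():
        raise ValueError("no samples assigned to extreme groups")
    sample_ids = np.asarray(groups.sample_ids)[assigned]
    x = (labels[assigned] == "high").astype(float)
    if x.min() == x.max():
        raise ValueError("group indicator is constant")
    traits = traits.reindex(sample_ids)
    Xc = None
    if covariates is not None:
        Xc = covariates.reindex(sample_ids).to_numpy(dtype=float)
        Xc = Xc[:, np.std(Xc, axis=0) > 0]
        if Xc.shape[1] == 0:
            Xc = None

    declared = {}
    if manifest is not None:
        declared = dict(zip(manifest["trait"], manifest["type"]))
    _CANON = {"continuous": "continuous", "binary": "binary",
              "ordered": "ordered_categorical", "ordered_categorical": "ordered_categorical",
              "unordered": "unordered_categorical", "unordered_categorical": "unordered_categorical"}

    rows = []
    n = len(x)
    for trait in traits.columns:
        col = traits[trait]
        miss = float(col.isna().mean())
        rec = dict(trait=trait, type=None, beta=np.nan, se=np.nan, ci_low=np.nan,
                   ci_high=np.nan, p=np.nan, n_used=0, status="tested", level=None)
        if miss > max_missing:
            rec["status"] = "excluded(missingness)"
            rows.append(rec)
            continue
        try:
            ttype = _CANON.get(declared.get(trait, ""), None) or infer_trait_type(col)
        except ValueError:
            ttype = "degenerate"
        if ttype == "degenerate":
            rec["status"] = "excluded(degenerate)"
            rows.append(rec)
            continue
        rec["type"] = ttype
        ok = col.notna().to_numpy()
        v = col[ok]
        xi = x[ok]
        Xi = Xc[ok] if Xc is not None else None

        if ttype in ("binary", "ordered_categorical", "unordered_categorical"):
            counts = v.value_counts()
            keep_levels = counts[counts >= min_category].index
            if len(keep_levels) < 2:
                rec["status"] = "excluded(category_size)"
                rows.append(rec)
                continue
            if len(keep_levels) < len(counts):
                sel = v.isin(keep_levels).to_numpy()
                v, xi = v[sel], xi[sel]
                Xi = Xi[sel] if Xi is not None else None
                if len(keep_levels) == 2:
                    ttype = rec["type"] = "binary" if ttype == "binary" else ttype
        if v.nunique() < 2 or xi.min() == xi.max():
            rec["status"] = "excluded(degenerate)"
            rows.append(rec)
            continue

        design = np.column_stack([np.ones(len(xi)), xi] +
                                 ([Xi.T[i] for i in range(Xi.shape[1])] if Xi is not None else []))
        try:
            if ttype == "continuous":
                b, s, p = _linear_fit(pd.to_numeric(v).to_numpy(float), design)
            elif ttype == "binary":
                y = (v == sorted(v.unique())[-1]).to_numpy(float)
                b, s, p = _logistic_p(y, design)
            elif ttype == "ordered_categorical":
                y = pd.to_numeric(v).to_numpy(float)
                b, s, p = _ordered_fit(y, design[:, 1:])
            else:  # unordered: one-vs-rest per level, best level x own Bonferroni
                best = (np.nan, np.nan, np.inf, None)
                levels = sorted(v.unique())
                for lev in levels:
                    y = (v == lev).to_numpy(float)
                    b_l, s_l, p_l = _logistic_p(y, design)
                    if np.isfinite(p_l) and p_l < best[2]:
                        best = (b_l, s_l, p_l, lev)
                b, s, p, rec["level"] = best[0], best[1], min(best[2] * len(levels), 1.0), best[3]
                if not np.isfinite(best[2]):
                    b = s = p = np.nan
        except (np.linalg.LinAlgError, ValueError):
            b = s = p = np.nan
        if not np.isfinite(p):
            rec["status"] = "excluded(degenerate)"
            rows.append(rec)
            continue
        rec.update(beta=b, se=s, p=max(p, 1e-300), n_used=int(len(xi)),
                   ci_low=b - 1.96 * s, ci_high=b + 1.96 * s)
        rows.append(rec)

    records = pd.DataFrame(rows)
    n_tests = int((records["status"] == "tested").sum())
    threshold = bonferroni_threshold(alpha, max(n_tests, 1))
    records["passes_bonferroni"] = (records["status"] == "tested") & (records["p"] <= threshold)
    records["passes_magnitude"] = (records["status"] == "tested") & (records["beta"].abs() >= 0.5)
    return PhewasResult(records, n_tests, threshold, alpha)
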