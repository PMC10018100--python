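"""Endophenotype verification: ROC discrimination of unaffected siblings
from controls, patient–sibling intraclass correlation, and clinical
correlation screens.

* ROC: logistic regression on one or more network features; the area under
  the curve is computed by the Mann–Whitney rank identity and its 95% CI
  by DeLong's method.
* ICC: one-way random-effects, single-measurement ICC(1,1) over sibling
  pairs (member order exchangeable), with the F-distribution CI.
* Correlations: Pearson / Spearman / covariate-adjusted partial
  correlations between candidate endophenotypes and clinical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .stats import bh_fdr, partial_correlation

__all__ = [
    "ROCResult",
    "ICCResult",
    "rank_auc",
    "delong_ci",
    "logistic_roc",
    "icc_pairs",
    "clinical_correlation_screen",
]


@dataclass
class ROCResult:
    feature_set: list
    auc_value: float
    ci_lower: float
    ci_upper: float
    n_positive: int
    n_negative: int
    scores: np.ndarray | None = None


@dataclass
class ICCResult:
    parameter_name: str
    icc_value: float
    ci_lower: float
    ci_upper: float
    n_pairs: int
    p_value: float


class UndefinedMetricError(ValueError):
    pass


def rank_auc(scores, labels) -> float:
    """AUC via the Mann–Whitney identity: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_placements(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                    for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size
                    for n in neg])
    return v10, v01


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """DeLong AUC variance -> normal-approximation (1-alpha) CI."""
    v10, v01 = _delong_placements(scores, labels)
    auc = v10.mean()
    var = 0.0
    if v10.size > 1:
        var += v10.var(ddof=1) / v10.size
    if v01.size > 1:
        var += v01.var(ddof=1) / v01.size
    half = sps.norm.ppf(1 - alpha / 2) * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def logistic_roc(features, labels, feature_names: list | None = None
                 ) -> ROCResult:
    """Fit an unpenalised logistic model and evaluate the in-sample ROC.

    Works for a single feature or a combined feature set.  On complete
    separation the fit is degenerate but monotone, so the AUC (1.0) is
    still well defined; a warning is emitted.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("need n > n_features + 1 observations")
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(x.shape[1])]
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    scores = model.decision_function(x)
    auc, lo, hi = delong_ci(scores, y.astype(bool))
    if auc >= 1.0 - 1e-12:
        warnings.warn("classes are completely separated; "
                      "logistic fit is degenerate but the ROC is valid")
    return ROCResult(feature_set=list(feature_names), auc_value=auc,
                     ci_lower=lo, ci_upper=hi,
                     n_positive=int(y.sum()), n_negative=int((1 - y).sum()),
                     scores=scores)


def icc_pairs(pair_values, parameter_name: str = "",
              alpha: float = 0.05) -> ICCResult:
    """One-way random-effects single-measurement ICC(1,1) over pairs.

    ICC = (MSB - MSW) / (MSB + MSW) from the one-way ANOVA over pairs with
    two exchangeable members each; CI via the F distribution (Shrout &
    Fleiss); one-sided p for ICC > 0.
    """
    pairs = np.asarray(pair_values, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pair_values must be (n_pairs, 2)")
    n = pairs.shape[0]
    if n < 3:
        raise ValueError("need >= 3 pairs for a finite CI")
    grand = pairs.mean()
    pair_means = pairs.mean(axis=1)
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((pairs - pair_means[:, None]) ** 2) / n
    if msb + msw == 0:
        raise UndefinedMetricError("zero total variance; ICC undefined")
    if msw == 0:
        icc, f0, p = 1.0, np.inf, 0.0
        lo = hi = 1.0
        return ICCResult(parameter_name, icc, lo, hi, n, p)
    icc = (msb - msw) / (msb + msw)
    f0 = msb / msw
    df1, df2 = n - 1, n  # n(k-1) with k=2
    p = float(sps.f.sf(f0, df1, df2))
    f_l = f0 / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f0 * sps.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + 1)
    hi = (f_u - 1) / (f_u + 1)
    return ICCResult(parameter_name=parameter_name, icc_value=float(icc),
                     ci_lower=float(lo), ci_upper=float(hi), n_pairs=n,
                     p_value=p)


ORDINAL_CLINICAL = ("seizure_frequency", "n_asms")


def clinical_correlation_screen(metrics: pd.DataFrame, clinical: pd.DataFrame,
                                covariates: pd.DataFrame | None = None,
                                method: str = "pearson",
                                fdr: bool = True) -> pd.DataFrame:
    """Correlate every candidate endophenotype with every clinical variable.

    One row per (metric, clinical variable) with r and p; Spearman is used
    for ordinal clinical variables regardless of ``method``.  Constant
    columns are skipped with a warning.
    """
    if method not in ("pearson", "spearman", "partial"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for m in metrics.columns:
        x = metrics[m].to_numpy(dtype=float)
        for c in clinical.columns:
            y = clinical[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4:
                warnings.warn(f"too few observations for {m} vs {c}; skipped")
                continue
            xs, ys = x[ok], y[ok]
            if np.std(xs) == 0 or np.std(ys) == 0:
                warnings.warn(f"constant column in {m} vs {c}; skipped")
                continue
            use = "spearman" if c in ORDINAL_CLINICAL else method
            if use == "spearman":
                r, p = sps.spearmanr(xs, ys)
            elif use == "partial" and covariates is not None:
                r, p = partial_correlation(xs, ys,
                                           covariates.loc[ok].to_numpy(float))
            else:
                r, p = sps.pearsonr(xs, ys)
            rows.append({"metric": m, "clinical": c, "method": use,
                         "n": int(ok.sum()), "r": float(r),
                         "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out
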