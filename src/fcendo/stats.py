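"""Group-level inference: ANCOVA (parametric and Quade rank-based),
nonparametric tests, effect sizes, FDR, partial correlation, and the
control-sample reference interval.

All tests return a :class:`StatResult` so downstream tables are uniform.
The ANCOVA is an ordinary linear model ``y ~ group + covariates`` whose
group F is computed from residual sums of squares of the nested models
(identical to a type-II ANOVA for a single factor plus covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ReferenceInterval",
    "DegenerateDesignError",
    "ancova",
    "ancova_many",
    "quade_ancova",
    "kruskal_wallis",
    "mann_whitney",
    "chi_square_or_fisher",
    "bh_fdr",
    "partial_correlation",
    "reference_interval",
]


class DegenerateDesignError(ValueError):
    """Design matrix is singular or otherwise unusable."""


@dataclass
class StatResult:
    test_name: str
    statistic_value: float
    effect_size: float
    p_raw: float
    df: tuple
    contrast: str = ""
    p_fdr: float | None = None
    pairwise: list["StatResult"] = field(default_factory=list)


@dataclass
class ReferenceInterval:
    """95% normal reference range of a control sample (mean +/- 1.96 sd)."""

    lower: float
    upper: float

    def flag(self, value: float) -> bool:
        """True iff the value falls below the lower reference bound."""
        return bool(value < self.lower)


def _as_2d(covariates) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    c = np.asarray(covariates, dtype=float)
    if c.size == 0:
        return np.empty((0, 0))
    if c.ndim == 1:
        c = c[:, None]
    return c


def _group_dummies(group: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(group).tolist(), key=str)
    dummies = np.column_stack([(group == lv).astype(float)
                               for lv in levels[1:]])
    return dummies, levels


def _ols_rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def ancova(y, group, covariates=None) -> StatResult:
    """Linear-model ANCOVA: F for the group factor adjusting for covariates.

    Partial eta^2 = SS_group / (SS_group + SS_residual).  Pairwise post hoc
    contrasts (same adjusted model per pair) are attached as StatResults.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    cov = _as_2d(covariates)
    n = y.size
    dummies, levels = _group_dummies(group)
    k = len(levels)
    if k < 2:
        raise ValueError("ANCOVA needs >= 2 groups")
    n_cov = cov.shape[1] if cov.size else 0
    if n <= n_cov + k:
        raise ValueError("too few observations for the design")
    ones = np.ones((n, 1))
    x_red = np.hstack([ones, cov]) if n_cov else ones
    x_full = np.hstack([x_red, dummies])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DegenerateDesignError("singular ANCOVA design")
    rss_red = _ols_rss(x_red, y)
    rss_full = _ols_rss(x_full, y)
    df1 = k - 1
    df2 = n - x_full.shape[1]
    ss_group = max(rss_red - rss_full, 0.0)
    if rss_full <= 0:
        f_stat = 0.0 if ss_group <= 0 else np.inf
    else:
        f_stat = (ss_group / df1) / (rss_full / df2)
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    eta_p = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 0.0
    result = StatResult(test_name="ancova", statistic_value=float(f_stat),
                        effect_size=float(eta_p), p_raw=p, df=(df1, df2),
                        contrast=" vs ".join(map(str, levels)))
    for ga, gb in combinations(levels, 2):
        sel = np.isin(group, [ga, gb])
        sub_cov = cov[sel] if n_cov else None
        try:
            pair = _pairwise_ancova(y[sel], group[sel], sub_cov, ga, gb)
        except (ValueError, DegenerateDesignError):
            continue
        result.pairwise.append(pair)
    return result


def _pairwise_ancova(y, group, cov, ga, gb) -> StatResult:
    res = _two_group_fit(y, group, cov, ga, gb)
    return StatResult(test_name="ancova_pairwise", statistic_value=res["t"],
                      effect_size=res["eta_p"], p_raw=res["p"],
                      df=(1, res["df2"]), contrast=f"{ga} vs {gb}")


def _two_group_fit(y, group, cov, ga, gb) -> dict:
    y = np.asarray(y, dtype=float)
    ind = (np.asarray(group) == gb).astype(float)
    cov = _as_2d(cov)
    n = y.size
    ones = np.ones((n, 1))
    x = np.hstack([ones, cov, ind[:, None]]) if cov.size else np.hstack([ones, ind[:, None]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegenerateDesignError("singular pairwise design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df2 = n - x.shape[1]
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(resid @ resid) / df2
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(s2 * xtx_inv[-1, -1])
    t = beta[-1] / se if se > 0 else 0.0
    p = 2 * float(sps.t.sf(abs(t), df2))
    ss_eff = t * t * s2
    eta_p = ss_eff / (ss_eff + float(resid @ resid)) if s2 > 0 else 0.0
    return {"t": float(t), "p": p, "df2": df2, "eta_p": float(eta_p)}


def ancova_many(y_matrix, group, covariates=None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised group-factor ANCOVA over many outcomes sharing one design.

    Returns (F, p, partial eta^2) arrays, one entry per column of
    ``y_matrix``.  Identical to calling :func:`ancova` per column (checked
    in the test suite); used where thousands of outcomes share the design.
    """
    y = np.asarray(y_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    group = np.asarray(group)
    cov = _as_2d(covariates)
    n = y.shape[0]
    dummies, levels = _group_dummies(group)
    k = len(levels)
    ones = np.ones((n, 1))
    x_red = np.hstack([ones, cov]) if cov.size else ones
    x_full = np.hstack([x_red, dummies])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise DegenerateDesignError("singular ANCOVA design")
    q_red, _ = np.linalg.qr(x_red)
    q_full, _ = np.linalg.qr(x_full)
    total = (y ** 2).sum(axis=0)
    rss_red = total - ((q_red.T @ y) ** 2).sum(axis=0)
    rss_full = total - ((q_full.T @ y) ** 2).sum(axis=0)
    df1 = k - 1
    df2 = n - x_full.shape[1]
    ss_group = np.maximum(rss_red - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_group / df1) / (rss_full / df2)
    f = np.where(rss_full > 0, f, np.where(ss_group > 0, np.inf, 0.0))
    p = sps.f.sf(f, df1, df2)
    denom = ss_group + rss_full
    eta = np.divide(ss_group, denom, out=np.zeros_like(ss_group),
                    where=denom > 0)
    return f, p, eta


def quade_ancova(y, group, covariates=None) -> StatResult:
    """Quade's rank analysis of covariance.

    Rank y and each covariate over the whole sample, regress the y-ranks on
    the covariate ranks by OLS, and run a one-way ANOVA F on the residuals
    across groups.  Being rank-based, the test is invariant under strictly
    monotone transforms of y and the covariates.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    cov = _as_2d(covariates)
    n = y.size
    ry = sps.rankdata(y)
    if cov.size:
        rc = np.column_stack([sps.rankdata(cov[:, j])
                              for j in range(cov.shape[1])])
        x = np.hstack([np.ones((n, 1)), rc])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise DegenerateDesignError("singular covariate-rank design")
        beta, *_ = np.linalg.lstsq(x, ry, rcond=None)
        resid = ry - x @ beta
    else:
        resid = ry - ry.mean()
    levels = sorted(pd.unique(group).tolist(), key=str)
    samples = [resid[group == lv] for lv in levels]
    k = len(levels)
    if k < 2:
        raise ValueError("Quade ANCOVA needs >= 2 groups")
    grand = resid.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        f_stat = 0.0 if ss_between <= 0 else np.inf
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    return StatResult(test_name="quade_ancova", statistic_value=float(f_stat),
                      effect_size=float(eta), p_raw=p, df=(df1, df2),
                      contrast=" vs ".join(map(str, levels)))


def kruskal_wallis(y, group) -> StatResult:
    """Kruskal–Wallis H with eta^2_H = (H - k + 1)/(n - k)."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist(), key=str)
    samples = [y[group == lv] for lv in levels]
    h, p = sps.kruskal(*samples)
    k, n = len(levels), y.size
    eta_h = (h - k + 1) / (n - k) if n > k else np.nan
    return StatResult(test_name="kruskal_wallis", statistic_value=float(h),
                      effect_size=float(eta_h), p_raw=float(p), df=(k - 1,),
                      contrast=" vs ".join(map(str, levels)))


def mann_whitney(y, group) -> StatResult:
    """Mann–Whitney U for two groups with rank-biserial effect size."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist(), key=str)
    if len(levels) != 2:
        raise ValueError("Mann–Whitney needs exactly 2 groups")
    a, b = (y[group == lv] for lv in levels)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    rb = 1.0 - 2.0 * u / (len(a) * len(b))  # rank-biserial correlation
    return StatResult(test_name="mann_whitney", statistic_value=float(u),
                      effect_size=float(rb), p_raw=float(p), df=(),
                      contrast=f"{levels[0]} vs {levels[1]}")


def chi_square_or_fisher(table) -> StatResult:
    """Chi-square test of independence, or Fisher's exact test when any
    expected cell count is below 5 (2x2 only).  Phi = sqrt(chi^2 / n)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    chi2, p_chi, dof, expected = sps.chi2_contingency(table, correction=False)
    phi = float(np.sqrt(chi2 / n)) if n > 0 else np.nan
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = sps.fisher_exact(table)
        return StatResult(test_name="fisher_exact", statistic_value=float(chi2),
                          effect_size=phi, p_raw=float(p), df=(int(dof),))
    return StatResult(test_name="chi_square", statistic_value=float(chi2),
                      effect_size=phi, p_raw=float(p_chi), df=(int(dof),))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Correlation of x and y after removing covariates from both.

    Significance by the t statistic with df = n - k - 2 (k covariates).
    With no covariates this is the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = _as_2d(covariates)
    n = x.size
    k = cov.shape[1] if cov.size else 0
    design = np.hstack([np.ones((n, 1)), cov]) if k else np.ones((n, 1))
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx, ry = x - design @ bx, y - design @ by
    # a variable fully explained by the covariates has no unique variance
    tiny_x = (rx @ rx) <= 1e-12 * max(x @ x, 1e-300)
    tiny_y = (ry @ ry) <= 1e-12 * max(y @ y, 1e-300)
    if tiny_x or tiny_y:
        return 0.0, 1.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if df <= 0:
        return r, 1.0
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r * r))
    p = 2 * float(sps.t.sf(abs(t), df))
    return r, p


def reference_interval(control_values) -> ReferenceInterval:
    """95% normal reference range of the control distribution."""
    v = np.asarray(control_values, dtype=float)
    mean, sd = v.mean(), v.std(ddof=1)
    return ReferenceInterval(lower=float(mean - 1.96 * sd),
                             upper=float(mean + 1.96 * sd))
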