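"""Group statistics: feature-grade association and the site screen.

Per feature: tie-corrected Spearman correlation against ISUP grade group
(1-5), two-tailed Mann-Whitney U between the two aggressiveness classes,
Benjamini-Hochberg step-up correction of each p-value family at FDR 0.05,
and a two-way ANOVA screen (institution x class, log scale for positive
features) that drops features with a significant site main effect or
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_COLUMNS, dichotomize  # noqa: F401  (re-exported)

ALPHA = 0.05


def spearman_vs_grade(feature: np.ndarray, grades: np.ndarray) -> tuple[float, float, bool]:
    """Tie-corrected Spearman rho of a feature against grade group, with the
    two-sided t-approximation p. Returns ``(rho, p, degenerate)``; a constant
    feature is degenerate and reported as rho 0, p 1."""
    feature = np.asarray(feature, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if feature.size < 3:
        raise ValueError("need at least 3 tumors")
    if np.unique(grades).size < 2:
        raise ValueError("grades must span at least 2 distinct values")
    if np.unique(feature).size < 2:
        return 0.0, 1.0, True
    rho, p = sps.spearmanr(feature, grades)
    return float(rho), float(p), False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with midrank tie handling."""
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx = ranks[:nx].sum()
    return float(rx - nx * (nx + 1) / 2.0)


def mwu_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact p by enumeration of all group labelings (tie-safe) when the
    combined sample size is at most 12; otherwise the normal approximation
    with continuity and tie correction. Returns ``(U, p)`` with U computed
    for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    u_obs = _u_statistic(x, y)
    nx, ny = len(x), len(y)
    n = nx + ny
    if n <= 12:
        pooled = np.concatenate([x, y])
        mean_u = nx * ny / 2.0
        dev_obs = abs(u_obs - mean_u)
        count = 0
        total = comb(n, nx)
        idx_all = np.arange(n)
        for pick in combinations(range(n), nx):
            pick = np.asarray(pick)
            rest = np.setdiff1d(idx_all, pick, assume_unique=True)
            u = _u_statistic(pooled[pick], pooled[rest])
            if abs(u - mean_u) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class AssociationResult:
    table: pd.DataFrame  # per feature: rho, p_rho, U, p_u, q_rho, q_u, significant flags


def association_analysis(table: pd.DataFrame, features: list[str] | None = None, alpha: float = ALPHA) -> AssociationResult:
    """Spearman-vs-grade and low vs int/high Mann-Whitney per feature, with
    BH correction applied within each statistic's family."""
    features = list(features) if features is not None else [c for c in FEATURE_COLUMNS if c in table.columns]
    grades = table["grade_group"].to_numpy()
    low = table["aggressiveness"] == "low"
    rows = []
    for f in features:
        vals = table[f].to_numpy(dtype=float)
        rho, p_rho, degen = spearman_vs_grade(vals, grades)
        u, p_u = mwu_test(vals[low], vals[~low])
        rows.append({"feature": f, "rho": rho, "p_rho": p_rho, "degenerate": degen, "U": u, "p_u": p_u})
    df = pd.DataFrame(rows)
    df["q_rho"] = bh_adjust(df["p_rho"].to_numpy())
    df["q_u"] = bh_adjust(df["p_u"].to_numpy())
    df["sig_rho"] = df["q_rho"] < alpha
    df["sig_u"] = df["q_u"] < alpha
    return AssociationResult(table=df)


def _screen_transform(x: np.ndarray) -> np.ndarray:
    """log for strictly positive features, raw scale otherwise.

    Log stabilizes multiplicative (gain-like) site effects for positive
    features. Features that span zero are analyzed on the raw scale: a
    data-driven positivity shift would place part of the sample where log
    is steepest, making the residual variance depend on the class and
    badly inflating the interaction F-test.
    """
    x = np.asarray(x, dtype=float)
    if x.min() > 0:
        return np.log(x)
    return x


def anova_site_screen(
    table: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-way ANOVA (type II) of the feature on institution and class,
    on the log scale for strictly positive features.

    A feature is dropped when the institution main effect or the
    institution x class interaction is significant at ``alpha``. Sites
    contributing a single tumor are left out of the screen fit.
    Returns a DataFrame with columns feature, keep, p_site, p_interaction.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    features = list(features) if features is not None else [c for c in FEATURE_COLUMNS if c in table.columns]
    counts = table["site_id"].value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"sites with a single tumor excluded from the site screen: {list(small)}")
    sub = table[~table["site_id"].isin(small)].copy()
    sites_with_both = (
        sub.groupby("site_id")["aggressiveness"].nunique()
    )
    if (sites_with_both >= 2).sum() < 2:
        raise ValueError("need >= 2 sites with both classes represented")
    rows = []
    for f in features:
        d = pd.DataFrame(
            {
                "y": _screen_transform(sub[f].to_numpy(dtype=float)),
                "site": sub["site_id"].to_numpy(),
                "cls": sub["aggressiveness"].to_numpy(),
            }
        )
        if np.allclose(d["y"].std(), 0):
            rows.append({"feature": f, "keep": True, "p_site": 1.0, "p_interaction": 1.0, "reason": "constant"})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ols("y ~ C(site) * C(cls)", data=d).fit()
            aov = sm.stats.anova_lm(model, typ=2)
        p_site = float(aov.loc["C(site)", "PR(>F)"])
        p_int = float(aov.loc["C(site):C(cls)", "PR(>F)"])
        if not np.isfinite(p_site):
            p_site = 1.0
        if not np.isfinite(p_int):
            p_int = 1.0
        keep = (p_site >= alpha) and (p_int >= alpha)
        reason = "" if keep else ("site effect" if p_site < alpha else "interaction")
        rows.append({"feature": f, "keep": keep, "p_site": p_site, "p_interaction": p_int, "reason": reason})
    return pd.DataFrame(rows)
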