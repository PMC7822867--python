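"""Hold-one-institution-out linear-SVM evaluation.

For each institution in turn, a linear SVM is trained on the other sites
and tested on the held-out site. Training runs a stratified, patient-level
10-fold cross-validation in which the misclassification cost C (seven
log-spaced values over 10^-1..10^1) and the feature subset (recursive
feature elimination by smallest absolute weight, one feature per step) are
selected concurrently by lowest mean balanced misclassification error.
Class imbalance is handled with inverse-class-frequency sample weights.
The decision threshold is the Youden-optimal cut on pooled out-of-fold
training scores and is transferred unchanged to the test site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedGroupKFold

from .features import FEATURE_SETS
from .svm import fit_linear_svm

POSITIVE_CLASS = "int_high"  # sensitivity is computed on this class


def make_c_grid() -> np.ndarray:
    """Seven logarithmically spaced misclassification costs, 10^-1 .. 10^1."""
    return 10.0 ** np.linspace(-1.0, 1.0, 7)


@dataclass
class ModelSpec:
    """A trained linear SVM: cost, selected features, scaling, weights, threshold."""

    C: float
    selected_features: list[str]
    youden_threshold: float
    class_weights: dict[str, float]
    coef: np.ndarray = field(repr=False, default=None)
    intercept: float = 0.0
    scale_mean: np.ndarray = field(repr=False, default=None)
    scale_sd: np.ndarray = field(repr=False, default=None)
    cv_error: float = float("nan")

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.selected_features].to_numpy(dtype=float)
        z = (X - self.scale_mean) / self.scale_sd
        return z @ self.coef + self.intercept


@dataclass
class SiteSplitResult:
    held_out_site: str
    feature_set: str
    model: ModelSpec
    test_scores: np.ndarray
    test_labels: np.ndarray  # 1 = int_high, 0 = low
    auc: float
    auc_ci95: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    auc_defined: bool = True


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """L2-regularized squared-hinge linear SVM with balanced class weights
    (identical objective to sklearn's LinearSVC defaults; see pzrad.svm)."""
    return fit_linear_svm(X, y, C)


def _standardize(train: np.ndarray, eps: float = 1e-12):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd < eps, 1.0, sd)
    return mean, sd


def _rfe_path(X: np.ndarray, y: np.ndarray, C: float):
    """Recursive feature elimination path, one feature per step.

    Returns ``[(active_indices, coef, intercept)]`` from all features down
    to one; the model at each entry is trained on exactly those features.
    """
    active = np.arange(X.shape[1])
    path = []
    while active.size >= 1:
        coef, intercept = _fit_svm(X[:, active], y, C)
        path.append((active.copy(), coef, intercept))
        if active.size == 1:
            break
        drop = int(np.argmin(np.abs(coef)))
        active = np.delete(active, drop)
    return path


def _balanced_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    errs = []
    for cls in (0, 1):
        m = y_true == cls
        if m.any():
            errs.append(float((y_pred[m] != cls).mean()))
    return float(np.mean(errs))


def inner_cv_train(
    train_table: pd.DataFrame,
    feature_columns: list[str],
    seed: int,
    n_splits: int = 10,
) -> ModelSpec:
    """Concurrent C / feature-subset selection by stratified patient-level CV.

    Folds stratify by aggressiveness class and group by patient (all tumors
    of a patient share a fold). For every (C, subset size) pair the mean
    balanced misclassification error over the validation folds is recorded;
    the argmin (ties: fewer features, then smaller C) defines the model,
    which is refit on the full training set. The Youden threshold comes from
    the pooled out-of-fold decision scores of the winning configuration.
    """
    y = (train_table["aggressiveness"] == POSITIVE_CLASS).to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("degenerate training set: a class is absent")
    groups = train_table["patient_id"].to_numpy()
    if pd.unique(groups).size < 10:
        raise ValueError("need at least 10 patients for 10-fold patient-level CV")
    X = train_table[list(feature_columns)].to_numpy(dtype=float)
    n_feat = X.shape[1]
    grid = make_c_grid()

    # patient-level class counts limit the number of stratified folds
    pat = pd.DataFrame({"g": groups, "y": y}).groupby("g")["y"].max()
    n_splits = int(min(n_splits, pat.value_counts().min()))
    n_splits = max(n_splits, 2)
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    err = np.zeros((len(grid), n_feat))
    fold_counts = np.zeros((len(grid), n_feat))
    oof_scores = [[[] for _ in range(n_feat)] for _ in grid]
    oof_labels = [[[] for _ in range(n_feat)] for _ in grid]

    for tr_idx, va_idx in cv.split(X, y, groups):
        if y[tr_idx].min() == y[tr_idx].max():
            continue  # fold without both classes carries no information
        mean, sd = _standardize(X[tr_idx])
        Xtr = (X[tr_idx] - mean) / sd
        Xva = (X[va_idx] - mean) / sd
        for ci, C in enumerate(grid):
            for active, coef, intercept in _rfe_path(Xtr, y[tr_idx], C):
                k = active.size
                scores = Xva[:, active] @ coef + intercept
                pred = (scores >= 0).astype(int)
                err[ci, k - 1] += _balanced_error(y[va_idx], pred)
                fold_counts[ci, k - 1] += 1
                oof_scores[ci][k - 1].append(scores)
                oof_labels[ci][k - 1].append(y[va_idx])

    with np.errstate(invalid="ignore"):
        mean_err = np.where(fold_counts > 0, err / np.maximum(fold_counts, 1), np.inf)
    # argmin with ties broken toward fewer features, then smaller C
    best = None
    for ci in range(len(grid)):
        for k in range(1, n_feat + 1):
            cand = (mean_err[ci, k - 1], k, grid[ci])
            if best is None or cand < best:
                best = cand
                best_ci, best_k = ci, k
    best_C = float(grid[best_ci])

    pooled_scores = np.concatenate(oof_scores[best_ci][best_k - 1])
    pooled_labels = np.concatenate(oof_labels[best_ci][best_k - 1])
    thr, _, _ = youden_threshold(pooled_scores, pooled_labels)

    # refit on the full training set with the winning configuration
    mean, sd = _standardize(X)
    Xs = (X - mean) / sd
    path = _rfe_path(Xs, y, best_C)
    active, coef, intercept = next(step for step in path if step[0].size == best_k)
    n1 = int(y.sum())
    n0 = len(y) - n1
    class_weights = {"low": len(y) / (2.0 * n0), POSITIVE_CLASS: len(y) / (2.0 * n1)}
    return ModelSpec(
        C=best_C,
        selected_features=[feature_columns[i] for i in active],
        youden_threshold=float(thr),
        class_weights=class_weights,
        coef=coef.copy(),
        intercept=float(intercept),
        scale_mean=mean[active],
        scale_sd=sd[active],
        cv_error=float(mean_err[best_ci, best_k - 1]),
    )


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, bool]:
    """Threshold maximizing sensitivity + specificity - 1.

    Candidate cuts are midpoints between adjacent sorted unique scores; ties
    break toward the higher threshold (higher specificity). Returns
    ``(threshold, best_J, anti_separated)`` where the flag marks best J <= 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes required")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0]), 0.0, True
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    best_thr, best_j = cands[0], -np.inf
    for t in cands:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and t > best_thr):
            best_thr, best_j = float(t), float(j)
    return best_thr, best_j, best_j <= 0


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = cmp_mat.mean()
    v10 = cmp_mat.mean(axis=1)  # per positive
    v01 = cmp_mat.mean(axis=0)  # per negative
    return float(auc), v10, v01


def roc_auc_ci(scores: np.ndarray, labels: np.ndarray) -> tuple[float, tuple[float, float]]:
    """AUC (midrank / trapezoidal ROC, identical to U/(n1*n0)) with the
    DeLong 95% confidence interval, truncated to [0, 1]."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: only one class present")
    auc, v10, v01 = _delong_components(np.asarray(scores, dtype=float), labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _auc_of(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp_mat = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    return float(cmp_mat.mean())


def delong_compare(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Two-sided p for the difference of two correlated AUCs on the same
    tumors. Returns ``(p, degenerate)``.

    The asymptotic DeLong structural-component z-test is only valid with a
    reasonable number of cases per class; small test sets (as produced by
    holding out a small institution) instead get a model-exchangeability
    sign-swap test on the AUC difference: each tumor's pair of scores is
    swapped between the models, exactly enumerated for up to 14 tumors and
    by 5000 deterministic draws otherwise (used whenever the minority class
    has fewer than 10 cases). A permutation distribution that is identically
    zero, or zero asymptotic variance, is degenerate with p = 1.
    """
    labels = np.asarray(labels, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    n_tot = m + n

    if min(m, n) < 10:
        d_obs = _auc_of(a, labels) - _auc_of(b, labels)
        if n_tot <= 14:
            swaps = ((np.arange(2**n_tot)[:, None] >> np.arange(n_tot)) & 1).astype(bool)
        else:
            rng = np.random.default_rng(1234)
            swaps = rng.random((5000, n_tot)) < 0.5
        diffs = np.empty(len(swaps))
        for i, sw in enumerate(swaps):
            sa = np.where(sw, b, a)
            sb = np.where(sw, a, b)
            diffs[i] = _auc_of(sa, labels) - _auc_of(sb, labels)
        if np.allclose(diffs, 0.0) and abs(d_obs) < 1e-12:
            return 1.0, True
        p = float(np.mean(np.abs(diffs) >= abs(d_obs) - 1e-12))
        return p, False

    auc_a, v10_a, v01_a = _delong_components(a, labels)
    auc_b, v10_b, v01_b = _delong_components(b, labels)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 1.0, True
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z))), False


def site_performance(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[float, float, float]:
    """Balanced accuracy, sensitivity (int/high) and specificity (low) at a
    fixed threshold. A class absent from the test set leaves its member NaN
    and the balanced accuracy equal to the defined member."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    sens = float((pred & (labels == 1)).mean() / max((labels == 1).mean(), 1e-300)) if (labels == 1).any() else np.nan
    spec = float((~pred & (labels == 0)).mean() / max((labels == 0).mean(), 1e-300)) if (labels == 0).any() else np.nan
    parts = [x for x in (sens, spec) if np.isfinite(x)]
    acc = float(np.mean(parts)) if parts else np.nan
    return acc, sens, spec


def paired_site_ttest(metric_a, metric_b) -> tuple[float, bool]:
    """Two-sided paired t-test on per-site metric differences.

    Returns ``(p, degenerate)``; zero-variance differences are degenerate
    with p = 1."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched metrics for at least 3 sites")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0, True
    t, p = sps.ttest_rel(a, b)
    return float(p), False


def hold_one_site_out(
    table: pd.DataFrame,
    feature_sets: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
    site_screen: bool = True,
) -> list[SiteSplitResult]:
    """Train and test once per institution, for each named feature set.

    With ``site_screen`` (the default, leakage-free mode) the two-way ANOVA
    institution screen runs on the training sites only within each split and
    removes flagged features from every feature set before model selection;
    a set emptied by the screen falls back to its least site-affected
    feature.
    """
    from .stats import anova_site_screen

    feature_sets = feature_sets if feature_sets is not None else FEATURE_SETS
    sites = list(pd.unique(table["site_id"]))
    if len(sites) < 2:
        raise ValueError("hold-one-site-out needs at least 2 sites")
    results: list[SiteSplitResult] = []
    for i, held in enumerate(sites):
        train = table[table["site_id"] != held]
        test = table[table["site_id"] == held]
        if train["aggressiveness"].nunique() < 2:
            raise ValueError(f"training union without both classes when holding out {held}")
        all_feats = sorted({f for cols in feature_sets.values() for f in cols})
        if site_screen:
            screen = anova_site_screen(train, features=all_feats)
            kept = set(screen.loc[screen["keep"], "feature"])
            p_site = dict(zip(screen["feature"], screen["p_site"]))
        else:
            kept = set(all_feats)
            p_site = {f: 1.0 for f in all_feats}
        y_test = (test["aggressiveness"] == POSITIVE_CLASS).to_numpy(dtype=int)
        for set_name, cols in feature_sets.items():
            use = [c for c in cols if c in kept]
            if not use:
                use = [max(cols, key=lambda c: p_site.get(c, 0.0))]
            model = inner_cv_train(train, use, seed=seed + 1009 * i)
            scores = model.decision_scores(test)
            if y_test.min() != y_test.max():
                auc, ci = roc_auc_ci(scores, y_test)
                auc_defined = True
            else:
                auc, ci, auc_defined = np.nan, (np.nan, np.nan), False
            acc, sens, spec = site_performance(scores, y_test, model.youden_threshold)
            results.append(
                SiteSplitResult(
                    held_out_site=held,
                    feature_set=set_name,
                    model=model,
                    test_scores=scores,
                    test_labels=y_test,
                    auc=auc,
                    auc_ci95=ci,
                    accuracy=acc,
                    sensitivity=sens,
                    specificity=spec,
                    auc_defined=auc_defined,
                )
            )
    return results


def results_table(results: list[SiteSplitResult]) -> pd.DataFrame:
    """Per-(site, feature set) performance summary, one row each."""
    return pd.DataFrame(
        [
            {
                "held_out_site": r.held_out_site,
                "feature_set": r.feature_set,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci95[0],
                "auc_ci_high": r.auc_ci95[1],
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "C": r.model.C,
                "n_selected": len(r.model.selected_features),
                "selected_features": ";".join(r.model.selected_features),
            }
            for r in results
        ]
    )


def augmentation_tests(
    results: list[SiteSplitResult],
    before: str = "adc_t2w_hist",
    after: str = "adc_t2w_hist_texture",
) -> dict:
    """Added value of texture augmentation: per-site DeLong comparisons of the
    before/after scores plus across-site paired t-tests on AUC and balanced
    accuracy.

    The augmentation analysis is one family of hypotheses, so the overall
    verdict (``significant_augmentation``) applies Benjamini-Hochberg across
    *all* of its p-values (both paired t-tests and every per-site DeLong
    comparison) at FDR 0.05: testing each at 0.05 separately would raise a
    false alarm for a large fraction of null cohorts purely by multiplicity.
    """
    from .stats import bh_adjust

    by = {(r.held_out_site, r.feature_set): r for r in results}
    sites = sorted({r.held_out_site for r in results})
    delong_p = {}
    auc_b, auc_a, acc_b, acc_a = [], [], [], []
    for s in sites:
        rb, ra = by[(s, before)], by[(s, after)]
        if rb.auc_defined and ra.auc_defined:
            p, _ = delong_compare(ra.test_scores, rb.test_scores, rb.test_labels)
            delong_p[s] = p
            auc_b.append(rb.auc)
            auc_a.append(ra.auc)
        acc_b.append(rb.accuracy)
        acc_a.append(ra.accuracy)
    out = {"delong_p_by_site": delong_p}
    if delong_p:
        out["delong_q_by_site"] = dict(zip(delong_p, bh_adjust(list(delong_p.values()))))
    out["paired_t_auc_p"] = paired_site_ttest(auc_a, auc_b)[0] if len(auc_a) >= 3 else np.nan
    out["paired_t_acc_p"] = paired_site_ttest(acc_a, acc_b)[0] if len(acc_a) >= 3 else np.nan

    family = {f"delong_{s}": p for s, p in delong_p.items()}
    family["paired_t_auc"] = out["paired_t_auc_p"]
    family["paired_t_acc"] = out["paired_t_acc_p"]
    family = {k: p for k, p in family.items() if np.isfinite(p)}
    if family:
        q = bh_adjust(list(family.values()))
        out["family_q"] = dict(zip(family, q))
        out["significant_augmentation"] = bool((q < 0.05).any())
    else:
        out["family_q"] = {}
        out["significant_augmentation"] = False
    return out
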