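"""ROC discrimination for single miRNAs and the combined logistic panel,
plus clinical covariate associations and group comparisons.

The AUC is the Mann–Whitney probability of correct pairwise ranking (ties
count one half); its 95% CI uses the DeLong placement-variance estimator.
The combined panel is a logistic regression on standardized log2 values;
in-sample AUC is the default (mirroring apparent-AUC reporting), with a
stratified k-fold cross-validated AUC available, and a ridge-stabilized
fallback when the classes are perfectly separable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._stats import student_t_test

__all__ = [
    "RocCurve",
    "roc_single",
    "MiRNAPanelClassifier",
    "PanelModel",
    "combined_panel_roc",
    "AssociationResult",
    "associate_continuous",
    "associate_binary",
    "compare_clinical_tables",
]


@dataclass
class RocCurve:
    label: str
    auc: float
    ci_low: float
    ci_high: float
    flipped: bool
    n_pos: int
    n_neg: int


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via midranks (ties contribute one half)."""
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from placement values."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n          # P(neg < pos_i)
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m    # P(neg_j < pos)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_single(
    values,
    labels,
    positive: str | int = "QNBC",
    label: str = "",
    allow_flip: bool = True,
) -> RocCurve:
    """Single-marker ROC: rank AUC with DeLong 95% CI.

    For an undirected marker the orientation is chosen so AUC >= 0.5 and a
    flip (the positive class scores lower) is recorded rather than hidden.
    ``allow_flip=False`` keeps the caller's orientation — appropriate for
    scores with a defined direction, like a fitted panel score, where
    flipping would bias a null AUC above one half.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask_pos = labels == positive
    if not mask_pos.any() or mask_pos.all():
        raise ValueError("both classes must be present")
    pos, neg = values[mask_pos], values[~mask_pos]
    auc = _rank_auc(pos, neg)
    flipped = allow_flip and auc < 0.5
    if flipped:
        pos, neg = -pos, -neg
        auc = _rank_auc(pos, neg)
    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * np.sqrt(var)
    return RocCurve(
        label=label,
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        flipped=bool(flipped),
        n_pos=pos.size,
        n_neg=neg.size,
    )


class MiRNAPanelClassifier(BaseEstimator, ClassifierMixin):
    """Logistic combining score over standardized expression values.

    Fits an unpenalized logistic regression; on perfect separation (or a
    failed fit) it falls back to a ridge-penalized fit and flags it in
    ``ridge_fallback_``.  The decision function is a deterministic linear
    score of the member expression values.
    """

    def __init__(self, ridge_c: float = 1.0, max_iter: int = 200):
        self.ridge_c = ridge_c
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("exactly two classes are required")
        y01 = (y == self.classes_[1]).astype(float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale == 0.0, 1.0, scale)
        Z = (X - self.mean_) / self.scale_

        self.ridge_fallback_ = False
        params = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y01, sm.add_constant(Z, has_constant="add")).fit(
                    disp=0, maxiter=self.max_iter
                )
                params = np.asarray(res.params, dtype=float)
                fitted = res.predict()
                separated = np.max(np.abs(fitted - y01)) < 1e-6
                converged = bool(res.mle_retvals.get("converged", False))
                if not np.all(np.isfinite(params)) or separated or not converged:
                    params = None
            except Exception:
                params = None
        if params is None:
            self.ridge_fallback_ = True
            lr = LogisticRegression(C=self.ridge_c, max_iter=max(self.max_iter, 1000))
            lr.fit(Z, y01)
            self.intercept_ = float(lr.intercept_[0])
            self.coef_ = lr.coef_[0].astype(float)
        else:
            self.intercept_ = float(params[0])
            self.coef_ = params[1:]
        return self

    def decision_function(self, X):
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self.intercept_ + Z @ self.coef_

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


@dataclass
class PanelModel:
    members: list[str]
    coef: np.ndarray
    intercept: float
    ridge_fallback: bool
    in_sample: RocCurve
    cross_validated: RocCurve | None = None


def combined_panel_roc(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    positive: str = "QNBC",
    cv: int | None = None,
    seed: int = 0,
) -> PanelModel:
    """Fit the logistic panel and report in-sample (and optional CV) AUC.

    ``matrix`` is samples x miRNAs.  The in-sample AUC mirrors apparent
    (non-cross-validated) reporting; ``cv=k`` adds a stratified k-fold
    out-of-fold AUC on the pooled held-out scores.
    """
    labels = pd.Series(labels).reindex(matrix.index)
    if matrix.isna().any().any() or labels.isna().any():
        raise ValueError("missing values are not allowed")
    X = matrix.to_numpy(dtype=float)
    y = labels.to_numpy()
    clf = MiRNAPanelClassifier().fit(X, y)

    def _oriented(model, data):
        score = model.decision_function(data)
        return score if model.classes_[1] == positive else -score

    scores = _oriented(clf, X)
    in_sample = roc_single(scores, y, positive=positive, label="panel",
                           allow_flip=False)
    cv_curve = None
    if cv:
        oof = np.full(len(y), np.nan)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            fold = MiRNAPanelClassifier().fit(X[train], y[train])
            oof[test] = _oriented(fold, X[test])
        cv_curve = roc_single(oof, y, positive=positive, label="panel_cv",
                              allow_flip=False)
    return PanelModel(
        members=list(matrix.columns),
        coef=clf.coef_,
        intercept=clf.intercept_,
        ridge_fallback=clf.ridge_fallback_,
        in_sample=in_sample,
        cross_validated=cv_curve,
    )


@dataclass
class AssociationResult:
    name: str
    covariate: str
    model: str
    effect: float
    p: float
    extra: dict | None = None


def associate_continuous(values, covariate, name: str = "", covariate_name: str = "") -> AssociationResult:
    """Univariable linear regression: miRNA log2 outcome ~ covariate."""
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 samples are required")
    if np.all(x == x[0]):
        raise ValueError("constant covariate")
    res = stats.linregress(x, y)
    return AssociationResult(
        name=name,
        covariate=covariate_name,
        model="linear",
        effect=float(res.slope),
        p=float(res.pvalue),
        extra=dict(intercept=float(res.intercept), r=float(res.rvalue)),
    )


def associate_binary(values, flag, name: str = "", covariate_name: str = "") -> AssociationResult:
    """Binary covariate: unpaired t-test plus a logistic coefficient p.

    Effect is the mean difference (flag=1 minus flag=0).  The logistic
    model (flag ~ expression) may fail to converge under separation; its
    p is then reported as missing.
    """
    y = np.asarray(values, dtype=float)
    f = np.asarray(flag).astype(int)
    if len(np.unique(f)) != 2:
        raise ValueError("both flag levels must be present")
    a, b = y[f == 1], y[f == 0]
    t, p_t = student_t_test(a, b)
    logit_p = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(f, sm.add_constant(y)).fit(disp=0)
            if np.all(np.isfinite(res.bse)):
                logit_p = float(res.pvalues[1])
        except Exception:
            pass
    return AssociationResult(
        name=name,
        covariate=covariate_name,
        model="t-test+logistic",
        effect=float(np.mean(a) - np.mean(b)),
        p=float(p_t),
        extra=dict(t=t, logistic_p=logit_p),
    )


def compare_clinical_tables(
    clinical: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    variable_types: Mapping[str, str],
    continuous_test: str = "t",
) -> pd.DataFrame:
    """Per-variable group comparison of a clinical table.

    Categorical variables use Fisher's exact test when any expected cell
    count is below 5 (2x2 tables), otherwise chi-squared; continuous
    variables use an unpaired t-test by default (``continuous_test='wilcoxon'``
    switches to Mann–Whitney).  Missing values are dropped per variable;
    all-missing variables are skipped with a warning.
    """
    groups = pd.Series(groups).reindex(clinical.index)
    rows = []
    for var, vtype in variable_types.items():
        col = clinical[var]
        ok = col.notna() & groups.notna()
        if not ok.any():
            warnings.warn(f"{var}: all values missing; skipped")
            continue
        x, g = col[ok], groups[ok]
        if vtype == "categorical":
            table = pd.crosstab(x, g)
            # Pearson chi-squared (no continuity correction); Fisher's exact
            # when any expected 2x2 cell falls below 5
            _, p, _, expected = stats.chi2_contingency(table, correction=False)
            test = "chi2"
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table.to_numpy())
                test = "fisher"
            rows.append(dict(variable=var, test=test, p=float(p)))
        elif vtype == "continuous":
            a = x[g == sorted(g.unique())[0]].to_numpy(dtype=float)
            b = x[g == sorted(g.unique())[1]].to_numpy(dtype=float)
            if continuous_test == "wilcoxon":
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                rows.append(dict(variable=var, test="mannwhitney", p=float(p)))
            else:
                _, p = student_t_test(a, b)
                rows.append(dict(variable=var, test="t", p=float(p)))
        else:
            raise ValueError(f"unknown variable type {vtype!r} for {var}")
    return pd.DataFrame(rows, columns=["variable", "test", "p"])
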