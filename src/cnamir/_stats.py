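"""Shared statistical helpers: geometric means, t-tests, BH adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "geometric_mean_positive",
    "student_t_test",
    "rowwise_t_test",
    "bh_adjust",
]


def geometric_mean_positive(values) -> float:
    """Geometric mean over the strictly positive entries of ``values``.

    Zeros (and negatives, which cannot arise from counts) are excluded so
    that the mean is exactly equivariant under a positive rescaling of the
    input — the property the normalization chain relies on.  Returns 0.0
    when no entry is positive.
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


def student_t_test(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t-test returning ``(t, p)``.

    Degenerate inputs (zero variance in both groups) are resolved
    explicitly: equal means give p = 1, unequal means give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def rowwise_t_test(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Vectorised two-sided unpaired t-test across rows of two matrices.

    ``a`` is (features x n1), ``b`` is (features x n2).  Returns
    ``(t, p)`` arrays.  Rows with zero variance in both groups get
    p = 1 when the means agree and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full(a.shape[0], n1 + n2 - 2, dtype=float)
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    if np.any(degenerate):
        same = degenerate & (diff == 0.0)
        t[same] = 0.0
        p[same] = 1.0
        split = degenerate & (diff != 0.0)
        t[split] = np.sign(diff[split]) * np.inf
        p[split] = 0.0
    return t, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in the p-value rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
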