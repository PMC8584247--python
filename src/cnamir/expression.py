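"""miRNA panel count normalization, differential expression and clustering.

Normalization follows the three-stage geometric-mean scheme used for
NanoString-style count panels:

1. background subtraction — each sample's geometric mean of its negative
   controls is subtracted from every count, flooring at 0;
2. technical (lane) normalization — counts are multiplied by
   ``grand_mean(pos-ctrl geometric means) / this sample's pos-ctrl
   geometric mean``;
3. codeset content normalization — the same factor construction over all
   endogenous probes;
4. ``log2(x + 1)``.

Geometric means are taken over strictly positive counts, which makes the
whole chain exactly invariant to a per-sample global rescaling (a lane
scanning-intensity factor cancels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import bh_adjust, geometric_mean_positive, rowwise_t_test

__all__ = [
    "PROBE_CLASSES",
    "RawCountMatrix",
    "NormalizedMatrix",
    "NanoStringNormalizer",
    "read_count_matrix",
    "write_count_matrix",
    "normalize_counts",
    "differential_expression",
    "ClusteringResult",
    "supervised_clustering",
]

PROBE_CLASSES = ("endogenous", "pos_ctrl", "neg_ctrl", "housekeeping", "spike_in")


@dataclass
class RawCountMatrix:
    """Probe x sample counts with a per-probe class annotation."""

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self):
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class[self.probe_class.isna()].index[:3])
            raise ValueError(f"probes without class annotation: {missing}")
        unknown = set(self.probe_class) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative counts are not allowed")
        for required in ("neg_ctrl", "pos_ctrl"):
            if not (self.probe_class == required).any():
                raise ValueError(f"at least one {required} row is required")

    def rows(self, probe_class: str) -> pd.DataFrame:
        return self.counts.loc[self.probe_class == probe_class]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_count_matrix(path) -> RawCountMatrix:
    """Read a CSV/TSV count matrix: first column probe id, a ``probe_class``
    column, remaining columns sample counts."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if "probe_class" not in df.columns:
        raise ValueError(f"{path}: a probe_class column is required")
    probe_class = df["probe_class"].astype(str)
    counts = df.drop(columns=["probe_class"]).apply(pd.to_numeric)
    if counts.isna().any().any():
        raise ValueError(f"{path}: non-numeric counts present")
    return RawCountMatrix(counts.astype(float), probe_class)


def write_count_matrix(raw: RawCountMatrix, path) -> None:
    out = raw.counts.copy()
    out.insert(0, "probe_class", raw.probe_class)
    out.to_csv(path, float_format="%.6g")


@dataclass
class NormalizedMatrix:
    """log2 endogenous expression plus the per-sample normalization audit."""

    log2: pd.DataFrame
    audit: pd.DataFrame  # columns: background, pos_factor, content_factor


class NanoStringNormalizer(BaseEstimator, TransformerMixin):
    """Three-stage geometric-mean normalizer (sklearn transformer style).

    ``fit`` computes the per-sample background and the positive-control and
    content factors; ``transform`` returns the log2 endogenous matrix.
    The factors are a function of the fitted matrix as a whole (the grand
    means couple samples), so the intended use is ``fit_transform`` on one
    cohort.
    """

    def fit(self, X: RawCountMatrix, y=None):
        counts = X.counts.to_numpy(dtype=float)
        neg = X.rows("neg_ctrl").to_numpy(dtype=float)
        background = np.array(
            [geometric_mean_positive(neg[:, j]) for j in range(neg.shape[1])]
        )
        bg_sub = np.clip(counts - background[None, :], 0.0, None)

        pos_mask = (X.probe_class == "pos_ctrl").to_numpy()
        pos_gm = np.array(
            [geometric_mean_positive(bg_sub[pos_mask, j]) for j in range(bg_sub.shape[1])]
        )
        if (pos_gm == 0).any():
            bad = [s for s, g in zip(X.samples, pos_gm) if g == 0]
            raise ValueError(f"uncorrectable lane(s): zero pos-ctrl geometric mean in {bad}")
        pos_factor = np.mean(pos_gm) / pos_gm
        scaled = bg_sub * pos_factor[None, :]

        endo_mask = (X.probe_class == "endogenous").to_numpy()
        content_gm = np.array(
            [geometric_mean_positive(scaled[endo_mask, j]) for j in range(scaled.shape[1])]
        )
        if (content_gm == 0).any():
            bad = [s for s, g in zip(X.samples, content_gm) if g == 0]
            raise ValueError(f"zero endogenous geometric mean in {bad}")
        content_factor = np.mean(content_gm) / content_gm

        self.background_ = pd.Series(background, index=X.samples)
        self.pos_factor_ = pd.Series(pos_factor, index=X.samples)
        self.content_factor_ = pd.Series(content_factor, index=X.samples)
        normalized = scaled * content_factor[None, :]
        self.log2_ = pd.DataFrame(
            np.log2(normalized[endo_mask] + 1.0),
            index=X.counts.index[endo_mask],
            columns=X.samples,
        )
        return self

    def transform(self, X: RawCountMatrix) -> pd.DataFrame:
        return self.log2_

    def fit_transform(self, X: RawCountMatrix, y=None) -> pd.DataFrame:
        return self.fit(X).log2_


def normalize_counts(raw: RawCountMatrix) -> NormalizedMatrix:
    """Functional wrapper over :class:`NanoStringNormalizer`."""
    norm = NanoStringNormalizer().fit(raw)
    audit = pd.DataFrame(
        dict(
            background=norm.background_,
            pos_factor=norm.pos_factor_,
            content_factor=norm.content_factor_,
        )
    )
    return NormalizedMatrix(norm.log2_, audit)


def differential_expression(
    norm: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str = "QNBC",
    group_b: str = "TNBC",
    p_threshold: float = 0.05,
    q_threshold: float = 0.25,
    equal_var: bool = True,
    min_mean_log2: float | None = None,
) -> pd.DataFrame:
    """Per-miRNA unpaired t-test with Benjamini–Hochberg FDR.

    ``log2fc`` is mean(group_a) - mean(group_b); a probe is ``significant``
    when p < p_threshold and q < q_threshold.  ``min_mean_log2`` optionally
    drops low-expression probes (mean log2 across all samples below the
    floor) before testing; default is no filter.  Result is sorted by p.
    """
    cols_a = [s for s in norm.columns if groups.get(s) == group_a]
    cols_b = [s for s in norm.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    mat = norm
    if min_mean_log2 is not None:
        mat = mat.loc[mat.mean(axis=1) >= min_mean_log2]
    a = mat[cols_a].to_numpy(dtype=float)
    b = mat[cols_b].to_numpy(dtype=float)
    t, p = rowwise_t_test(a, b, equal_var=equal_var)
    q = bh_adjust(p)
    out = pd.DataFrame(
        dict(
            mirna=mat.index,
            log2fc=a.mean(axis=1) - b.mean(axis=1),
            t=t,
            p=p,
            q=q,
        )
    )
    out["significant"] = (out["p"] < p_threshold) & (out["q"] < q_threshold)
    return out.sort_values(["p", "mirna"], kind="mergesort").reset_index(drop=True)


@dataclass
class ClusteringResult:
    sample_order: list[str]
    mirna_order: list[str]
    sample_linkage: np.ndarray
    mirna_linkage: np.ndarray
    metric: str = "pearson"
    linkage: str = "average"
    dropped_rows: list[str] = field(default_factory=list)


def _corr_condensed(X: np.ndarray) -> np.ndarray:
    # Pearson-correlation distance 1 - r, clipped against fp round-off
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def supervised_clustering(
    norm: pd.DataFrame,
    mirnas: Sequence[str] | None = None,
) -> ClusteringResult:
    """Average-linkage hierarchical clustering (1 - Pearson r) on both axes.

    Constant rows have undefined correlations and are dropped with a
    warning.  Leaf orderings are deterministic (scipy tie-break by input
    order).
    """
    mat = norm.loc[list(mirnas)] if mirnas is not None else norm
    if len(mat) < 2:
        raise ValueError("at least 2 miRNAs are required")
    sd = mat.std(axis=1)
    dropped = list(mat.index[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant row(s) from clustering")
        mat = mat.loc[sd > 0.0]
    if len(mat) < 2:
        raise ValueError("fewer than 2 non-constant miRNAs remain")
    X = mat.to_numpy(dtype=float)
    mirna_link = average(_corr_condensed(X))
    sample_link = average(_corr_condensed(X.T))
    return ClusteringResult(
        sample_order=[mat.columns[i] for i in leaves_list(sample_link)],
        mirna_order=[mat.index[i] for i in leaves_list(mirna_link)],
        sample_linkage=sample_link,
        mirna_linkage=mirna_link,
        dropped_rows=dropped,
    )
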