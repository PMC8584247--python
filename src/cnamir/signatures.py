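"""CA20 / CIN25 signature copy-number comparison and expression scores.

CA20 is a 20-gene centrosome-amplification signature; CIN25 is a 25-gene
chromosomal-instability signature.  The CIN25 list circulates with legacy
symbols (CDC2, CNAP1, C20orf24, CDC45L, H2AFZ); a shipped alias table
resolves them against the annotation actually supplied, and symbols that
resolve nowhere are reported as missing rather than silently dropped.

The expression score of a signature is the unweighted sum, per sample, of
log2 median-centered expression over the signature genes: a sample sitting
at every gene's cohort median scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import student_t_test
from .cna import compare_group_gene_cn

__all__ = [
    "CA20_GENES",
    "CIN25_GENES",
    "SYMBOL_ALIASES",
    "SignatureDefinition",
    "signature_cn_comparison",
    "signature_expression_score",
    "stratify_by_gene_percentile",
    "compare_scores",
]

CA20_GENES = (
    "AURKA", "CCNA2", "CCND1", "CCNE2", "CDK1", "CEP63", "CEP152", "E2F1",
    "E2F2", "LMO4", "MDM2", "MYCN", "NDRG1", "NEK2", "PIN1", "PLK1", "PLK4",
    "SASS6", "STIL", "TUBG1",
)

CIN25_GENES = (
    "TPX2", "PRC1", "FOXM1", "CDC2", "C20orf24", "MCM2", "H2AFZ", "TOP2A",
    "PCNA", "UBE2C", "MELK", "TRIP13", "CNAP1", "MCM7", "RNASEH2A",
    "RAD51AP1", "KIF20A", "CDC45L", "MAD2L1", "ESPL1", "CCNB2", "FEN1",
    "TTK", "CCT5", "RFC4",
)

# legacy symbol -> current HGNC symbol
SYMBOL_ALIASES: dict[str, str] = {
    "CDC2": "CDK1",
    "CNAP1": "NCAPD2",
    "C20orf24": "TGIF2",
    "CDC45L": "CDC45",
    "H2AFZ": "H2AZ1",
}


@dataclass(frozen=True)
class SignatureDefinition:
    name: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError(f"signature {self.name} has duplicate symbols")

    def resolve(self, available: Sequence[str]) -> tuple[dict[str, str], list[str]]:
        """Map each printed symbol to an id present in ``available``.

        Returns (mapping printed->resolved, missing printed symbols);
        the alias table is consulted when the printed symbol is absent.
        """
        avail = set(available)
        mapping: dict[str, str] = {}
        missing: list[str] = []
        for symbol in self.gene_symbols:
            if symbol in avail:
                mapping[symbol] = symbol
            elif SYMBOL_ALIASES.get(symbol) in avail:
                mapping[symbol] = SYMBOL_ALIASES[symbol]
            else:
                missing.append(symbol)
        return mapping, missing


CA20 = SignatureDefinition("CA20", CA20_GENES)
CIN25 = SignatureDefinition("CIN25", CIN25_GENES)


def read_signature(path) -> SignatureDefinition:
    """One-symbol-per-line signature file; first line is the name header."""
    lines = [ln.strip() for ln in open(path) if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a name header and >=1 symbol")
    return SignatureDefinition(lines[0], tuple(lines[1:]))


def signature_cn_comparison(
    gene_cn: pd.DataFrame,
    signature: SignatureDefinition,
    groups: Mapping[str, str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-signature-gene group comparison of copy number.

    ``gene_cn`` is a genes x samples table from ``cna.gene_copy_number``
    (either mode).  Unannotated signature genes appear with
    ``missing=True``.
    """
    mapping, missing = signature.resolve(gene_cn.index)
    rows = []
    if mapping:
        tested = compare_group_gene_cn(
            gene_cn.loc[list(mapping.values())], groups, equal_var=equal_var
        )
        for printed, resolved in mapping.items():
            rec = tested.loc[resolved].to_dict()
            rec.update(symbol=printed, resolved_id=resolved, missing=False)
            rows.append(rec)
    for symbol in missing:
        rows.append(dict(symbol=symbol, resolved_id=None, missing=True, tested=False))
    return pd.DataFrame(rows).set_index("symbol")


def signature_expression_score(
    expression: pd.DataFrame,
    signature: SignatureDefinition,
) -> pd.DataFrame:
    """Sum of log2 median-centered expression over signature genes.

    ``expression`` is a genes x samples log2 matrix.  Genes absent from
    the matrix are excluded and reflected in ``n_genes_used``; no gene
    present at all is an error.
    """
    mapping, _missing = signature.resolve(expression.index)
    if not mapping:
        raise ValueError(f"no {signature.name} gene present in the matrix")
    used = list(mapping.values())
    sub = expression.loc[used]
    centered = sub.sub(sub.median(axis=1), axis=0)
    scores = centered.sum(axis=0)
    out = pd.DataFrame(
        dict(sample_id=scores.index, score=scores.to_numpy(), n_genes_used=len(used))
    ).reset_index(drop=True)
    return out


def stratify_by_gene_percentile(
    values: pd.Series,
    percentile: float = 10.0,
) -> tuple[pd.Series, float]:
    """Label samples low/high against an empirical percentile threshold.

    The threshold is the linear-interpolation quantile; ``low`` means
    strictly below it (ties go to ``high``).  Returns (labels, threshold).
    """
    values = pd.Series(values)
    if len(values) < 10:
        raise ValueError("at least 10 samples are required")
    threshold = float(np.percentile(values.to_numpy(dtype=float), percentile))
    labels = pd.Series(
        np.where(values.to_numpy(dtype=float) < threshold, "low", "high"),
        index=values.index,
    )
    return labels, threshold


def compare_scores(
    scores: pd.Series,
    labels: pd.Series,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided unpaired t-test of signature scores between two label classes."""
    scores, labels = pd.Series(scores), pd.Series(labels)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly two label classes are required")
    a = scores[labels == classes[0]].to_numpy(dtype=float)
    b = scores[labels == classes[1]].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both classes need at least 2 members")
    return student_t_test(a, b, equal_var=equal_var)
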