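"""Two-step CNA / miRNA integration and downstream set operations.

Step one maps differentially expressed miRNAs onto cytoband ranges whose
aberration frequency in the reference group passes a threshold and keeps
the pairings whose expression direction agrees with the copy-number
direction (gain & up, or loss & down).  Step two intersects the
consensus-predicted targets of the concordant miRNAs (a target must
appear in at least ``min_db`` of the prediction databases) with the genes
physically located in the retained CNA ranges.  Around these sit a
hypergeometric gene-set overlap test, confidence filtering of a
protein-protein interaction edge table, and per-sample counts of altered
miRNA expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, student_t_test
from .genome import Cytoband, CytobandRange, FeatureLocus, bands_in_range, locate_feature

__all__ = [
    "map_de_mirnas_to_cna_cytobands",
    "concordance_filter",
    "consensus_targets",
    "IntegrationSummary",
    "intersect_targets_with_cna_genes",
    "read_gmt",
    "gene_set_overlap",
    "filter_ppi_edges",
    "per_sample_alteration_count",
]

CONCORDANCE_COLUMNS = (
    "mirna",
    "cytoband_range",
    "direction",
    "frequency_pct",
    "log2fc",
    "p",
    "concordant",
)


def map_de_mirnas_to_cna_cytobands(
    de_results: pd.DataFrame,
    mirna_loci: Sequence[FeatureLocus],
    freq_table: pd.DataFrame,
    cytobands: Sequence[Cytoband],
    min_frequency: float = 0.25,
    group: str = "QNBC",
    significant_only: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Pair significant DE miRNAs with frequent CNA cytoband ranges.

    ``min_frequency`` is a fraction (0.25 keeps ranges with >=25% group
    frequency).  A miRNA is *in* a range when any of its overlapped bands
    belongs to the range's band run.  miRNAs without a locus are excluded
    and returned separately.  Returns ``(records, unmapped_mirnas)``.
    """
    de = de_results[de_results["significant"]] if significant_only else de_results
    loci = {f.feature_id: f for f in mirna_loci}
    chroms = {b.chrom for b in cytobands}

    retained = freq_table[
        (freq_table["group"] == group)
        & (freq_table["frequency_pct"] >= 100.0 * min_frequency)
        & (freq_table["n_affected"] > 0)
    ]
    range_bands: list[tuple[pd.Series, set[str]]] = []
    for _, row in retained.iterrows():
        rng = CytobandRange(
            row["chrom"], "", "", int(row["start"]), int(row["end"])
        )
        range_bands.append((row, set(bands_in_range(rng, cytobands))))

    records, unmapped = [], []
    for _, mi in de.iterrows():
        locus = loci.get(mi["mirna"])
        if locus is None:
            unmapped.append(mi["mirna"])
            continue
        if locus.chrom not in chroms:
            unmapped.append(mi["mirna"])
            warnings.warn(f"{mi['mirna']}: chromosome {locus.chrom} not in cytoband table")
            continue
        mi_bands = set(locate_feature(locus, cytobands))
        for row, bands in range_bands:
            if mi_bands & bands:
                direction = row["direction"]
                fc = float(mi["log2fc"])
                records.append(
                    dict(
                        mirna=mi["mirna"],
                        cytoband_range=row["cytoband_range"],
                        direction=direction,
                        frequency_pct=float(row["frequency_pct"]),
                        log2fc=fc,
                        p=float(mi["p"]),
                        concordant=(direction == "gain" and fc > 0)
                        or (direction == "loss" and fc < 0),
                    )
                )
    if unmapped:
        warnings.warn(f"{len(unmapped)} significant miRNA(s) had no locus")
    return pd.DataFrame(records, columns=list(CONCORDANCE_COLUMNS)), unmapped


def concordance_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep gain&up / loss&down pairings (log2fc == 0 is never concordant)."""
    if records.empty:
        return records.copy()
    keep = (
        ((records["direction"] == "gain") & (records["log2fc"] > 0))
        | ((records["direction"] == "loss") & (records["log2fc"] < 0))
    )
    return records[keep].reset_index(drop=True)


def consensus_targets(
    prediction_tables: Mapping[str, pd.DataFrame],
    min_db: int = 2,
    mirnas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """(miRNA, gene) pairs present in at least ``min_db`` databases.

    Duplicate rows within one table are deduplicated with a warning.
    ``mirnas`` optionally restricts the tables to the selected miRNAs
    before counting.  Returns columns mirna, gene, n_db.
    """
    if len(prediction_tables) < min_db:
        raise ValueError("fewer prediction tables than min_db")
    counts: dict[tuple[str, str], int] = {}
    for db, table in prediction_tables.items():
        pairs = table[["mirna", "gene"]]
        if mirnas is not None:
            pairs = pairs[pairs["mirna"].isin(set(mirnas))]
        if pairs.duplicated().any():
            warnings.warn(f"{db}: duplicate (miRNA, gene) rows deduplicated")
            pairs = pairs.drop_duplicates()
        for mirna, gene in pairs.itertuples(index=False):
            counts[(mirna, gene)] = counts.get((mirna, gene), 0) + 1
    rows = [
        dict(mirna=m, gene=g, n_db=n)
        for (m, g), n in sorted(counts.items())
        if n >= min_db
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "n_db"])


@dataclass
class IntegrationSummary:
    n_targets_before: int
    n_targets_after: int
    reduction_pct: float | None
    genes_before: set[str] = field(default_factory=set)
    genes_after: set[str] = field(default_factory=set)
    surviving_pairs: pd.DataFrame | None = None


def intersect_targets_with_cna_genes(
    consensus: pd.DataFrame,
    cna_genes: Sequence[str],
) -> IntegrationSummary:
    """Second integration step: consensus targets ∩ genes in CNA regions.

    Reduction is 100·(before-after)/before on the unique target genes, or
    missing (None) when the consensus is empty.
    """
    before = set(consensus["gene"]) if len(consensus) else set()
    cna = set(cna_genes)
    after = before & cna
    if not before:
        return IntegrationSummary(0, 0, None, set(), set(), consensus.iloc[0:0])
    surviving = consensus[consensus["gene"].isin(after)].reset_index(drop=True)
    reduction = 100.0 * (len(before) - len(after)) / len(before)
    return IntegrationSummary(
        len(before), len(after), reduction, before, after, surviving
    )


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT gene sets: name -> (description, member genes)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >=3 columns")
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def gene_set_overlap(
    gene_list: Sequence[str],
    gmt_sets: Mapping[str, tuple[str, list[str]]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail overlap test per gene set, BH-corrected.

    ``P(X >= k)`` with k the overlap, against a universe of size N;
    genes in a set but outside the universe are dropped with a warning.
    The boundary convention gives p = 1 at k = 0.
    """
    uni = set(universe)
    query = set(gene_list)
    if not query <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(uni), len(query)
    rows = []
    for name, (_desc, members) in gmt_sets.items():
        inside = set(members) & uni
        if len(inside) < len(set(members)):
            warnings.warn(f"{name}: {len(set(members)) - len(inside)} gene(s) outside universe dropped")
        K = len(inside)
        k = len(inside & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(gene_set=name, overlap=k, set_size=K, p=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def filter_ppi_edges(
    edges: pd.DataFrame,
    min_score: float = 0.9,
    mirna_targets: pd.DataFrame | None = None,
) -> tuple[nx.Graph, list[str]]:
    """Confidence-filter a PPI edge table and attach miRNA-target edges.

    Edges below ``min_score`` and self-loops are removed; gene nodes left
    without any surviving PPI edge are dropped.  miRNA->target edges
    (columns mirna, gene) are then added as a second edge class
    (``kind='mirna_target'``) for targets still in the network.  Returns
    ``(graph, removed_genes)``.
    """
    scores = pd.to_numeric(edges["score"], errors="coerce")
    if scores.isna().any() or (scores < 0).any() or (scores > 1).any():
        raise ValueError("PPI scores must be numeric and within [0, 1]")
    all_nodes = set(edges["node_a"]) | set(edges["node_b"])
    kept = edges[(scores >= min_score) & (edges["node_a"] != edges["node_b"])]
    graph = nx.Graph()
    for a, b, s in kept[["node_a", "node_b", "score"]].itertuples(index=False):
        graph.add_edge(a, b, score=float(s), kind="ppi")
    removed = sorted(all_nodes - set(graph.nodes))
    if mirna_targets is not None:
        for mirna, gene in mirna_targets[["mirna", "gene"]].itertuples(index=False):
            if gene in graph.nodes:
                graph.add_edge(mirna, gene, kind="mirna_target")
    return graph, removed


def per_sample_alteration_count(
    norm: pd.DataFrame,
    concordant: pd.DataFrame,
    groups: Mapping[str, str],
    reference_group: str = "TNBC",
    k_sd: float = 1.0,
) -> tuple[pd.DataFrame, float, float]:
    """Count, per sample, concordant miRNAs with altered expression.

    A miRNA is *altered* in a sample when its log2 expression deviates
    from the reference-group mean by more than ``k_sd`` reference-group
    SDs in the direction of the miRNA's group-level log2fc.  miRNAs with
    zero reference SD are skipped with a warning.  Returns
    ``(per_sample_counts, t, p)`` with the t-test between groups.
    """
    panel = concordant.drop_duplicates("mirna")
    ref_cols = [s for s in norm.columns if groups.get(s) == reference_group]
    if len(ref_cols) < 2:
        raise ValueError("reference group needs at least 2 samples")
    altered = pd.DataFrame(0, index=norm.columns, columns=[], dtype=int)
    counts = pd.Series(0, index=norm.columns, dtype=int)
    for _, row in panel.iterrows():
        mirna, fc = row["mirna"], float(row["log2fc"])
        if mirna not in norm.index:
            raise KeyError(f"{mirna} absent from expression matrix")
        ref = norm.loc[mirna, ref_cols].to_numpy(dtype=float)
        mu, sd = float(np.mean(ref)), float(np.std(ref, ddof=1))
        if sd == 0.0:
            warnings.warn(f"{mirna}: zero reference-group SD; skipped")
            continue
        x = norm.loc[mirna].to_numpy(dtype=float)
        hit = x > mu + k_sd * sd if fc > 0 else x < mu - k_sd * sd
        counts += hit.astype(int)
    per_sample = pd.DataFrame(
        dict(
            sample_id=norm.columns,
            group=[groups[s] for s in norm.columns],
            n_altered=counts.to_numpy(),
        )
    )
    by_group = {g: d["n_altered"].to_numpy(dtype=float) for g, d in per_sample.groupby("group")}
    g1, g2 = sorted(by_group)
    t, p = student_t_test(by_group[g1], by_group[g2])
    return per_sample, t, p
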