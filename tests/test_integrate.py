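"""Concordance mapping, consensus targets, enrichment, PPI filtering."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnamir.genome import FeatureLocus, make_range
from cnamir.integrate import (
    concordance_filter,
    consensus_targets,
    filter_ppi_edges,
    gene_set_overlap,
    intersect_targets_with_cna_genes,
    map_de_mirnas_to_cna_cytobands,
    per_sample_alteration_count,
)


def de_frame(rows):
    df = pd.DataFrame(rows, columns=["mirna", "log2fc", "p"])
    df["q"] = df["p"]
    df["significant"] = True
    return df


def freq_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "cytoband_range", "chrom", "start", "end", "direction",
            "group", "n_affected", "n_samples", "frequency_pct",
        ],
    )


@pytest.fixture
def mapping_setup(toy_cytobands):
    rng8 = make_range("chr8", "p12", "p11.11", toy_cytobands)
    freq = freq_frame([
        [rng8.label, "chr8", rng8.start, rng8.end, "gain", "QNBC", 12, 19, 63.2],
        [rng8.label, "chr8", rng8.start, rng8.end, "loss", "QNBC", 0, 19, 0.0],
    ])
    loci = [FeatureLocus("miR-up", "miRNA", "chr8", 100_000, 100_100)]
    return freq, loci


class TestMapping:
    def test_upregulated_mirna_in_frequent_gain_is_emitted(self, mapping_setup, toy_cytobands):
        freq, loci = mapping_setup
        de = de_frame([["miR-up", 1.2, 0.01]])
        records, unmapped = map_de_mirnas_to_cna_cytobands(
            de, loci, freq, toy_cytobands, min_frequency=0.30
        )
        assert len(records) == 1
        assert records.iloc[0]["concordant"]
        assert unmapped == []

    def test_threshold_above_frequency_excludes(self, mapping_setup, toy_cytobands):
        freq, loci = mapping_setup
        de = de_frame([["miR-up", 1.2, 0.01]])
        records, _ = map_de_mirnas_to_cna_cytobands(
            de, loci, freq, toy_cytobands, min_frequency=0.70
        )
        assert records.empty

    def test_mirna_without_locus_counted_unmapped(self, mapping_setup, toy_cytobands):
        freq, loci = mapping_setup
        de = de_frame([["miR-ghost", 1.0, 0.01]])
        with pytest.warns(UserWarning, match="no locus"):
            records, unmapped = map_de_mirnas_to_cna_cytobands(
                de, loci, freq, toy_cytobands
            )
        assert unmapped == ["miR-ghost"]

    def test_matches_bruteforce_cross_join(self, toy_cytobands, rng):
        ranges = [
            make_range("chr8", "p12", "p11.11", toy_cytobands),
            make_range("chr8", "q11", "q24.21", toy_cytobands),
            make_range("chr4", "p16.3", "p12", toy_cytobands),
        ]
        rows = []
        for i, r in enumerate(ranges):
            for direction in ("gain", "loss"):
                f = float(rng.integers(0, 100))
                rows.append([r.label, r.chrom, r.start, r.end, direction, "QNBC",
                             int(f > 0), 19, f])
        freq = freq_frame(rows)
        loci, de_rows = [], []
        for i in range(25):
            chrom = "chr8" if rng.random() < 0.6 else "chr4"
            start = int(rng.integers(0, 7_000_000 if chrom == "chr8" else 3_900_000))
            loci.append(FeatureLocus(f"m{i}", "miRNA", chrom, start, start + 100))
            de_rows.append([f"m{i}", float(rng.normal()), 0.01])
        de = de_frame(de_rows)
        records, _ = map_de_mirnas_to_cna_cytobands(
            de, loci, freq, toy_cytobands, min_frequency=0.30
        )
        got = set(zip(records["mirna"], records["cytoband_range"], records["direction"]))
        expected = set()
        for locus, (_, de_row) in zip(loci, de.iterrows()):
            for _, f_row in freq.iterrows():
                if f_row["frequency_pct"] < 30 or f_row["n_affected"] == 0:
                    continue
                if locus.chrom != f_row["chrom"]:
                    continue
                if locus.start < f_row["end"] and locus.end > f_row["start"]:
                    expected.add((locus.feature_id, f_row["cytoband_range"], f_row["direction"]))
        assert got == expected

    def test_raising_min_frequency_never_enlarges(self, toy_cytobands, mapping_setup):
        freq, loci = mapping_setup
        de = de_frame([["miR-up", 1.2, 0.01]])
        sizes = []
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            records, _ = map_de_mirnas_to_cna_cytobands(
                de, loci, freq, toy_cytobands, min_frequency=thr
            )
            sizes.append(len(records))
        assert sizes == sorted(sizes, reverse=True)


class TestConcordance:
    def test_direction_rule(self):
        records = pd.DataFrame(
            dict(
                mirna=["a", "b", "c", "d"],
                cytoband_range=["r"] * 4,
                direction=["gain", "gain", "loss", "gain"],
                frequency_pct=[50.0] * 4,
                log2fc=[1.2, -1.2, -0.5, 0.0],
                p=[0.01] * 4,
                concordant=[True, False, True, False],
            )
        )
        kept = concordance_filter(records)
        assert list(kept["mirna"]) == ["a", "c"]

    def test_zero_fc_never_concordant(self):
        records = pd.DataFrame(
            dict(mirna=["z"], cytoband_range=["r"], direction=["gain"],
                 frequency_pct=[99.0], log2fc=[0.0], p=[0.5], concordant=[False])
        )
        assert concordance_filter(records).empty


class TestConsensusTargets:
    def test_two_of_three_kept_one_dropped(self):
        tables = {
            "db1": pd.DataFrame(dict(mirna=["m1", "m1"], gene=["A", "B"])),
            "db2": pd.DataFrame(dict(mirna=["m1"], gene=["A"])),
            "db3": pd.DataFrame(dict(mirna=["m2"], gene=["C"])),
        }
        out = consensus_targets(tables, min_db=2)
        assert list(out.itertuples(index=False)) == [("m1", "A", 2)]

    def test_duplicates_within_table_warn_and_collapse(self):
        tables = {
            "db1": pd.DataFrame(dict(mirna=["m1", "m1"], gene=["A", "A"])),
            "db2": pd.DataFrame(dict(mirna=["m1"], gene=["A"])),
        }
        with pytest.warns(UserWarning, match="duplicate"):
            out = consensus_targets(tables, min_db=2)
        assert out.iloc[0]["n_db"] == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mirnas = [f"m{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(12)]
        tables, sets = {}, {}
        for db in ("d1", "d2", "d3"):
            pairs = {
                (m, g)
                for m in mirnas
                for g in genes
                if rng.random() < 0.25
            }
            tables[db] = pd.DataFrame(sorted(pairs), columns=["mirna", "gene"])
            sets[db] = pairs
        out = consensus_targets(tables, min_db=2)
        got = set(zip(out["mirna"], out["gene"]))
        d1, d2, d3 = sets["d1"], sets["d2"], sets["d3"]
        expected = (d1 & d2) | (d1 & d3) | (d2 & d3)
        assert got == expected

    def test_min_db_monotonicity(self):
        rng = np.random.default_rng(9)
        tables = {
            db: pd.DataFrame(
                sorted({("m", f"g{int(i)}") for i in rng.integers(0, 20, 12)}),
                columns=["mirna", "gene"],
            )
            for db in ("d1", "d2", "d3")
        }
        sizes = [len(consensus_targets(tables, min_db=k)) for k in (1, 2, 3)]
        assert sizes == sorted(sizes, reverse=True)


class TestIntersection:
    def test_printed_reduction(self):
        consensus = pd.DataFrame(
            dict(mirna=["m"] * 4050, gene=[f"g{i}" for i in range(4050)], n_db=2)
        )
        cna_genes = [f"g{i}" for i in range(1239)]
        summary = intersect_targets_with_cna_genes(consensus, cna_genes)
        assert summary.n_targets_before == 4050
        assert summary.n_targets_after == 1239
        assert round(summary.reduction_pct, 1) == 69.4

    def test_disjoint_lists_full_reduction(self):
        consensus = pd.DataFrame(dict(mirna=["m"], gene=["a"], n_db=2))
        summary = intersect_targets_with_cna_genes(consensus, ["b"])
        assert summary.n_targets_after == 0
        assert summary.reduction_pct == 100.0

    def test_empty_consensus_reported_missing(self):
        consensus = pd.DataFrame(columns=["mirna", "gene", "n_db"])
        summary = intersect_targets_with_cna_genes(consensus, ["a"])
        assert summary.reduction_pct is None

    def test_matches_membership_scan(self, rng):
        genes = [f"g{i}" for i in range(200)]
        consensus = pd.DataFrame(
            dict(
                mirna="m",
                gene=[genes[int(i)] for i in rng.choice(200, 80, replace=False)],
                n_db=2,
            )
        )
        cna = [genes[int(i)] for i in rng.choice(200, 100, replace=False)]
        summary = intersect_targets_with_cna_genes(consensus, cna)
        assert summary.genes_after == set(consensus["gene"]) & set(cna)


class TestGeneSetOverlap:
    def test_whole_set_has_minimal_p_among_equal_sizes(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sets = {
            "hit": ("", universe[:10]),
            "other": ("", universe[20:30]),
        }
        out = gene_set_overlap(universe[:10], sets, universe).set_index("gene_set")
        assert out.loc["hit", "p"] < out.loc["other", "p"]

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = gene_set_overlap(universe[:5], {"s": ("", universe[10:15])}, universe)
        assert out.iloc[0]["overlap"] == 0
        # upper-tail convention: P(X >= 0) = 1
        assert out.iloc[0]["p"] <= 1.0 and out.iloc[0]["p"] > 0.5

    def test_matches_exhaustive_enumeration_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:6]
        members = universe[3:10]
        out = gene_set_overlap(query, {"s": ("", members)}, universe)
        k_obs = len(set(query) & set(members))
        # enumerate all draws of |query| from the universe
        N, K, n = 20, len(members), len(query)
        total = 0
        hits = 0
        for combo in itertools.combinations(range(N), n):
            total += 1
            k = sum(1 for c in combo if c in range(3, 10))
            hits += k >= k_obs
        assert out.iloc[0]["p"] == pytest.approx(hits / total, rel=1e-9)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            gene_set_overlap(["zz"], {"s": ("", ["a"])}, ["a", "b"])


class TestPPIFilter:
    def test_low_score_edge_removed(self):
        edges = pd.DataFrame(dict(node_a=["A"], node_b=["B"], score=[0.85]))
        graph, removed = filter_ppi_edges(edges, 0.9)
        assert graph.number_of_edges() == 0
        assert removed == ["A", "B"]

    def test_isolated_gene_removed(self):
        edges = pd.DataFrame(
            dict(node_a=["A", "C"], node_b=["B", "D"], score=[0.95, 0.4])
        )
        graph, removed = filter_ppi_edges(edges, 0.9)
        assert set(graph.nodes) == {"A", "B"}
        assert removed == ["C", "D"]

    def test_mirna_edges_added_for_surviving_targets_only(self):
        edges = pd.DataFrame(dict(node_a=["A"], node_b=["B"], score=[0.95]))
        targets = pd.DataFrame(dict(mirna=["mx", "mx"], gene=["A", "ZZ"]))
        graph, _ = filter_ppi_edges(edges, 0.9, mirna_targets=targets)
        assert graph.has_edge("mx", "A")
        assert "ZZ" not in graph.nodes

    def test_malformed_score_errors(self):
        edges = pd.DataFrame(dict(node_a=["A"], node_b=["B"], score=[1.5]))
        with pytest.raises(ValueError, match="score"):
            filter_ppi_edges(edges)

    def test_matches_bruteforce_degree_filter(self, rng):
        nodes = [f"n{i}" for i in range(25)]
        rows = []
        for _ in range(120):
            a, b = rng.choice(25, 2, replace=False)
            rows.append((nodes[int(a)], nodes[int(b)], float(rng.random())))
        edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
        graph, removed = filter_ppi_edges(edges, 0.7)
        g_ref = nx.Graph()
        g_ref.add_nodes_from(set(edges["node_a"]) | set(edges["node_b"]))
        for a, b, s in rows:
            if s >= 0.7 and a != b:
                g_ref.add_edge(a, b)
        expected_nodes = {n for n in g_ref.nodes if g_ref.degree(n) > 0}
        assert set(graph.nodes) == expected_nodes
        assert set(removed) == set(g_ref.nodes) - expected_nodes


class TestAlterationCounts:
    @staticmethod
    def setup_matrix(rng):
        cols = [f"q{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
        groups = {c: ("QNBC" if c.startswith("q") else "TNBC") for c in cols}
        data = rng.normal(8.0, 0.5, size=(8, 12))
        norm = pd.DataFrame(data, index=[f"m{i}" for i in range(8)], columns=cols)
        concordant = pd.DataFrame(
            dict(mirna=[f"m{i}" for i in range(8)], log2fc=[1.0] * 8)
        )
        return norm, concordant, groups

    def test_sample_at_reference_mean_counts_zero(self, rng):
        norm, concordant, groups = self.setup_matrix(rng)
        ref_mean = norm[[c for c in norm.columns if c.startswith("t")]].mean(axis=1)
        norm["q0"] = ref_mean
        per_sample, _, _ = per_sample_alteration_count(norm, concordant, groups)
        row = per_sample.set_index("sample_id").loc["q0"]
        assert row["n_altered"] == 0

    def test_ten_sd_shift_counts_full_panel(self, rng):
        norm, concordant, groups = self.setup_matrix(rng)
        ref_cols = [c for c in norm.columns if c.startswith("t")]
        shift = norm[ref_cols].mean(axis=1) + 10 * norm[ref_cols].std(axis=1, ddof=1)
        norm["q1"] = shift
        per_sample, _, _ = per_sample_alteration_count(norm, concordant, groups)
        assert per_sample.set_index("sample_id").loc["q1", "n_altered"] == 8

    def test_effect_group_has_higher_mean_counts_across_seeds(self):
        higher = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            norm, concordant, groups = self.setup_matrix(rng)
            q_cols = [c for c in norm.columns if c.startswith("q")]
            norm.loc[:, q_cols] += 1.5  # planted panel-wide upshift in QNBC
            per_sample, _, _ = per_sample_alteration_count(norm, concordant, groups)
            means = per_sample.groupby("group")["n_altered"].mean()
            higher += means["QNBC"] > means["TNBC"]
        assert higher >= 19

    def test_zero_reference_sd_skipped(self, rng):
        norm, concordant, groups = self.setup_matrix(rng)
        ref_cols = [c for c in norm.columns if c.startswith("t")]
        norm.loc["m0", ref_cols] = 3.0  # constant reference row -> skipped
        norm["q1"] = norm[ref_cols].mean(axis=1) + 10 * norm[ref_cols].std(axis=1, ddof=1)
        with pytest.warns(UserWarning, match="zero reference"):
            per_sample, _, _ = per_sample_alteration_count(norm, concordant, groups)
        # the skipped miRNA cannot contribute: even a +10 SD sample caps at 7
        assert per_sample.set_index("sample_id").loc["q1", "n_altered"] == 7
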