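"""Aberration caller, call summaries, cytoband frequencies, gene CN."""

import numpy as np
import pandas as pd
import pytest

from cnamir.cna import (
    CallerParams,
    call_aberrations,
    compare_group_gene_cn,
    cytoband_frequency,
    estimate_noise_sd,
    gene_copy_number,
    read_probe_table,
    summarize_calls,
)
from cnamir.genome import FeatureLocus, make_range
from cnamir._stats import student_t_test


def probe_frame(values, chrom="chr1", spacing=1000):
    starts = np.arange(len(values)) * spacing
    return pd.DataFrame(
        dict(
            probe_id=[f"p{i}" for i in range(len(values))],
            chrom=chrom,
            start=starts,
            end=starts + 60,
            log2_ratio=values,
        )
    )


def oracle_calls(values, params: CallerParams):
    """Independent exhaustive interval-scoring oracle (pure-Python loops).

    Enumerates every interval, keeps scores >= threshold, resolves
    overlaps greedily by (score desc, start asc, length desc), then
    filters by min_probes and the mean-log2 floor.
    """
    n = len(values)
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = max(mad / (0.6745 * np.sqrt(2.0)), params.sigma_floor)
    cands = []
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += values[j]
            length = j - i + 1
            mean = total / length
            score = abs(mean) * np.sqrt(length) / sigma
            if score >= params.score_threshold:
                cands.append((score, i, j + 1, length, mean))
    cands.sort(key=lambda c: (-c[0], c[1], -c[3]))
    accepted = []
    for score, i, e, length, mean in cands:
        if any(e > ai and i < ae for _, ai, ae, _, _ in accepted):
            continue
        accepted.append((score, i, e, length, mean))
    out = []
    for score, i, e, length, mean in accepted:
        if length < params.min_probes or abs(mean) <= params.min_abs_mean_log2:
            continue
        out.append(dict(i=i, e=e, n_probes=length, mean=mean, score=score))
    return sorted(out, key=lambda c: c["i"])


class TestReadProbeTable:
    def test_sorted_output(self, tmp_path):
        df = probe_frame([0.1, 0.2, 0.3, 0.4])
        shuffled = df.sample(frac=1, random_state=3)
        p = tmp_path / "probes.tsv"
        shuffled.to_csv(p, sep="\t", index=False)
        out = read_probe_table(p)
        assert list(out["start"]) == sorted(out["start"])
        pd.testing.assert_frame_equal(out, df)

    def test_nan_log2_errors_with_line(self, tmp_path):
        p = tmp_path / "probes.tsv"
        p.write_text(
            "probe_id\tchrom\tstart\tend\tlog2_ratio\np0\tchr1\t0\t60\t0.1\n"
            "p1\tchr1\t100\t160\tNaN\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_probe_table(p)


class TestCallAberrations:
    def test_flat_profile_yields_no_calls(self):
        calls = call_aberrations(probe_frame([0.0] * 50))
        assert calls.empty

    def test_two_probe_aberration_filtered_by_min_probes(self, rng):
        values = rng.normal(0, 0.05, 60)
        values[30:32] = 1.0
        calls = call_aberrations(probe_frame(values), CallerParams())
        assert all(calls["n_probes"] >= 3)
        assert not ((calls["start"] <= 30_000) & (calls["end"] >= 31_000)).any()

    def test_low_amplitude_excluded_despite_high_score(self, rng):
        values = rng.normal(0, 0.05, 100)
        values[40:50] += 0.20  # mean ~0.20 <= 0.25 floor, score >> 6
        calls = call_aberrations(probe_frame(values), CallerParams())
        assert calls.empty or all(abs(calls["mean_log2"]) > 0.25)

    def test_planted_gain_matches_oracle(self, rng):
        values = rng.normal(0, 0.1, 120)
        values[50:70] += 0.8
        params = CallerParams()
        calls = call_aberrations(probe_frame(values), params)
        expected = oracle_calls(values, params)
        assert len(calls) == len(expected) >= 1
        top = expected[0]
        row = calls.iloc[0]
        assert row["n_probes"] == top["n_probes"]
        assert row["direction"] == "gain"
        assert row["start"] == top["i"] * 1000

    @pytest.mark.parametrize("seed", range(6))
    def test_caller_equals_exhaustive_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        values = rng.normal(0, 0.1, n)
        for _ in range(rng.integers(0, 4)):
            i = int(rng.integers(0, n - 5))
            ln = int(rng.integers(2, 25))
            values[i : i + ln] += rng.choice([-1, 1]) * rng.uniform(0.2, 1.0)
        params = CallerParams()
        calls = call_aberrations(probe_frame(values), params)
        expected = oracle_calls(values, params)
        assert len(calls) == len(expected)
        for row, exp in zip(calls.itertuples(), expected):
            assert row.n_probes == exp["n_probes"]
            assert row.start == exp["i"] * 1000
            assert row.mean_log2 == pytest.approx(exp["mean"])
            assert row.score == pytest.approx(exp["score"])

    def test_calls_never_overlap_and_satisfy_filters(self, rng):
        values = rng.normal(0, 0.1, 200)
        for i in (20, 80, 150):
            values[i : i + 15] += 0.7
        params = CallerParams()
        calls = call_aberrations(probe_frame(values), params).sort_values("start")
        assert (calls["n_probes"] >= params.min_probes).all()
        assert (calls["mean_log2"].abs() > params.min_abs_mean_log2).all()
        assert (calls["score"] >= params.score_threshold).all()
        ends = calls["end"].to_numpy()[:-1]
        starts = calls["start"].to_numpy()[1:]
        assert (starts >= ends).all()

    def test_raising_threshold_never_adds_calls(self, rng):
        values = rng.normal(0, 0.1, 150)
        values[30:45] += 0.6
        values[100:110] -= 0.5
        frame = probe_frame(values)
        previous = None
        for thr in (4.0, 6.0, 8.0, 12.0, 20.0):
            n = len(call_aberrations(frame, CallerParams(score_threshold=thr)))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_short_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="<4 probes"):
            calls = call_aberrations(probe_frame([1.0, 1.0, 1.0]))
        assert calls.empty


class TestSummarizeCalls:
    @staticmethod
    def make_callsets(counts, group):
        sets, groups = {}, {}
        for i, c in enumerate(counts):
            name = f"{group}_{i}"
            sets[name] = pd.DataFrame(dict(start=range(c)))
            groups[name] = group
        return sets, groups

    def test_group_means_match_printed_averages(self):
        # 204 calls over 14 samples and 484 over 19 -> 14.57 and 25.47
        t_counts = [204 // 14 + (1 if i < 204 % 14 else 0) for i in range(14)]
        q_counts = [484 // 19 + (1 if i < 484 % 19 else 0) for i in range(19)]
        sets_t, grp_t = self.make_callsets(t_counts, "TNBC")
        sets_q, grp_q = self.make_callsets(q_counts, "QNBC")
        per_sample, stats, _t, _p = summarize_calls({**sets_t, **sets_q}, {**grp_t, **grp_q})
        means = stats.set_index("group")["mean_calls"]
        assert round(means["TNBC"], 2) == 14.57
        assert round(means["QNBC"], 2) == 25.47

    def test_identical_count_vectors_give_p_one(self):
        sets_a, grp_a = self.make_callsets([5, 7, 9], "QNBC")
        sets_b, grp_b = self.make_callsets([5, 7, 9], "TNBC")
        _, _, t, p = summarize_calls({**sets_a, **sets_b}, {**grp_a, **grp_b})
        assert p == pytest.approx(1.0)
        assert t == pytest.approx(0.0)

    def test_single_sample_group_rejected(self):
        sets_a, grp_a = self.make_callsets([5], "QNBC")
        sets_b, grp_b = self.make_callsets([5, 6], "TNBC")
        with pytest.raises(ValueError, match="<2 samples"):
            summarize_calls({**sets_a, **sets_b}, {**grp_a, **grp_b})


def call_row(chrom, start, end, direction, mean=0.6):
    return dict(
        sample_id="", chrom=chrom, start=start, end=end,
        n_probes=5, mean_log2=mean if direction == "gain" else -mean,
        direction=direction, score=10.0,
    )


class TestCytobandFrequency:
    def test_fifteen_of_nineteen_gives_78_9(self, toy_cytobands):
        rng_ = make_range("chr8", "p12", "p11.11", toy_cytobands)
        callsets, groups = {}, {}
        for i in range(19):
            rows = [call_row("chr8", 100_000, 900_000, "gain")] if i < 15 else []
            callsets[f"Q{i}"] = pd.DataFrame(rows)
            groups[f"Q{i}"] = "QNBC"
        for i in range(2):
            callsets[f"T{i}"] = pd.DataFrame([])
            groups[f"T{i}"] = "TNBC"
        freq = cytoband_frequency(callsets, [rng_], groups)
        row = freq[(freq["group"] == "QNBC") & (freq["direction"] == "gain")].iloc[0]
        assert round(row["frequency_pct"], 1) == 78.9
        assert row["n_affected"] == 15

    def test_no_calls_zero_everywhere(self, toy_cytobands):
        rng_ = make_range("chr8", "p12", "p11.11", toy_cytobands)
        callsets = {s: pd.DataFrame([]) for s in ("a", "b", "c", "d")}
        groups = dict(a="QNBC", b="QNBC", c="TNBC", d="TNBC")
        freq = cytoband_frequency(callsets, [rng_], groups)
        assert (freq["frequency_pct"] == 0).all()

    def test_matches_bruteforce_overlap_count(self, toy_cytobands, rng):
        ranges = [
            make_range("chr8", "p12", "p11.11", toy_cytobands),
            make_range("chr4", "p15", "p12", toy_cytobands),
        ]
        callsets, groups = {}, {}
        for i in range(12):
            rows = []
            for _ in range(int(rng.integers(0, 4))):
                chrom = "chr8" if rng.random() < 0.5 else "chr4"
                s = int(rng.integers(0, 4_000_000))
                rows.append(call_row(chrom, s, s + int(rng.integers(10_000, 2_000_000)),
                                     "gain" if rng.random() < 0.7 else "loss"))
            name = f"s{i}"
            callsets[name] = pd.DataFrame(rows)
            groups[name] = "QNBC" if i < 6 else "TNBC"
        freq = cytoband_frequency(callsets, ranges, groups)
        for _, row in freq.iterrows():
            expected = 0
            for s, g in groups.items():
                if g != row["group"]:
                    continue
                hit = any(
                    c["chrom"] == row["chrom"]
                    and c["direction"] == row["direction"]
                    and c["start"] < row["end"]
                    and c["end"] > row["start"]
                    for c in callsets[s].to_dict("records")
                )
                expected += hit
            assert row["n_affected"] == expected


class TestGeneCopyNumber:
    loci = [FeatureLocus("G1", "protein_coding", "chr1", 10_000, 15_000)]

    def test_mean_probe_over_uniform_probes(self):
        probes = probe_frame([0.6] * 20, spacing=1000)
        cn = gene_copy_number({"s": probes}, self.loci, mode="mean_probe")
        assert cn.loc["G1", "s"] == pytest.approx(0.6)

    def test_interval_neutral_outside_calls(self):
        calls = pd.DataFrame([call_row("chr1", 50_000, 60_000, "gain")])
        cn = gene_copy_number({"s": calls}, self.loci, mode="interval")
        assert cn.loc["G1", "s"] == 0.0

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            gene_copy_number({}, self.loci, mode="median")

    def test_mean_probe_missing_when_uncovered(self):
        probes = probe_frame([0.6] * 5, chrom="chr2")
        cn = gene_copy_number({"s": probes}, self.loci, mode="mean_probe")
        assert np.isnan(cn.loc["G1", "s"])


class TestCompareGroupGeneCN:
    def test_identical_groups_p_one(self):
        cn = pd.DataFrame(
            {"a": [0.1], "b": [0.3], "c": [0.1], "d": [0.3]}, index=["G1"]
        )
        groups = dict(a="QNBC", b="QNBC", c="TNBC", d="TNBC")
        res = compare_group_gene_cn(cn, groups)
        assert res.loc["G1", "p"] == pytest.approx(1.0)

    def test_matches_closed_form_pooled_t(self):
        a = np.array([0.8, 0.6, 0.9, 0.7])
        b = np.array([0.1, 0.0, 0.2])
        cn = pd.DataFrame(
            {f"q{i}": [v] for i, v in enumerate(a)} | {f"t{i}": [v] for i, v in enumerate(b)},
            index=["G1"],
        )
        groups = {f"q{i}": "QNBC" for i in range(4)} | {f"t{i}": "TNBC" for i in range(3)}
        res = compare_group_gene_cn(cn, groups)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert abs(res.loc["G1", "t"]) == pytest.approx(abs(t_manual))

    def test_power_at_three_sigma_shift(self):
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.normal(3.0, 1.0, 19)
            b = rng.normal(0.0, 1.0, 14)
            _, p = student_t_test(a, b)
            hits += p < 0.05
        assert hits / n_rep >= 0.95

    def test_all_missing_gene_flagged_not_tested(self):
        cn = pd.DataFrame({"a": [np.nan], "b": [np.nan], "c": [np.nan], "d": [np.nan]},
                          index=["G1"])
        groups = dict(a="QNBC", b="QNBC", c="TNBC", d="TNBC")
        res = compare_group_gene_cn(cn, groups)
        assert not res.loc["G1", "tested"]


def test_noise_estimator_recovers_sigma():
    rng = np.random.default_rng(4)
    values = rng.normal(0, 0.1, 5000)
    assert estimate_noise_sd(values) == pytest.approx(0.1, rel=0.1)
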