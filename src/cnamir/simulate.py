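"""Synthetic cohort generator with planted ground truth.

Generates everything the pipeline consumes — per-sample aCGH probe
tables, a raw miRNA count matrix with control-probe structure, cytoband
and feature annotations, three target-prediction tables, gene sets, a
PPI edge table and a clinical table — on a toy genome, together with a
manifest of the planted truth so every downstream stage is testable
without external data.

The default ("study") configuration emulates the conditions of the
AR-stratified triple-negative cohort this package targets: 19 vs 14
arrays and 20 vs 12 expression samples, planted frequent segments with
Table-2-style per-group frequencies and gain/loss directions, passenger
CNAs calibrated so expected calls/sample land near 25.5 (QNBC) and 14.6
(TNBC), log-normal counts with planted group fold-changes, and eight
concordant miRNAs physically located inside matching planted segments.
The "noiseless" preset zeroes every noise source and makes the planted
segments group-pure (frequencies 1 and 0) so each pipeline stage's
output is predictable from the manifest in closed form.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Cytoband, CytobandRange, make_range

__all__ = [
    "ToyChromosome",
    "PlantedSegment",
    "MirnaSpec",
    "SimulationConfig",
    "GroundTruthManifest",
    "default_config",
    "generate_cohort",
    "generate_mirna_counts",
    "generate_target_tables",
]

PROBE_LENGTH = 60
FEATURE_LENGTH = 2000

HOUSEKEEPING = ("ACTB", "B2M", "GAPDH", "RPL19", "RPL0")
SPIKE_INS = ("ath-miR-159a", "cel-miR-248", "cel-miR-254", "osa-miR-414", "osa-miR-442")
POS_CONTROL_LEVELS = (8000.0, 2000.0, 500.0, 125.0, 31.25, 7.8)


@dataclass(frozen=True)
class ToyChromosome:
    name: str
    band_names: tuple[str, ...]
    band_size: int = 1_000_000

    @property
    def length(self) -> int:
        return len(self.band_names) * self.band_size

    def bands(self) -> list[tuple[str, int, int]]:
        return [
            (b, i * self.band_size, (i + 1) * self.band_size)
            for i, b in enumerate(self.band_names)
        ]


@dataclass
class PlantedSegment:
    """A recurrent aberration planted at a cytoband range."""

    chrom: str
    first_band: str
    last_band: str
    direction: str
    amplitude: float
    freq_qnbc: float
    freq_tnbc: float

    @property
    def label(self) -> str:
        num = self.chrom[3:] if self.chrom.startswith("chr") else self.chrom
        if self.first_band == self.last_band:
            return f"{num}{self.first_band}"
        return f"{num}{self.first_band}-{self.last_band}"


@dataclass
class MirnaSpec:
    """One endogenous panel probe with its planted truth."""

    mirna_id: str
    log2fc: float = 0.0
    concordant: bool = False
    chrom: str | None = None
    start: int | None = None
    baseline_log2: float = 8.0
    dispersion: float = 0.5


@dataclass
class SimulationConfig:
    seed: int = 0
    n_qnbc: int = 20
    n_tnbc: int = 14
    n_qnbc_acgh: int = 19
    n_tnbc_acgh: int = 14
    n_qnbc_mirna: int = 20
    n_tnbc_mirna: int = 12
    probe_spacing_bp: int = 20_000
    probe_noise_sd: float = 0.1
    passenger_rate_qnbc: float = 21.4
    passenger_rate_tnbc: float = 12.6
    passenger_gain_prob: float = 0.75
    passenger_amp_low: float = 0.5
    passenger_amp_high: float = 0.9
    lane_scale_sd: float = 0.15
    control_noise_sd: float = 0.1
    neg_control_mean: float = 4.0
    n_neg_controls: int = 8
    n_pos_controls: int = 6
    n_consensus_targets_in: int = 7
    n_consensus_targets_out: int = 5
    n_decoy_targets: int = 6
    metastasis_base_rate: float = 0.24
    metastasis_strength: float = 1.2
    toy_genome: list[ToyChromosome] = field(default_factory=list)
    planted_segments: list[PlantedSegment] = field(default_factory=list)
    mirna_panel: list[MirnaSpec] = field(default_factory=list)
    clinical_assoc: dict[str, int] = field(default_factory=dict)

    # -- derived helpers -------------------------------------------------
    def chromosome(self, name: str) -> ToyChromosome:
        for c in self.toy_genome:
            if c.name == name:
                return c
        raise ValueError(f"chromosome {name} not in toy genome")

    def cytobands(self) -> list[Cytoband]:
        stains = ("gneg", "gpos50")
        bands = []
        for chrom in self.toy_genome:
            for i, (name, start, end) in enumerate(chrom.bands()):
                bands.append(Cytoband(chrom.name, start, end, name, stains[i % 2]))
        return bands

    def segment_coords(self, seg: PlantedSegment) -> tuple[int, int]:
        rng = make_range(seg.chrom, seg.first_band, seg.last_band, self.cytobands())
        return rng.start, rng.end

    def segment_range(self, seg: PlantedSegment) -> CytobandRange:
        return make_range(seg.chrom, seg.first_band, seg.last_band, self.cytobands())

    def segment_for_locus(self, chrom: str, start: int) -> int | None:
        for i, seg in enumerate(self.planted_segments):
            s, e = self.segment_coords(seg)
            if seg.chrom == chrom and s <= start < e:
                return i
        return None

    def validate(self) -> None:
        for seg in self.planted_segments:
            self.segment_coords(seg)  # raises if bands are off-genome
            if seg.direction not in ("gain", "loss"):
                raise ValueError(f"{seg.label}: bad direction {seg.direction}")
            if (seg.direction == "gain") != (seg.amplitude > 0):
                raise ValueError(f"{seg.label}: amplitude sign mismatches direction")
            for f in (seg.freq_qnbc, seg.freq_tnbc):
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"{seg.label}: frequency {f} outside [0, 1]")
        ids = [m.mirna_id for m in self.mirna_panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in panel")
        for m in self.mirna_panel:
            if m.dispersion < 0:
                raise ValueError(f"{m.mirna_id}: negative dispersion")
            if m.concordant:
                if m.chrom is None or m.start is None:
                    raise ValueError(f"{m.mirna_id}: concordant miRNA needs a locus")
                idx = self.segment_for_locus(m.chrom, m.start)
                if idx is None:
                    raise ValueError(
                        f"{m.mirna_id}: concordant but outside every planted segment"
                    )
                seg = self.planted_segments[idx]
                if (seg.direction == "gain") != (m.log2fc > 0):
                    raise ValueError(
                        f"{m.mirna_id}: effect direction mismatches segment {seg.label}"
                    )


@dataclass
class GroundTruthManifest:
    """Planted truth: fully determines noiseless pipeline outputs."""

    seed: int
    samples: dict
    carriers: dict            # segment label -> {sample: bool}
    per_sample_segments: dict  # sample -> list of planted/passenger intervals
    mirna_truth: dict          # mirna -> {log2fc, concordant, mapped, segment}
    concordant_mirnas: list
    mapped_mirnas: list
    consensus_pairs: list      # [mirna, gene, n_db]
    decoy_pairs: list
    expected_surviving_genes: list
    ppi_kept_genes: list
    ppi_removed_genes: list
    clinical_assoc: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# default configuration


def _default_genome() -> list[ToyChromosome]:
    p_arm = ("p14", "p13", "p12", "p11")
    q_arm = ("q11", "q12", "q21", "q22", "q23", "q24")
    names = [f"chr{i}" for i in range(1, 13)] + ["chrX"]
    return [ToyChromosome(n, p_arm + q_arm) for n in names]


def _default_segments() -> list[PlantedSegment]:
    return [
        PlantedSegment("chr1", "q21", "q24", "gain", 0.8, 0.632, 0.357),
        PlantedSegment("chr4", "p13", "p11", "loss", -0.8, 0.421, 0.214),
        PlantedSegment("chr6", "p14", "p12", "gain", 0.8, 0.632, 0.286),
        PlantedSegment("chr8", "q11", "q24", "gain", 0.9, 0.789, 0.643),
        PlantedSegment("chr9", "p14", "p12", "gain", 0.8, 0.632, 0.143),
        PlantedSegment("chr12", "p13", "p11", "gain", 0.7, 0.579, 0.143),
        PlantedSegment("chrX", "p13", "p11", "loss", -0.8, 0.421, 0.214),
    ]


_CONCORDANT_PANEL = [
    # (id, chrom, start, log2fc) — effect sign matches the planted direction
    ("hsa-miR-1204", "chr8", 9_300_000, 1.7),
    ("hsa-miR-1265", "chr1", 7_500_000, 1.4),
    ("hsa-miR-1267", "chr6", 2_500_000, 1.2),
    ("hsa-miR-23c", "chr4", 2_500_000, -1.5),
    ("hsa-miR-548ai", "chr6", 1_400_000, 1.6),
    ("hsa-miR-567", "chr9", 1_200_000, 1.5),
    ("hsa-miR-613", "chr12", 1_300_000, 1.3),
    ("hsa-miR-943", "chrX", 2_500_000, -1.8),
]

_DISCORDANT_PANEL = [
    # inside planted ranges but with the OPPOSITE expression direction
    ("hsa-miR-sim-d1", "chr1", 8_500_000, -1.0),
    ("hsa-miR-sim-d2", "chr8", 6_500_000, -0.9),
    ("hsa-miR-sim-d3", "chr9", 2_200_000, -1.1),
    ("hsa-miR-sim-d4", "chr12", 2_800_000, -0.8),
    ("hsa-miR-sim-d5", "chr6", 600_000, -1.2),
    ("hsa-miR-sim-d6", "chr4", 3_500_000, 1.0),
    ("hsa-miR-sim-d7", "chrX", 3_500_000, 0.9),
]

_TABLE3_PANEL = [
    # non-mapped DE miRNAs with printed-magnitude fold changes; three
    # deliberately lack a locus to exercise the unmapped-warning path
    ("hsa-miR-219-5p", "chr2", -0.738),
    ("hsa-miR-127-3p", "chr2", -2.302),
    ("hsa-let-7c", "chr3", -1.953),
    ("hsa-miR-4455", None, -1.504),
    ("hsa-miR-152", "chr3", -1.208),
    ("hsa-miR-335-5p", "chr5", -1.191),
    ("hsa-miR-628-3p", "chr5", -1.062),
    ("hsa-miR-503", "chr7", -0.872),
    ("hsa-miR-643", "chr7", 1.691),
    ("hsa-miR-548b-3p", "chr10", 1.497),
    ("hsa-miR-199b-5p", "chr10", -2.586),
    ("hsa-miR-140-5p", "chr11", -1.788),
    ("hsa-miR-375", "chr11", -1.177),
    ("hsa-miR-518b", None, -1.146),
    ("hsa-miR-384", None, -1.027),
]


def default_config(seed: int = 0, preset: str = "study") -> SimulationConfig:
    """Build the default cohort configuration.

    ``preset='study'`` reproduces the emulated study conditions;
    ``preset='noiseless'`` zeroes all noise sources, sets dispersions to
    zero and makes the planted segments group-pure (carrier frequency 1
    in QNBC, 0 in TNBC) so the whole pipeline is closed-form predictable.
    """
    if preset not in ("study", "noiseless"):
        raise ValueError(f"unknown preset {preset!r}")
    noiseless = preset == "noiseless"
    segments = _default_segments()
    if noiseless:
        for seg in segments:
            seg.freq_qnbc, seg.freq_tnbc = 1.0, 0.0

    disp = 0.0 if noiseless else 0.5
    panel: list[MirnaSpec] = []
    for i, (mid, chrom, start, fc) in enumerate(_CONCORDANT_PANEL):
        panel.append(
            MirnaSpec(mid, fc, True, chrom, start, 8.0 + (i * 37 % 30) / 10.0, disp)
        )
    for i, (mid, chrom, start, fc) in enumerate(_DISCORDANT_PANEL):
        panel.append(
            MirnaSpec(mid, fc, False, chrom, start, 7.5 + (i * 31 % 30) / 10.0, disp)
        )
    for i, (mid, chrom, fc) in enumerate(_TABLE3_PANEL):
        start = None if chrom is None else (i % 9) * 1_000_000 + 120_000
        panel.append(MirnaSpec(mid, fc, False, chrom, start, 7.0 + (i * 29 % 40) / 10.0, disp))
    free_chroms = ("chr2", "chr3", "chr5", "chr7", "chr10", "chr11")
    for i in range(90):
        mid = f"hsa-miR-sim-n{i + 1:03d}"
        if i < 60:
            chrom = free_chroms[i % len(free_chroms)]
            start = (i // len(free_chroms)) * 1_000_000 + 160_000
        else:
            chrom, start = None, None
        panel.append(MirnaSpec(mid, 0.0, False, chrom, start, 5.5 + (i * 17 % 55) / 10.0, disp))

    cfg = SimulationConfig(
        seed=seed,
        probe_noise_sd=0.0 if noiseless else 0.1,
        lane_scale_sd=0.0 if noiseless else 0.15,
        control_noise_sd=0.0 if noiseless else 0.1,
        passenger_rate_qnbc=0.0 if noiseless else 21.4,
        passenger_rate_tnbc=0.0 if noiseless else 12.6,
        toy_genome=_default_genome(),
        planted_segments=segments,
        mirna_panel=panel,
        clinical_assoc={
            "hsa-miR-548ai": 1,
            "hsa-miR-567": 1,
            "hsa-miR-1265": 1,
            "hsa-miR-1267": 1,
            "hsa-miR-23c": -1,
        },
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation

SLOT_LEN = 300_000     # passenger segment length in bp (15 probes at 20 kb)
SLOT_STRIDE = 1_000_000
SLOT_OFFSET = 500_000
SLOT_MARGIN = 700_000  # clearance around planted ranges (> 2x passenger len)


def passenger_slots(config: SimulationConfig) -> list[tuple[str, int, int]]:
    """Fixed non-overlapping slots where passenger CNAs may land.

    Slots keep a clearance of more than twice the passenger length from
    every planted range and from each other, so the greedy caller never
    merges neighbouring aberrations.
    """
    planted = {}
    for seg in config.planted_segments:
        planted.setdefault(seg.chrom, []).append(config.segment_coords(seg))
    slots = []
    for chrom in config.toy_genome:
        k = 0
        while True:
            s = k * SLOT_STRIDE + SLOT_OFFSET
            e = s + SLOT_LEN
            k += 1
            if e > chrom.length:
                break
            clear = all(
                e + SLOT_MARGIN <= ps or s >= pe + SLOT_MARGIN
                for ps, pe in planted.get(chrom.name, [])
            )
            if clear:
                slots.append((chrom.name, s, e))
    return slots


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    q = [f"QNBC_{i + 1:02d}" for i in range(config.n_qnbc)]
    t = [f"TNBC_{i + 1:02d}" for i in range(config.n_tnbc)]
    return q, t


def _draw_carriers(config: SimulationConfig, rng) -> dict[str, dict[str, bool]]:
    q, t = _sample_names(config)
    carriers: dict[str, dict[str, bool]] = {}
    for seg in config.planted_segments:
        row = {}
        for s in q:
            row[s] = bool(rng.random() < seg.freq_qnbc)
        for s in t:
            row[s] = bool(rng.random() < seg.freq_tnbc)
        carriers[seg.label] = row
    return carriers


def _draw_passengers(config: SimulationConfig, samples_with_group, rng):
    slots = passenger_slots(config)
    out: dict[str, list[dict]] = {}
    for sample, group in samples_with_group:
        rate = (
            config.passenger_rate_qnbc if group == "QNBC" else config.passenger_rate_tnbc
        )
        count = 0 if rate == 0 else min(int(rng.poisson(rate)), len(slots))
        chosen = rng.choice(len(slots), size=count, replace=False) if count else []
        events = []
        for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
            chrom, s, e = slots[idx]
            gain = rng.random() < config.passenger_gain_prob
            amp = float(rng.uniform(config.passenger_amp_low, config.passenger_amp_high))
            events.append(
                dict(
                    chrom=chrom,
                    start=s,
                    end=e,
                    direction="gain" if gain else "loss",
                    amplitude=amp if gain else -amp,
                    kind="passenger",
                )
            )
        out[sample] = events
    return out


def _probe_grid(chrom: ToyChromosome, spacing: int) -> np.ndarray:
    return np.arange(0, chrom.length - PROBE_LENGTH + 1, spacing, dtype=int)


def _write_probe_table(path, config, segments, rng) -> None:
    rows = []
    for chrom in config.toy_genome:
        starts = _probe_grid(chrom, config.probe_spacing_bp)
        values = np.zeros(starts.size)
        for seg in segments:
            if seg["chrom"] != chrom.name:
                continue
            inside = (starts >= seg["start"]) & (starts < seg["end"])
            values[inside] += seg["amplitude"]
        if config.probe_noise_sd > 0:
            values = values + rng.normal(0.0, config.probe_noise_sd, starts.size)
        for i, (s, v) in enumerate(zip(starts, values)):
            rows.append(
                f"{chrom.name}_{i:04d}\t{chrom.name}\t{s}\t{s + PROBE_LENGTH}\t{v:.4f}"
            )
    Path(path).write_text(
        "probe_id\tchrom\tstart\tend\tlog2_ratio\n" + "\n".join(rows) + "\n"
    )


def generate_mirna_counts(
    config: SimulationConfig,
    carriers: Mapping[str, Mapping[str, bool]],
    samples_with_group: Sequence[tuple[str, str]],
    rng,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Raw count matrix (probes x samples) with probe classes.

    Endogenous counts are log-normal around ``baseline_log2`` with a
    multiplicative group effect ``2**log2fc``; concordant miRNAs receive
    their effect only in carrier samples of their planted segment.
    Returns ``(counts, probe_class, signal_log2)`` where ``signal_log2``
    holds the pre-lane-scale endogenous log2 signal (used for the
    clinical association draw).
    """
    for m in config.mirna_panel:
        if m.dispersion < 0:
            raise ValueError(f"{m.mirna_id}: negative dispersion")
    samples = [s for s, _ in samples_with_group]
    group_of = dict(samples_with_group)
    seg_labels = [seg.label for seg in config.planted_segments]

    index, classes, data = [], [], []
    signal_rows = {}
    for m in config.mirna_panel:
        seg_label = None
        if m.chrom is not None and m.start is not None:
            idx = config.segment_for_locus(m.chrom, m.start)
            if idx is not None:
                seg_label = seg_labels[idx]
        row = np.empty(len(samples))
        for j, s in enumerate(samples):
            if m.concordant:
                active = seg_label is not None and carriers[seg_label][s]
            else:
                active = group_of[s] == "QNBC" and m.log2fc != 0.0
            log2val = m.baseline_log2 + (m.log2fc if active else 0.0)
            if m.dispersion > 0:
                log2val += rng.normal(0.0, m.dispersion)
            row[j] = log2val
        signal_rows[m.mirna_id] = row.copy()
        index.append(m.mirna_id)
        classes.append("endogenous")
        data.append(2.0**row)

    def _control_rows(names, levels, probe_class):
        for name, level in zip(names, levels):
            noise = (
                rng.normal(0.0, config.control_noise_sd, len(samples))
                if config.control_noise_sd > 0
                else np.zeros(len(samples))
            )
            index.append(name)
            classes.append(probe_class)
            data.append(level * 2.0**noise)

    _control_rows(HOUSEKEEPING, [2.0**10] * len(HOUSEKEEPING), "housekeeping")
    _control_rows(
        [f"POS_{chr(65 + i)}" for i in range(config.n_pos_controls)],
        POS_CONTROL_LEVELS[: config.n_pos_controls],
        "pos_ctrl",
    )
    _control_rows(
        [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_controls)],
        [config.neg_control_mean] * config.n_neg_controls,
        "neg_ctrl",
    )
    _control_rows(SPIKE_INS, [2.0**7] * len(SPIKE_INS), "spike_in")

    counts = pd.DataFrame(np.vstack(data), index=index, columns=samples)
    if config.lane_scale_sd > 0:
        lane = 2.0 ** rng.normal(0.0, config.lane_scale_sd, len(samples))
        counts = counts * lane[None, :]
    probe_class = pd.Series(classes, index=index, name="probe_class")
    signal = pd.DataFrame(signal_rows, index=samples).T
    return counts, probe_class, signal


def _gene_annotation(config: SimulationConfig):
    """Gene loci: signature homologs plus in-range / out-of-range target pools."""
    from .signatures import CA20_GENES, CIN25_GENES, SYMBOL_ALIASES

    resolved = []
    for sym in CA20_GENES + CIN25_GENES:
        sym = SYMBOL_ALIASES.get(sym, sym)
        if sym not in resolved:
            resolved.append(sym)
    genes: list[tuple[str, str, int]] = []  # (id, chrom, start)
    # three CIN25 genes land inside the chr12 planted gain
    special = {"RAD51AP1": 1_200_000, "FOXM1": 1_500_000, "NCAPD2": 1_800_000}
    free_chroms = ("chr2", "chr3", "chr5", "chr7", "chr10", "chr11")
    k = 0
    for sym in resolved:
        if sym in special:
            genes.append((sym, "chr12", special[sym]))
        else:
            chrom = free_chroms[k % len(free_chroms)]
            start = (k // len(free_chroms)) * SLOT_STRIDE + 50_000
            genes.append((sym, chrom, start))
            k += 1
    # in-range target pool: spread over the planted ranges
    ranges = [(seg.chrom,) + config.segment_coords(seg) for seg in config.planted_segments]
    gin = []
    for i in range(40):
        chrom, s, e = ranges[i % len(ranges)]
        pos = s + 40_000 + (i // len(ranges)) * 150_000
        if pos + FEATURE_LENGTH > e:
            pos = e - FEATURE_LENGTH - 1_000
        name = f"GIN{i + 1:03d}"
        genes.append((name, chrom, pos))
        gin.append(name)
    # out-of-range pool: free chromosomes, between passenger slots
    gout = []
    for i in range(60):
        chrom = free_chroms[i % len(free_chroms)]
        start = (i // len(free_chroms)) * SLOT_STRIDE + 90_000
        name = f"GOUT{i + 1:03d}"
        genes.append((name, chrom, start))
        gout.append(name)
    return genes, gin, gout


def generate_target_tables(
    config: SimulationConfig,
    mapped_mirnas: Sequence[str],
    gin: Sequence[str],
    gout: Sequence[str],
    rng,
):
    """Three prediction tables with planted consensus targets and decoys.

    Every planted consensus pair appears in >=2 of the 3 databases; every
    decoy appears in exactly 1.  Returns
    ``(tables, consensus_pairs, decoy_pairs)``.
    """
    dbs = ("dianamicrot", "mirdb", "targetscan")
    rows: dict[str, list[tuple[str, str]]] = {db: [] for db in dbs}
    consensus_pairs, decoy_pairs = [], []
    for mirna in mapped_mirnas:
        t_in = [gin[int(i)] for i in rng.choice(len(gin), config.n_consensus_targets_in, replace=False)]
        t_out = [gout[int(i)] for i in rng.choice(len(gout), config.n_consensus_targets_out, replace=False)]
        for gene in t_in + t_out:
            n_db = 3 if rng.random() < 0.3 else 2
            for d in rng.choice(len(dbs), size=n_db, replace=False):
                rows[dbs[int(d)]].append((mirna, gene))
            consensus_pairs.append([mirna, gene, n_db])
        used = set(t_in) | set(t_out)
        decoy_pool = [g for g in list(gin) + list(gout) if g not in used]
        for i in rng.choice(len(decoy_pool), config.n_decoy_targets, replace=False):
            gene = decoy_pool[int(i)]
            db = dbs[int(rng.integers(len(dbs)))]
            rows[db].append((mirna, gene))
            decoy_pairs.append([mirna, gene, db])
    tables = {
        db: pd.DataFrame(sorted(pairs), columns=["mirna", "gene"]) for db, pairs in rows.items()
    }
    return tables, consensus_pairs, decoy_pairs


def _build_gmt(universe, survivors, rng):
    sets = {}
    surv = sorted(survivors)
    take = min(15, len(surv))
    chosen = [surv[int(i)] for i in rng.choice(len(surv), take, replace=False)] if surv else []
    sets["SET_SURVIVOR_ENRICHED"] = ("planted-enriched set", sorted(chosen))
    uni = sorted(universe)
    for k in range(5):
        members = sorted(uni[int(i)] for i in rng.choice(len(uni), 12, replace=False))
        sets[f"SET_RANDOM_{k + 1}"] = ("random background set", members)
    return sets


def _build_ppi(survivors, rng):
    surv = sorted(survivors)
    n_keep = max(2, int(round(0.75 * len(surv))))
    perm = [surv[int(i)] for i in rng.permutation(len(surv))]
    kept, dropped = perm[:n_keep], perm[n_keep:]
    edges = []
    for a, b in zip(kept, kept[1:]):
        edges.append((a, b, float(rng.uniform(0.9, 0.99))))
    for i in range(0, len(kept) - 2, 3):  # extra hub edges
        edges.append((kept[i], kept[i + 2], float(rng.uniform(0.9, 0.99))))
    for g in dropped:
        partner = kept[int(rng.integers(len(kept)))]
        edges.append((g, partner, float(rng.uniform(0.3, 0.7))))
    df = pd.DataFrame(edges, columns=["node_a", "node_b", "score"])
    return df, sorted(kept), sorted(dropped)


def _clinical_table(config, samples_with_group, signal, rng) -> pd.DataFrame:
    samples = [s for s, _ in samples_with_group]
    n = len(samples)
    age = rng.normal(51.75, 10.22, n)
    size = np.clip(rng.normal(2.96, 1.82, n), 0.3, None)
    node = (rng.random(n) < 0.44).astype(int)
    recurrence = (rng.random(n) < 0.12).astype(int)
    race = np.where(rng.random(n) < 0.41, "AA", "EA")

    base_logit = np.log(config.metastasis_base_rate / (1 - config.metastasis_base_rate))
    zbar = np.zeros(n)
    assoc = [(m, s) for m, s in config.clinical_assoc.items() if m in signal.index]
    if assoc:
        for j, s in enumerate(samples):
            if s not in signal.columns:
                continue
            zs = []
            for mirna, sign in assoc:
                row = signal.loc[mirna]
                sd = row.std()
                if sd > 0:
                    zs.append(sign * (row[s] - row.mean()) / sd)
            zbar[j] = np.mean(zs) if zs else 0.0
    p_met = 1.0 / (1.0 + np.exp(-(base_logit + config.metastasis_strength * zbar)))
    metastasis = (rng.random(n) < p_met).astype(int)
    return pd.DataFrame(
        dict(
            sample_id=samples,
            group=[g for _, g in samples_with_group],
            age=np.round(age, 2),
            tumor_size_cm=np.round(size, 2),
            node_positive=node,
            distant_metastasis=metastasis,
            recurrence=recurrence,
            race=race,
        )
    )


def generate_cohort(config: SimulationConfig, outdir) -> GroundTruthManifest:
    """Write the full synthetic cohort to ``outdir`` and return the manifest.

    Identical configurations (same seed) yield byte-identical outputs.
    Raises if a planted segment falls outside the toy genome.
    """
    config.validate()
    outdir = Path(outdir)
    for sub in ("acgh", "annotations", "targets"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    qnbc, tnbc = _sample_names(config)
    acgh_samples = [(s, "QNBC") for s in qnbc[: config.n_qnbc_acgh]] + [
        (s, "TNBC") for s in tnbc[: config.n_tnbc_acgh]
    ]
    mirna_samples = [(s, "QNBC") for s in qnbc[: config.n_qnbc_mirna]] + [
        (s, "TNBC") for s in tnbc[: config.n_tnbc_mirna]
    ]
    all_samples = [(s, "QNBC") for s in qnbc] + [(s, "TNBC") for s in tnbc]

    carriers = _draw_carriers(config, rng)
    passengers = _draw_passengers(config, all_samples, rng)

    per_sample_segments: dict[str, list[dict]] = {}
    for sample, _group in all_samples:
        events = []
        for seg in config.planted_segments:
            if carriers[seg.label][sample]:
                s, e = config.segment_coords(seg)
                events.append(
                    dict(
                        chrom=seg.chrom,
                        start=s,
                        end=e,
                        direction=seg.direction,
                        amplitude=seg.amplitude,
                        kind="planted",
                        label=seg.label,
                    )
                )
        events.extend(passengers[sample])
        per_sample_segments[sample] = events

    for sample, _group in acgh_samples:
        _write_probe_table(
            outdir / "acgh" / f"{sample}.tsv", config, per_sample_segments[sample], rng
        )

    counts, probe_class, signal = generate_mirna_counts(
        config, carriers, mirna_samples, rng
    )
    out = counts.copy()
    out.insert(0, "probe_class", probe_class)
    out.to_csv(outdir / "mirna_counts.csv", float_format="%.4f")

    # annotations
    band_lines = [
        f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}\t{b.stain}" for b in config.cytobands()
    ]
    (outdir / "annotations" / "cytobands.txt").write_text("\n".join(band_lines) + "\n")
    mirna_lines = [
        f"{m.chrom}\t{m.start}\t{m.start + FEATURE_LENGTH}\t{m.mirna_id}"
        for m in config.mirna_panel
        if m.chrom is not None and m.start is not None
    ]
    (outdir / "annotations" / "mirna_loci.bed").write_text("\n".join(mirna_lines) + "\n")
    genes, gin, gout = _gene_annotation(config)
    gene_lines = [f"{c}\t{s}\t{s + FEATURE_LENGTH}\t{g}" for g, c, s in genes]
    (outdir / "annotations" / "gene_loci.bed").write_text("\n".join(gene_lines) + "\n")

    mirna_truth = {}
    concordant, mapped = [], []
    seg_labels = [seg.label for seg in config.planted_segments]
    for m in config.mirna_panel:
        seg_label = None
        if m.chrom is not None and m.start is not None:
            idx = config.segment_for_locus(m.chrom, m.start)
            if idx is not None:
                seg_label = seg_labels[idx]
        is_mapped = seg_label is not None and m.log2fc != 0.0
        mirna_truth[m.mirna_id] = dict(
            log2fc=m.log2fc,
            concordant=m.concordant,
            mapped=is_mapped,
            segment=seg_label,
            baseline_log2=m.baseline_log2,
        )
        if m.concordant:
            concordant.append(m.mirna_id)
        if is_mapped:
            mapped.append(m.mirna_id)

    tables, consensus_pairs, decoy_pairs = generate_target_tables(
        config, sorted(mapped), gin, gout, rng
    )
    for db, table in tables.items():
        table.to_csv(outdir / "targets" / f"{db}.tsv", sep="\t", index=False)

    gin_set = set(gin)
    survivors = sorted(
        {g for m, g, _n in consensus_pairs if m in set(concordant) and g in gin_set}
    )
    universe = [g for g, _c, _s in genes]
    gmt = _build_gmt(universe, survivors, rng)
    gmt_lines = [
        "\t".join([name, desc] + members) for name, (desc, members) in gmt.items()
    ]
    (outdir / "gene_sets.gmt").write_text("\n".join(gmt_lines) + "\n")

    ppi, ppi_kept, ppi_removed = _build_ppi(survivors, rng)
    ppi.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False, float_format="%.3f")

    clinical = _clinical_table(config, all_samples, signal, rng)
    clinical.to_csv(outdir / "clinical.csv", index=False)

    manifest = GroundTruthManifest(
        seed=config.seed,
        samples=dict(
            qnbc=qnbc,
            tnbc=tnbc,
            acgh=[s for s, _ in acgh_samples],
            mirna=[s for s, _ in mirna_samples],
        ),
        carriers=carriers,
        per_sample_segments=per_sample_segments,
        mirna_truth=mirna_truth,
        concordant_mirnas=sorted(concordant),
        mapped_mirnas=sorted(mapped),
        consensus_pairs=sorted(consensus_pairs),
        decoy_pairs=sorted(decoy_pairs),
        expected_surviving_genes=survivors,
        ppi_kept_genes=ppi_kept,
        ppi_removed_genes=ppi_removed,
        clinical_assoc=dict(config.clinical_assoc),
    )
    manifest.to_json(outdir / "manifest.json")
    _write_pipeline_config(config, outdir)
    return manifest


def _write_pipeline_config(config: SimulationConfig, outdir: Path) -> None:
    import yaml

    doc = dict(
        seed=int(config.seed),
        acgh_dir="acgh",
        counts="mirna_counts.csv",
        cytobands="annotations/cytobands.txt",
        mirna_loci="annotations/mirna_loci.bed",
        gene_loci="annotations/gene_loci.bed",
        target_tables={
            "dianamicrot": "targets/dianamicrot.tsv",
            "mirdb": "targets/mirdb.tsv",
            "targetscan": "targets/targetscan.tsv",
        },
        gene_sets="gene_sets.gmt",
        ppi_edges="ppi_edges.tsv",
        clinical="clinical.csv",
        cytoband_ranges=[seg.label for seg in config.planted_segments],
        caller=dict(score_threshold=6.0, min_probes=3, min_abs_mean_log2=0.25),
        de=dict(p_threshold=0.05, q_threshold=0.25),
        min_frequency=0.25,
        frequency_group="QNBC",
        min_db=2,
        ppi_min_score=0.9,
        k_sd=1.0,
        cv_folds=5,
        output_dir="results",
    )
    (outdir / "pipeline_config.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
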