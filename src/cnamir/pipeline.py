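"""End-to-end pipeline: aCGH calling -> miRNA DE -> signatures ->
integration -> discrimination, driven by a single YAML configuration.

Every stage writes its outputs (TSV with a one-line header; JSON for
machine summaries) before the next begins, and a run report records the
per-stage record counts, the parameter echo and wall-clock times.  All
randomness flows from the configured seed, so a rerun with the same
configuration and inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cna, discriminate, expression, integrate, signatures
from .genome import read_cytoband_table, read_feature_loci, range_from_label

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    base_dir: Path
    acgh_dir: Path
    counts: Path
    cytobands: Path
    mirna_loci: Path
    gene_loci: Path
    target_tables: dict[str, Path]
    gene_sets: Path
    ppi_edges: Path
    clinical: Path
    cytoband_ranges: list[str]
    output_dir: Path
    seed: int = 0
    caller: cna.CallerParams = field(default_factory=cna.CallerParams)
    p_threshold: float = 0.05
    q_threshold: float = 0.25
    min_frequency: float = 0.25
    frequency_group: str = "QNBC"
    min_db: int = 2
    ppi_min_score: float = 0.9
    k_sd: float = 1.0
    cv_folds: int = 5


def validate_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config, collecting all errors.

    Relative paths are resolved against the config file's directory.
    Unknown keys warn; out-of-range thresholds and missing inputs error.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent
    errors: list[str] = []
    known = {
        "seed", "acgh_dir", "counts", "cytobands", "mirna_loci", "gene_loci",
        "target_tables", "gene_sets", "ppi_edges", "clinical", "cytoband_ranges",
        "caller", "de", "min_frequency", "frequency_group", "min_db",
        "ppi_min_score", "k_sd", "cv_folds", "output_dir",
    }
    for key in set(doc) - known:
        warnings.warn(f"unknown config key {key!r} ignored")

    def _path(key, required=True):
        raw = doc.get(key)
        if raw is None:
            if required:
                errors.append(f"missing required key {key!r}")
            return None
        p = base / raw
        if not p.exists():
            errors.append(f"{key}: path {p} does not exist")
        return p

    acgh_dir = _path("acgh_dir")
    counts = _path("counts")
    cytobands = _path("cytobands")
    mirna_loci = _path("mirna_loci")
    gene_loci = _path("gene_loci")
    gene_sets = _path("gene_sets")
    ppi_edges = _path("ppi_edges")
    clinical = _path("clinical")
    targets = {}
    for db, raw in (doc.get("target_tables") or {}).items():
        p = base / raw
        if not p.exists():
            errors.append(f"target_tables.{db}: path {p} does not exist")
        targets[db] = p
    if len(targets) < 2:
        errors.append("at least two target tables are required")

    de = doc.get("de") or {}
    p_thr = float(de.get("p_threshold", 0.05))
    q_thr = float(de.get("q_threshold", 0.25))
    min_freq = float(doc.get("min_frequency", 0.25))
    for name, value, lo, hi in (
        ("de.p_threshold", p_thr, 0.0, 1.0),
        ("de.q_threshold", q_thr, 0.0, 1.0),
        ("min_frequency", min_freq, 0.0, 1.0),
        ("ppi_min_score", float(doc.get("ppi_min_score", 0.9)), 0.0, 1.0),
    ):
        if not lo <= value <= hi:
            errors.append(f"{name}={value} outside [{lo}, {hi}]")

    caller_doc = doc.get("caller") or {}
    try:
        caller = cna.CallerParams(
            score_threshold=float(caller_doc.get("score_threshold", 6.0)),
            min_probes=int(caller_doc.get("min_probes", 3)),
            min_abs_mean_log2=float(caller_doc.get("min_abs_mean_log2", 0.25)),
        )
    except ValueError as exc:
        errors.append(str(exc))
        caller = cna.CallerParams()

    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return PipelineConfig(
        base_dir=base,
        acgh_dir=acgh_dir,
        counts=counts,
        cytobands=cytobands,
        mirna_loci=mirna_loci,
        gene_loci=gene_loci,
        target_tables=targets,
        gene_sets=gene_sets,
        ppi_edges=ppi_edges,
        clinical=clinical,
        cytoband_ranges=list(doc.get("cytoband_ranges") or []),
        output_dir=base / doc.get("output_dir", "results"),
        seed=int(doc.get("seed", 0)),
        caller=caller,
        p_threshold=p_thr,
        q_threshold=q_thr,
        min_frequency=min_freq,
        frequency_group=str(doc.get("frequency_group", "QNBC")),
        min_db=int(doc.get("min_db", 2)),
        ppi_min_score=float(doc.get("ppi_min_score", 0.9)),
        k_sd=float(doc.get("k_sd", 1.0)),
        cv_folds=int(doc.get("cv_folds", 5)),
    )


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = dict(version=_VERSION, parameters=_echo_params(config), stages={})

    def _stage(name):
        report["stages"][name] = dict(started=time.time())
        return report["stages"][name]

    # --- inputs shared across stages
    cytobands = read_cytoband_table(config.cytobands)
    mirna_loci = read_feature_loci(config.mirna_loci, "miRNA")
    gene_loci = read_feature_loci(config.gene_loci, "protein_coding")
    clinical = pd.read_csv(config.clinical).set_index("sample_id")
    groups = clinical["group"].to_dict()
    ranges = [range_from_label(lbl, cytobands) for lbl in config.cytoband_ranges]

    # --- stage: aCGH calling
    rec = _stage("acgh")
    probe_tables = {
        p.stem: cna.read_probe_table(p)
        for p in sorted(Path(config.acgh_dir).glob("*.tsv"))
    }
    callsets = {
        s: cna.call_aberrations(t, config.caller, sample_id=s)
        for s, t in probe_tables.items()
    }
    nonempty = [c for c in callsets.values() if not c.empty]
    all_calls = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else next(iter(callsets.values()))
    )
    _write_tsv(all_calls, out / "calls.tsv", "aberration interval report")
    acgh_groups = {s: groups[s] for s in callsets}
    per_sample, group_stats, t_calls, p_calls = cna.summarize_calls(callsets, acgh_groups)
    _write_tsv(per_sample, out / "calls_per_sample.tsv", "per-sample call counts")
    freq = cna.cytoband_frequency(callsets, ranges, acgh_groups)
    _write_tsv(freq, out / "cytoband_frequency.tsv", "per-group aberration frequencies")
    rec.update(
        n_samples=len(callsets),
        n_calls=int(len(all_calls)),
        call_count_ttest_p=p_calls,
        group_stats=group_stats.to_dict("records"),
        seconds=time.time() - rec.pop("started"),
    )

    # --- stage: signature copy number
    rec = _stage("signatures")
    cn_interval = cna.gene_copy_number(callsets, gene_loci, mode="interval")
    cn_meanprobe = cna.gene_copy_number(probe_tables, gene_loci, mode="mean_probe")
    sig_rows = []
    for sig in (signatures.CA20, signatures.CIN25):
        for mode, table in (("interval", cn_interval), ("mean_probe", cn_meanprobe)):
            cmp = signatures.signature_cn_comparison(table, sig, acgh_groups)
            cmp = cmp.reset_index().assign(signature=sig.name, mode=mode)
            sig_rows.append(cmp)
    sig_table = pd.concat(sig_rows, ignore_index=True)
    _write_tsv(sig_table, out / "signature_cn.tsv", "CA20/CIN25 copy-number comparison")
    n_sig = int(
        ((sig_table["mode"] == "interval") & (sig_table["p"] < 0.05)).sum()
    )
    rec.update(n_interval_significant=n_sig, seconds=time.time() - rec.pop("started"))

    # --- stage: miRNA normalization + DE + clustering
    rec = _stage("mirna")
    raw = expression.read_count_matrix(config.counts)
    norm = expression.normalize_counts(raw)
    norm.log2.to_csv(out / "normalized_log2.tsv", sep="\t", float_format="%.6g")
    de = expression.differential_expression(
        norm.log2,
        groups,
        p_threshold=config.p_threshold,
        q_threshold=config.q_threshold,
    )
    _write_tsv(de, out / "de.tsv", "differential expression (QNBC - TNBC)")
    sig_mirnas = list(de.loc[de["significant"], "mirna"])
    if len(sig_mirnas) >= 2:
        clust = expression.supervised_clustering(norm.log2, sig_mirnas)
        (out / "clustering.json").write_text(
            json.dumps(
                dict(
                    sample_order=clust.sample_order,
                    mirna_order=clust.mirna_order,
                    metric=clust.metric,
                    linkage=clust.linkage,
                ),
                indent=1,
            )
        )
    rec.update(
        n_tested=int(len(de)),
        n_significant=len(sig_mirnas),
        seconds=time.time() - rec.pop("started"),
    )

    # --- stage: integration
    rec = _stage("integration")
    records, unmapped = integrate.map_de_mirnas_to_cna_cytobands(
        de, mirna_loci, freq, cytobands,
        min_frequency=config.min_frequency, group=config.frequency_group,
    )
    _write_tsv(records, out / "cna_mirna_mapping.tsv", "DE miRNA x frequent CNA range pairings")
    concordant = integrate.concordance_filter(records)
    _write_tsv(concordant, out / "concordant.tsv", "direction-concordant pairings")
    concordant_mirnas = sorted(concordant["mirna"].unique())

    tables = {
        db: pd.read_csv(p, sep="\t") for db, p in sorted(config.target_tables.items())
    }
    consensus = integrate.consensus_targets(tables, config.min_db, mirnas=concordant_mirnas)
    _write_tsv(consensus, out / "consensus_targets.tsv", "targets in >=min_db databases")

    retained = records.drop_duplicates("cytoband_range")
    retained_ranges = [
        r for r in ranges if r.label in set(retained["cytoband_range"])
    ] or [
        r
        for r in ranges
        if r.label
        in set(
            freq[
                (freq["group"] == config.frequency_group)
                & (freq["frequency_pct"] >= 100.0 * config.min_frequency)
            ]["cytoband_range"]
        )
    ]
    cna_genes = sorted(
        {
            g.feature_id
            for g in gene_loci
            for r in retained_ranges
            if g.chrom == r.chrom and g.start < r.end and g.end > r.start
        }
    )
    summary = integrate.intersect_targets_with_cna_genes(consensus, cna_genes)
    (out / "integration_summary.json").write_text(
        json.dumps(
            dict(
                n_targets_before=summary.n_targets_before,
                n_targets_after=summary.n_targets_after,
                reduction_pct=summary.reduction_pct,
                surviving_genes=sorted(summary.genes_after),
            ),
            indent=1,
        )
    )
    gmt = integrate.read_gmt(config.gene_sets)
    universe = [g.feature_id for g in gene_loci]
    enrichment = integrate.gene_set_overlap(sorted(summary.genes_after), gmt, universe)
    _write_tsv(enrichment, out / "enrichment.tsv", "hypergeometric gene-set overlap")

    edges = pd.read_csv(config.ppi_edges, sep="\t")
    surviving_pairs = summary.surviving_pairs
    graph, removed = integrate.filter_ppi_edges(
        edges, config.ppi_min_score, mirna_targets=surviving_pairs
    )
    (out / "network.json").write_text(
        json.dumps(
            dict(
                nodes=sorted(graph.nodes),
                removed=removed,
                edges=[[a, b, d.get("kind")] for a, b, d in graph.edges(data=True)],
            ),
            indent=1,
        )
    )
    alteration = None
    if len(concordant_mirnas) >= 1:
        alteration, t_alt, p_alt = integrate.per_sample_alteration_count(
            norm.log2, concordant, groups, k_sd=config.k_sd
        )
        _write_tsv(alteration, out / "alteration_counts.tsv", "per-sample altered miRNA counts")
        rec["alteration_ttest_p"] = p_alt
    rec.update(
        n_mapped=int(records["mirna"].nunique()),
        n_unmapped=len(unmapped),
        n_concordant=len(concordant_mirnas),
        n_consensus_pairs=int(len(consensus)),
        n_targets_before=summary.n_targets_before,
        n_targets_after=summary.n_targets_after,
        reduction_pct=summary.reduction_pct,
        n_network_nodes=int(graph.number_of_nodes()),
        seconds=time.time() - rec.pop("started"),
    )

    # --- stage: discrimination + clinical
    rec = _stage("discrimination")
    roc_rows = []
    panel_doc = None
    mirna_cols = [s for s in norm.log2.columns]
    labels = pd.Series({s: groups[s] for s in mirna_cols})
    panel_mirnas = [m for m in concordant_mirnas if m in norm.log2.index]
    for m in panel_mirnas:
        curve = discriminate.roc_single(norm.log2.loc[m, mirna_cols], labels.values, label=m)
        roc_rows.append(
            dict(id=m, auc=curve.auc, ci_low=curve.ci_low, ci_high=curve.ci_high,
                 flipped=curve.flipped)
        )
    if len(panel_mirnas) >= 1:
        panel = discriminate.combined_panel_roc(
            norm.log2.loc[panel_mirnas, mirna_cols].T,
            labels,
            cv=config.cv_folds if len(panel_mirnas) >= 1 else None,
            seed=config.seed,
        )
        roc_rows.append(
            dict(
                id="panel",
                auc=panel.in_sample.auc,
                ci_low=panel.in_sample.ci_low,
                ci_high=panel.in_sample.ci_high,
                flipped=panel.in_sample.flipped,
            )
        )
        panel_doc = dict(
            members=panel.members,
            coef=[float(c) for c in panel.coef],
            intercept=panel.intercept,
            ridge_fallback=panel.ridge_fallback,
            auc_in_sample=panel.in_sample.auc,
            auc_cv=panel.cross_validated.auc if panel.cross_validated else None,
        )
        (out / "panel.json").write_text(json.dumps(panel_doc, indent=1))
    _write_tsv(pd.DataFrame(roc_rows), out / "roc.tsv", "ROC AUC with DeLong 95% CI")

    assoc_rows = []
    clin_mirna = clinical.loc[[s for s in mirna_cols]]
    for m in panel_mirnas:
        values = norm.log2.loc[m, clin_mirna.index]
        for cov in ("age", "tumor_size_cm"):
            ok = clin_mirna[cov].notna()
            res = discriminate.associate_continuous(
                values[ok], clin_mirna.loc[ok, cov], name=m, covariate_name=cov
            )
            assoc_rows.append(dict(mirna=m, covariate=cov, model=res.model,
                                   effect=res.effect, p=res.p))
        for cov in ("node_positive", "distant_metastasis", "recurrence"):
            ok = clin_mirna[cov].notna()
            # both flag levels need >=2 samples for a t-test
            level_counts = clin_mirna.loc[ok, cov].value_counts()
            if len(level_counts) < 2 or level_counts.min() < 2:
                continue
            res = discriminate.associate_binary(
                values[ok], clin_mirna.loc[ok, cov], name=m, covariate_name=cov
            )
            assoc_rows.append(dict(mirna=m, covariate=cov, model=res.model,
                                   effect=res.effect, p=res.p))
    _write_tsv(pd.DataFrame(assoc_rows), out / "clinical_associations.tsv",
               "miRNA expression vs clinical covariates")

    types = dict(
        age="continuous", tumor_size_cm="continuous", node_positive="categorical",
        distant_metastasis="categorical", recurrence="categorical", race="categorical",
    )
    clin_cmp = discriminate.compare_clinical_tables(clinical, clinical["group"], types)
    _write_tsv(clin_cmp, out / "clinical_comparison.tsv", "clinical covariates by group")
    rec.update(
        n_roc=len(roc_rows),
        panel=panel_doc,
        seconds=time.time() - rec.pop("started"),
    )

    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _echo_params(config: PipelineConfig) -> dict:
    return dict(
        seed=config.seed,
        score_threshold=config.caller.score_threshold,
        min_probes=config.caller.min_probes,
        min_abs_mean_log2=config.caller.min_abs_mean_log2,
        p_threshold=config.p_threshold,
        q_threshold=config.q_threshold,
        min_frequency=config.min_frequency,
        frequency_group=config.frequency_group,
        min_db=config.min_db,
        ppi_min_score=config.ppi_min_score,
        k_sd=config.k_sd,
        cv_folds=config.cv_folds,
    )
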