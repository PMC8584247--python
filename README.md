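# cnamir

Integrated array-CGH copy-number and miRNA expression analysis for
androgen-receptor-stratified triple-negative breast cancer cohorts.

Triple-negative breast tumors (ER−/PR−/HER2−) split into AR-positive
("TNBC" here) and AR-negative, quadruple-negative ("QNBC") groups, and the
AR-negative group tends to show higher genomic instability.  `cnamir` is a
tested re-implementation of the analysis chain used to characterize that
difference: it calls copy-number aberrations (CNAs) from probe-level aCGH
log2 ratios, profiles recurrently altered cytobands per group, compares
CA20/CIN25 instability-signature genes, normalizes NanoString-style miRNA
panel counts and tests differential expression, integrates the two layers
by locating differentially expressed miRNAs inside frequent CNA cytobands
with matching direction (gain & up / loss & down), intersects their
consensus-predicted targets with genes in CNA regions, and evaluates the
concordant miRNA panel as a QNBC/TNBC discriminator.  Because cohorts of
this kind are rarely deposited, a first-class synthetic-cohort generator
with planted ground truth makes every stage testable end to end.

The statistical core, in the field's usual notation:

- **Aberration calling** — per chromosome, noise
  `σ̂ = MAD(Δx)/(0.6745·√2)`; every probe interval I is scored
  `S(I) = |mean(I)|·√|I| / σ̂`; intervals with `S ≥ 6.0` are resolved
  greedily by descending score into non-overlapping calls, then filtered
  by ≥3 probes and `|mean| > 0.25` log2.
- **Normalization** — per sample: subtract the geometric mean of negative
  controls (floor 0), rescale by positive-control and all-endogenous
  geometric-mean factors, then `log2(x+1)`.  Exactly invariant to
  per-sample lane scalars.
- **Differential expression** — unpaired t-test on log2 values,
  `log2FC = mean(QNBC) − mean(TNBC)`, Benjamini–Hochberg FDR, significant
  when `p < 0.05` and `q < 0.25`.
- **Discrimination** — AUC as the Mann–Whitney statistic with DeLong 95%
  CIs; the combined panel is a logistic score on standardized expression
  with apparent and cross-validated AUC.

## Worked example

Generate a synthetic cohort at the emulated study conditions (19 QNBC vs
14 TNBC arrays, 20 vs 12 expression samples, planted segment frequencies
patterned on the reference frequency table) and run the full pipeline:

```python
from pathlib import Path
from cnamir.simulate import default_config, generate_cohort
from cnamir.pipeline import validate_config, run_pipeline

out = Path("cohort")
manifest = generate_cohort(default_config(seed=1), out)
report = run_pipeline(validate_config(out / "pipeline_config.yaml"))

acgh = report["stages"]["acgh"]
for rec in acgh["group_stats"]:
    print(f"{rec['group']}: {rec['mean_calls']:.2f} +/- {rec['sd_calls']:.2f} "
          f"calls/sample (n={rec['n_samples']})")
print(f"call-count t-test p = {acgh['call_count_ttest_p']:.2e}")
integ = report["stages"]["integration"]
print(f"DE miRNAs: {report['stages']['mirna']['n_significant']}, "
      f"mapped: {integ['n_mapped']}, concordant: {integ['n_concordant']}")
print(f"consensus targets: {integ['n_targets_before']}, surviving: "
      f"{integ['n_targets_after']} ({integ['reduction_pct']:.1f}% reduction)")
panel = report["stages"]["discrimination"]["panel"]
print(f"panel AUC (in-sample) = {panel['auc_in_sample']:.3f}, "
      f"cross-validated = {panel['auc_cv']:.3f}")
```

prints

```
QNBC: 26.58 +/- 3.85 calls/sample (n=19)
TNBC: 14.64 +/- 3.05 calls/sample (n=14)
call-count t-test p = 8.82e-11
DE miRNAs: 39, mapped: 10, concordant: 3
consensus targets: 29, surviving: 16 (44.8% reduction)
panel AUC (in-sample) = 0.883, cross-validated = 0.800
```

Read: the AR-negative group carries roughly 12 more aberrations per sample
than the AR-positive group (t-test p ≈ 1e-10); 39 of 120 panel miRNAs are
differentially expressed, 10 of them sit in cytobands altered in ≥25% of
QNBC samples, and 3 agree in direction with the copy-number change; their
consensus targets shrink by 44.8% when intersected with genes in CNA
regions; and the concordant panel separates the groups with apparent AUC
0.88 (0.80 cross-validated).  The concordant count recovers a subset of
the eight planted concordant miRNAs — with carrier-gated effects, ranges
whose two group frequencies are close carry little group-level expression
signal (see `docs/methods.md`).  Every number above is seeded and
reproducible; per-stage tables (`calls.tsv`, `de.tsv`, `concordant.tsv`,
`roc.tsv`, ...) land in `cohort/results/`.

The same pipeline is scriptable from the shell:

```sh
cnamir simulate-cohort --seed 1 --out cohort
cnamir all --config cohort/pipeline_config.yaml
```

with per-stage subcommands (`call-cna`, `normalize`, `de`, `frequency`,
`validate`) for running stages independently on prior outputs.

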