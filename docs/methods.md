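# Methods

`cnamir` implements a joint analysis of array-CGH copy-number profiles and
miRNA expression panels in triple-negative breast cancer (TNBC) cohorts
stratified by androgen-receptor (AR) status: AR-positive tumors (here
"TNBC") versus AR-negative, quadruple-negative tumors ("QNBC").  The
pipeline asks whether the AR-negative group carries more copy-number
alterations (CNAs), whether recurrently altered cytobands physically
contain differentially expressed miRNAs whose expression direction matches
the copy-number direction, and whether the resulting miRNA panel
discriminates the two groups.

## Aberration calling

Input is one probe table per sample (probe id, chrom, start, end,
log2(Cy5/Cy3) ratio), coordinates 0-based half-open throughout.  Per
chromosome:

1. Probe noise is estimated robustly from successive probe differences:
   `sigma = MAD(diff(x)) / (0.6745 * sqrt(2))`.  The `sqrt(2)` removes the
   variance doubling of differencing, the 0.6745 converts MAD to a normal
   SD.  With fewer than 4 probes the chromosome is skipped (the estimate is
   undefined).  A floor of 1e-6 keeps the noiseless limit well defined.
2. Every interval `I` is scored `S(I) = |mean(I)| * sqrt(|I|) / sigma` via
   prefix sums; intervals with `S >= 6.0` are candidates.
3. Candidates are resolved greedily into a non-overlapping set by
   descending score, ties by leftmost start then longest interval (the
   order makes the caller deterministic).
4. Survivors are filtered by a minimum of 3 probes and `|mean| > 0.25`
   log2, the conventional aberration-filter semantics for this platform
   family.  Direction is the sign of the interval mean.

This is an interval-score caller in the same family as the proprietary
vendor algorithm it replaces; because step 2 enumerates *all* intervals,
the caller is exactly equivalent to an exhaustive oracle, which the test
suite verifies on instances up to 200 probes.  The O(n²) enumeration is
deliberate: the package targets per-chromosome probe counts in the
hundreds-to-low-thousands, where exactness is worth more than an
approximate linear-time scan.

Calls are summarized as per-sample counts (group mean ± SD, unpaired
Student t-test) and as per-cytoband-range frequencies: a sample is
*affected* for a (range, direction) when any of its calls of that
direction overlaps the range; frequencies are percentages of the group.

Gene-level copy number is reported two ways, mirroring mean-probe and
interval-based reporting: `mean_probe` averages the probes overlapping the
gene span (missing when uncovered); `interval` takes the mean log2 of the
overlapping call, 0 (neutral) outside all calls, largest overlap winning
when a gene spans two calls.

## miRNA count normalization

The three-stage geometric-mean scheme used for NanoString-style panels:

1. **Background**: subtract each sample's geometric mean of its negative
   controls from every count, flooring at 0.
2. **Technical**: multiply by `grand_mean(per-sample pos-ctrl geometric
   means) / this sample's pos-ctrl geometric mean`.
3. **Content**: the same factor construction over all endogenous probes.
4. `log2(x + 1)`.

Geometric means are computed over strictly positive counts (zeros
excluded) rather than with a pseudocount inside the mean.  This choice
makes the chain *exactly* invariant to a per-sample global scalar — a lane
scanning-intensity factor multiplied into every row of a sample cancels
identically — at the cost of ignoring zeros when averaging controls.  The
`+1` is kept only in the final log transform.  A lane whose
positive-control geometric mean is zero cannot be corrected and raises.

One consequence worth knowing: content normalization divides each sample
by its all-endogenous geometric mean, so a strong planted (or biological)
group signal leaks, at `1/n_probes` strength, into every other probe's
normalized values.  On noisy data this is negligible; in the exact
noiseless limit it makes *every* probe formally group-different, which is
why exact-recovery checks are phrased on the concordant set (whose members
must also sit in frequent CNA ranges), not on the raw significant list.

## Differential expression and clustering

Per endogenous miRNA: two-sided unpaired Student t-test (Welch by flag) on
log2 values, log2FC = mean(QNBC) − mean(TNBC), Benjamini–Hochberg q-values
over all tested probes, and a dual significance rule `p < 0.05 AND
q < 0.25`.  Zero-variance probes with equal means get p = 1 (and p = 0
when the means differ — the degenerate noiseless limit).  An optional
mean-expression floor filter exists but is off by default.  Supervised
clustering of the significant probes uses Pearson-correlation distance
(1 − r) with average linkage on both axes; constant rows are dropped with
a warning since their correlations are undefined.

## Signature analyses

CA20 (20 genes, centrosome amplification) and CIN25 (25 genes, chromosomal
instability) ship exactly as printed in their sources; legacy symbols are
resolved through an alias table (CDC2→CDK1, CNAP1→NCAPD2, C20orf24→TGIF2,
CDC45L→CDC45, H2AFZ→H2AZ1) against whatever annotation is supplied, and
unresolvable symbols are reported missing rather than dropped.  Signature
copy number is compared per gene between groups in both CN modes.
Expression scores are the unweighted sum of log2 median-centered
expression over signature genes (a sample at every gene's cohort median
scores exactly 0); stratification against a gene (e.g. AR) uses the
linear-interpolation percentile with strict `<` so ties go to "high".

## Integration

Step one: each significant DE miRNA is located on the cytoband table and
paired with every (range, direction) whose frequency in the reference
group (QNBC) is at least `min_frequency` — default 0.25, with 0.30
available as the stricter preset; both thresholds are quoted in the
source analyses and are deliberately not reconciled.  Pairings are kept
when direction and expression agree (gain & up, loss & down; log2FC = 0 is
never concordant).  A miRNA overlapping several retained ranges yields one
record per range; the concordant miRNA list is the distinct projection.

Step two: targets of the concordant miRNAs predicted in at least
`min_db = 2` of the 3 prediction tables form the consensus; intersecting
with the genes located in retained ranges gives the surviving targets and
the percent reduction `100·(before − after)/before`.

Supporting operations: hypergeometric upper-tail gene-set overlap with BH
correction (explicit gene universe, so no hidden database-version
dependence); PPI edge filtering at a minimum combined score (default 0.9)
followed by removal of genes without any surviving interaction, then
attachment of miRNA→target edges as a second edge class; and per-sample
alteration counts — a concordant miRNA counts as altered in a sample when
its log2 expression deviates from the reference-group (TNBC) mean by more
than `k_sd` (default 1.0) reference SDs in the direction of its group
fold-change.  The k·SD rule is this package's own operationalization of
"altered expression"; k is configurable.

## Discrimination and clinical associations

Single-marker AUC is the Mann–Whitney rank statistic with midrank tie
handling; the 95% CI uses the DeLong placement-variance estimator.  For an
undirected marker the orientation is chosen so AUC ≥ 0.5 with the flip
recorded.  The combined panel is a logistic regression on standardized
log2 values; its score has a defined orientation, so the panel AUC is
computed *without* orientation flipping (flipping a null score would bias
the AUC above one half).  In-sample (apparent) AUC is the default
reporting mode; a stratified k-fold cross-validated AUC on pooled
out-of-fold scores is also produced.  Under perfect separation the
unpenalized fit is replaced by a ridge-stabilized one and flagged.

Clinical associations: univariable linear regression with miRNA log2
expression as outcome for continuous covariates (age, tumor size);
unpaired t-test plus a logistic coefficient p for binary covariates.
Group comparisons of the clinical table use Pearson chi-squared without
continuity correction — the convention that reproduces the reference
race-table p-value of 0.067 — switching to Fisher's exact when any
expected cell of a 2×2 table is below 5; continuous covariates use a
t-test with a Mann–Whitney flag.

## Synthetic cohort generator

Because the kind of cohort this pipeline targets is rarely deposited, the
generator produces everything the pipeline consumes on a toy genome of 13
chromosomes × 10 Mb (ten 1-Mb cytobands each, probes every 20 kb), with a
ground-truth manifest.

Study-conditions defaults: 19 QNBC / 14 TNBC arrays and 20 / 12 expression
samples; seven planted frequent segments with per-group carrier
frequencies and directions patterned on the reference frequency table
(gains at 63–79% vs 14–64%, two losses); constant amplitude within a
segment (±0.7–0.9) plus i.i.d. Gaussian probe noise (SD 0.1); passenger
CNAs per sample (Poisson means 21.4 / 12.6, placed in fixed slots that
keep more than twice a passenger's length clear of every other event so
the greedy caller never merges neighbours) calibrated so expected
calls/sample land near 25.5 and 14.6.  Carriers are per-sample Bernoulli
draws recorded in the manifest, so realized frequencies differ from
nominal exactly as empirical proportions do.

The 120-probe expression panel (a scaled-down stand-in for an 827-probe
assay) is log-normal on the log2 scale (dispersion 0.5) with multiplicative
group effects `2^log2FC`: eight concordant miRNAs inside matching planted
segments whose effects apply only in carrier samples; seven discordant
miRNAs inside planted ranges with opposite-direction direct group effects;
fifteen direct-effect miRNAs with printed-magnitude fold changes (three
deliberately without loci, to exercise the unmapped path); and ninety
nulls.  Controls follow the panel convention: six positive controls on a
nominal ladder, eight negative controls near a low constant, five
housekeeping probes and five spike-ins; a per-sample lane scalar
(log2-SD 0.15) multiplies every row and is exactly removed by
normalization.  Target tables plant every consensus pair in ≥2 of 3
databases and decoys in exactly 1; gene annotation places three CIN25
genes (RAD51AP1, FOXM1, NCAPD2) inside the chr12 planted gain and in-range
target genes inside planted ranges.  The clinical table ties the
metastasis flag to the designated miRNAs through a logistic model on their
standardized expression.

The `noiseless` preset zeroes every noise source and makes planted
segments group-pure (carrier frequency 1 in QNBC, 0 in TNBC); every
pipeline stage's output is then predictable from the manifest in closed
form, and the end-to-end test requires *exact* recovery of the planted
concordant set and surviving target genes.

What the generator does **not** emulate: scanner artifacts, GC waves,
tumor purity mixtures, FFPE degradation, probe-specific biases, or
correlated miRNA co-regulation.  Passing tests therefore demonstrate the
correctness of the computational chain under a clean generative model, not
robustness to platform pathology.

A deliberate consequence of carrier-gating: a concordant miRNA's
group-level fold change is its per-carrier effect times the difference in
carrier frequencies, so ranges whose two group frequencies are close (the
8q-style gain at 79% vs 64%) yield little DE power at realistic
dispersion.  The study-conditions run typically recovers a subset of the
eight planted concordant miRNAs; this dilution is a property of the dosage
model, reported as-is.

## Numerical choices and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `score_threshold` | 6.0 | interval score floor (noise SDs per sqrt-probe) |
| `min_probes` | 3 | minimum probes per call |
| `min_abs_mean_log2` | 0.25 | minimum absolute call amplitude (log2) |
| `p_threshold` / `q_threshold` | 0.05 / 0.25 | DE dual significance rule |
| `min_frequency` | 0.25 (preset 0.30) | CNA range retention, QNBC fraction |
| `min_db` | 2 | consensus databases per target |
| `ppi_min_score` | 0.9 | highest-confidence PPI edges |
| `percentile` | 10 | AR-low stratification decile |
| `k_sd` | 1.0 | per-sample "altered expression" rule |
| `cv_folds` | 5 | panel cross-validation |

Tie-breaks: greedy caller (score, then leftmost, then longest); percentile
ties go to "high"; clustering leaf order follows scipy's deterministic
input-order convention.  Degenerate inputs: zero-variance t-tests resolve
to p ∈ {0, 1} by mean equality; empty consensus reports reduction as
missing rather than 0; chromosomes with <4 probes, constant clustering
rows, zero-reference-SD miRNAs and all-missing clinical variables are
skipped with warnings, never silently.

Problem sizes in the shipped tests and acceptance script (a 13×10 Mb toy
genome, 500 probes/chromosome, a 120-probe panel, 20-seed Monte-Carlo
loops) are the package's chosen design points for exactness-checking
against brute-force oracles; all scale linearly in samples and
quadratically (caller) in probes per chromosome.

## Known limitations

- The caller's exhaustive enumeration is quadratic per chromosome; for
  180k-probe whole-genome arrays a windowed or recursive scan would be
  needed.
- Content normalization couples probes (see above); with small panels and
  many true effects the coupling biases null probes slightly.
- The interval-mode neutral value 0 treats uncalled regions as diploid,
  which ignores purity and ploidy.
- The combined-panel AUC is apparent by default; cross-validated AUC is
  reported alongside and is the honest generalization estimate.
- Overlap is strand-blind, as cytoband mapping is; no liftover support —
  annotation files are taken as authoritative.
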