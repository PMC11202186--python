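# Methods

## Background and model

Plasma cell-free DNA (cfDNA) is released mostly by dying cells as
nucleosome-protected fragments of ~167 bp. Around the transcription start
site (TSS) of an *active* gene lies a nucleosome-depleted region, so cfDNA
fragments are under-represented there; the depth of that dip is therefore a
proxy for promoter activity in the tissues contributing to the plasma pool.
In cancer patients, tumour-derived DNA shifts these accessibility profiles,
which is the signal the package's classifiers exploit.

The core statistic is the **TSS relative coverage**

    R = (mean fragment depth over [t−500, t+500)) /
        (mean fragment depth over [t−1500, t−500) ∪ [t+500, t+1500))

for a TSS at position `t`. All three windows are half-open 1000-base
intervals, so the divisors are exact and the windows partition
`[t−1500, t+1500)`. `R ≈ 1` means no dip (inactive promoter or no signal),
`R < 1` a depleted, accessible promoter. The statistic is symmetric about
the TSS and is applied identically on both strands. Depth is
*fragment-overlap* depth: each sequenced template counts once over its full
span, because the cfDNA signal is the fragment footprint, not the read
footprint. Zero flanking depth makes `R` undefined; such entries are masked
(NaN), never raised as errors.

BAM input is filtered like `samtools view -q 2 -F 3840`: records with
mapping quality < 2 and records with any of the secondary / QC-fail /
duplicate / supplementary flag bits are excluded; each template contributes
one fragment, taken from the leftmost mate (TLEN > 0). BED fragment input
is passed through untouched, on the assumption that its producer already
filtered.

## Normalization and feature selection

Relative-coverage values are z-scored per transcript with mean/sd estimated
**on the training cohort only** and then frozen; validation and test
cohorts are transformed with the same parameters, so no scale information
leaks out of training. Transcripts masked in more than 20% of training
samples, or with zero training variance, are dropped at fit time; remaining
masked entries are imputed with the training mean (z = 0).

The early-detection panel is built in four steps on the normalized training
matrix, cheapest first:

1. **Near-zero variance**: drop features whose most-common /
   second-most-common value frequency ratio exceeds 19, or whose distinct-
   value fraction is below 10% (both configurable).
2. **High correlation**: greedy pruning while any pairwise |Pearson r| >
   0.9 remains, dropping the member of the worst pair with the larger mean
   absolute correlation.
3. **Group screen**: per-transcript two-sided Wilcoxon rank-sum test,
   cancer vs healthy, retaining p < 0.01. The rank-sum test is the default
   because the coverage ratios are right-skewed; a Welch t-test is
   available by option. No multiple-testing correction is applied — the
   screen is a pre-filter whose retained count is reported, not an
   inference.
4. **Stage-monotone selection**: compute group means for healthy and each
   stage I–IV; keep transcripts whose five means order *strictly*
   increasing (cancer-up) or strictly decreasing (healthy-up); rank each
   class by |mean(stage I) − mean(healthy)| descending (ties broken by
   transcript id, so selection is fully deterministic) and keep the top
   100 per direction. A top-200-per-direction pre-cut is retained as an
   intermediate artifact. Strict inequalities are used because non-strict
   ordering would admit flat noise profiles.

The stage-I-vs-healthy ranking deliberately prioritises features that move
early in disease, which is what makes the panel sensitive for early-stage
detection.

## Pathway scores and the EGFR feature set

Gene-level values are the mean of each gene's transcript z-scores (so
multi-transcript genes are not over-weighted), and a pathway's **path
score** in a sample is the mean gene-level value over the pathway's genes
present in the matrix. Gene sets are read from GMT; the "EGFR-related"
subset is defined as every set containing a configurable anchor symbol
(default `EGFR`). Per-pathway group differences (EGFR-positive vs
wild-type) use the two-sided Wilcoxon test at p < 0.01, with significant
fractions reported for all, anchor-related, and remaining pathways. The
EGFR model's features are the anchor-related pathway genes individually
passing the same screen, ordered by p-value then symbol.

## Classifiers and evaluation

Cohorts are split 70/30 stratified by label, with *per-stratum ceiling*
rounding (`ceil(0.7·n)` training members per stratum): this is the caret
`createDataPartition` convention and the only rounding rule that produces
both reference partitions (96 + 100 → 68 + 70 train / 58 validation, and
29 + 36 → 21 + 26 train / 18 validation).

The classifier is a random forest; the screening model uses 1500 trees
with 1 feature per split, the EGFR model 2500 trees with 5. Prediction
error is assessed by three repeats of stratified ten-fold CV on the
training data (folds seeded; a class smaller than the fold count reduces
the fold count with a warning, which the small EGFR cohort needs); the
final forest refits on all training data. The predictor score is the
forest's positive-class vote fraction. Held-out cohorts are evaluated by
threshold-swept ROC with trapezoidal AUC — verified in tests to equal the
Mann–Whitney concordance probability with ties counted ½ — and a 95%
DeLong CI (normal approximation on the structural-components variance,
clipped to [0, 1]; percentile bootstrap available by option). Stage
subgroup ROCs (e.g. stage I/II cases) use the subgroup's cases against
*all* controls in the cohort. Evaluating any sample present in training
raises an error.

## Synthetic cohort generator

The generator emulates exactly what the statistic measures, on one
synthetic chromosome `chrS` with TSSs every 4 kb (so ±1500 bp windows
never overlap):

* Fragment **midpoints** are Poisson with per-base rate
  `background_depth / E[fragment length]` everywhere, thinned inside each
  TSS ± 500 bp to that sample's depletion fraction for that TSS
  (depletions above 1 add extra Poisson midpoints). Lengths are
  Normal(167, 10) truncated to [80, 300]. Expected flank depth therefore
  equals `background_depth` (default 6×, shallow-WGS scale).
* Every TSS is active with baseline depletion 0.5. Planted cancer-up TSSs
  gain `stage_effect` of depletion per stage step healthy → I → II → III →
  IV; planted healthy-up TSSs lose it; genes of the planted "EGFR"
  pathways gain `pathway_effect` (default 0.1) in EGFR-positive samples.
  All depletions clamp to [0, 1.5].
* `noise_sd` (default 0.08) is multiplicative noise on the per-(sample,
  TSS) depletion fraction. A global per-sample depth factor would cancel
  exactly in the coverage ratio, so between-sample biological variation
  has to enter through the depletion itself.
* Default cohort: 60 healthy + 15 per stage, 2000 TSSs, 100 + 100 planted
  features, 30 pathways of 20 genes with 5 planted EGFR-related sets, and
  an EGFR-positive fraction of 0.45 among cancer samples.

`stage_effect` defaults to 0.12. At 6× depth the central window holds only
~20–30 fragments, so the coverage ratio carries ~0.1–0.2 sd of counting
noise per sample; 0.12 per stage step is the smallest round step at which
strict five-group monotonicity survives that noise reliably at the default
per-stage sample sizes, while still being a dip-depth change of a few
tenths — the regime the statistic is meant for. It is a config knob, not a
biological claim.

Everything is driven by one integer seed through spawned per-sample
substreams, so cohorts are byte-identical across runs and individual
samples can be regenerated lazily without holding the cohort's fragments
in memory.

**What the generator does not emulate** — GC and mappability bias,
copy-number signal, nucleosome-phasing harmonics in the flanks,
class-dependent fragment-size shifts, and real genome coordinates.
Passing the synthetic-recovery benchmarks therefore demonstrates that the
pipeline's statistics and machinery behave as designed under the stated
noise model; it does not demonstrate clinical performance on real plasma.

## Numerical and design notes

* Window sums use a per-chromosome prefix-sum of the depth track, so each
  window is two array lookups; results are tested to 1e−12 against a naive
  per-base double loop.
* Transcripts sharing one TSS coordinate are computed once and share the
  value.
* The simulator calibration test compares the cohort mean against an
  independent brute-force Monte-Carlo tally rather than the nominal
  depletion: fragment-length blur at window edges and the ratio
  estimator's Jensen bias shift the expectation from 0.50 to ≈ 0.53 at 6×,
  and the oracle reproduces both effects from first principles.
* Problem sizes in the test and acceptance suites (800–2000 TSSs, cohorts
  of 100–120 samples, three seeds for stochastic checks) were chosen as
  the smallest scales at which the planted structure is comfortably
  detectable; all checks are seeded and deterministic at fixed seed.

## Known limitations

* The generator's flat ±500 bp depletion window is the simplest structure
  the statistic can detect; real nucleosome-depleted regions are
  asymmetric and phase-structured.
* The Wilcoxon screen's null calibration is slightly conservative at small
  n because of the statistic's discreteness.
* The pipeline consumes aligned fragments; alignment, duplicate marking
  and QC are upstream of this package.
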