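# Methods

This note documents the models, estimators and numerical choices behind
`promcoupling`, and what the synthetic-data generator does and does not
emulate.

## Kinetic model

Every gene is modeled with first-order kinetics: synthesis rate `k_syn`
(transcripts/min) and degradation rate `k_deg` (1/min), steady state
`k_syn/k_deg`, half-life `t½ = ln2/k_deg`. Time is in minutes everywhere,
rates in 1/min, and all ratios, effects and noise terms in log2 units.
Noise is multiplicative log-normal on levels (additive Gaussian in log2),
because expression measurement error is scale-proportional and log-space
Gaussianity keeps downstream statistics tractable.

Two-condition cohorts draw condition-1 rates log-normally (half-life
median 240 min, spread 0.8 log2 units — typical of mammalian turnover
data; synthesis spread 1.5 log2 units, matching the much wider dynamic
range of expression levels than of half-lives). The decay-course cohorts
use a 20-min median half-life, appropriate for yeast. Condition-2 rates
are the baseline scaled by `2^Δ`, with `Δsyn`, `Δdeg` drawn per generative
model:

- **independent** — `Δdeg ~ N(0, sd_bio)`, `Δsyn ~ N(0, sd_bio)`,
  independent;
- **noise** — no true changes; all apparent differences are measurement
  distortion;
- **coupled** — `Δsyn = β·Δdeg + N(0, sd_bio)`; β > 1 means transcription
  over-compensates degradation changes, so total mRNA moves *with* the
  degradation change.

Defaults `sd_bio = 0.7`, `sd_noise = 0.25` log2 units. The biological
spread is chosen so that roughly a quarter to a third of genes pass the
dual 1.75-fold differential-degradation classifier, the regime the
framework is designed for; the measurement distortion is kept well below
the biological spread, consistent with the observation that total and
nascent interspecies ratios correlate strongly (measurement error is not
the dominant variance component). The Gaussian form of the effect-size
distribution is a modeling choice; the data sources this emulates report
no parametric form.

`sd_noise` is interpreted as a per-gene, per-assay (total vs nascent),
per-condition distortion — probe-efficiency differences that survive
replicate averaging. Per-replicate noise is a separate, smaller knob
(default 0.1 log2 in the cohort pipelines). Without a distortion layer
that survives averaging, the "noise" model would have no observable
content at realistic replicate counts.

### Nascent-capture bias

`simulate_labeling` supports a per-gene bias on the nascent assay
(`capture_sd`, default 0.5 log2 in cohort pipelines), shared between the
two conditions of the same gene. This emulates sequence-dependent capture
efficiency of labeled RNA (4sU incorporation scales with uridine
content), which is a gene property and therefore common to orthologs. It
cancels exactly in ortholog Δnew comparisons, but not between unrelated
genes — which is why shuffling the ortholog map produces the noise-model
signature rather than the independent-model one: the shuffled "degradation
differences" are dominated by symmetric gene-level nascent-assay offsets
that hit Δnew and Δ(new−total) coherently.

## Decay-course estimators

For strains SW and WT after transcriptional arrest, the reference-
normalized log2 ratio declines linearly with slope `-(k_SW - k_WT)/ln2`.

- `delta_swap = log2[(SW_g/WT_g)/(SW_c/WT_c)]` — steady-state effect at
  t = 0, reference gene c measured in the same strains.
- `fit_decay_slope` — OLS of the log2 ratio on time (scipy
  `linregress`). Replicates are pooled into one fit by default; averaging
  per timepoint first is available (`mode="mean"`) since the source data
  description leaves the choice open (both agree exactly for balanced
  designs).
- `delta_deg = log2((1/t½ - slope)/(1/t½))`, with the native half-life
  t½ imported from prior measurements. Under noiseless kinetics this is
  exactly `log2(k_SW/k_WT)`. `1/t½ - slope ≤ 0` would imply a negative
  rate and raises.
- Interval changes `Δ_{i,i+20} = log2(m_{i+20}/m_i)` are paired by
  (replicate, interval start) between strains and tested with a
  two-sided one-sample t-test on the differences; all-zero differences
  return p = 1 by convention rather than a degenerate statistic. Interval
  starts are every available grid point with a partner 20 min later
  (i ∈ {0,20,40} for 4-point courses).
- Effects are classified `increased` (negative slope: the swapped
  sequence accelerates decay), `decreased`, or `not_significant`
  (p > 0.05). Steady-state effects are called significant at fold-change
  ≥ 1.4 in either direction (|Δswap| ≥ log2 1.4 ≈ 0.485) — the symmetric
  reading of a "40% change" cutoff.
- `exponential_fit_quality` is the R² of log2(level) vs time;
  `select_best_fit` keeps the top 12% by default, the filter used to
  restrict control analyses to genes best described by single-exponential
  decay.

**Calibration caveat.** The three 20-minute intervals overlap at their
shared timepoints, so consecutive paired differences have a −0.5 lag-1
autocorrelation under iid per-measurement noise. The t-test is therefore
conservative: the Monte-Carlo null rejection rate at nominal α = 0.05 is
≈ 0.006 (10,000 genes, sd 0.1, two replicates). Power remains high —
≈ 0.999 at a true slope difference of 0.025/min under the same noise.
The package implements the published pairing faithfully rather than
decorrelating it; the test suite asserts the conservative behavior.

## Gene-pair architecture analysis

Adjacency means consecutive gene bodies on a chromosome, sorted by start,
in 0-based half-open coordinates; overlapping neighbours are excluded
(negative intergenic length has no promoter-sharing reading) and counted.
Strand combinations map to divergent (−,+), convergent (+,−) or tandem
(equal). A gene may belong to two pairs. Pair similarity is the
correlation of a per-gene statistic between left and right members,
Pearson unbinned and Spearman within bins (both selectable). Binning is
equal-count by covariate rank *within* each architecture, ties broken by
genomic order, so bin sizes differ by at most one and bins are comparable
across architectures. Fewer than three usable pairs yields an explicitly
undefined (NaN) correlation, never a silent zero.

The synthetic genome places each pair on its own chromosome so that
annotation adjacency coincides exactly with the generated pairing.
Divergent pairs share one latent promoter-activity change feeding both
members' Δsyn and Δdeg with variance fraction `coupling_strength`
(sqrt-weights, so the expected pair correlation equals the coupling);
optionally the effective coupling decays as `exp(-L/scale)` with
intergenic length L. Expression profiles for co-expression binning use
the same shared/own variance split.

The shared-regulator analysis compares gene pairs sharing ≥ 3 regulators
with pairs sharing none. Pair similarity is the absolute difference of
the per-gene statistic — a stand-in metric, since the source analysis
names no formula. Pairs are stratified into five equal-count bins of
expression-change similarity; within each stratum a one-sided
Mann–Whitney test asks whether co-regulated pairs are more similar in
degradation change, and strata are pooled by Stouffer's method weighted
by sqrt(stratum size). Per-stratum medians at realistic sizes are noisy;
the pooled test is the primary readout.

## Δtotal/Δnew framework

From four genes × replicates matrices and an explicit two-column ortholog
map: replicate means per gene, an intensity filter (drop ortholog pairs
below the 5% total-intensity quantile of either condition, plus
non-positive means), `Δ = log2(condition2/condition1)` for total and
nascent, an implausibility filter (|Δ| > 5 log2 units dropped), and
centering of each Δ vector to zero. Median centering is the default
(robust to the heavy class tails); mean centering is a switch. The filter
thresholds are configuration parameters reported in output provenance —
the reference analysis states that its trends survive with and without
filtering, so they are not load-bearing.

Turnover from labeling inverts `new/total = 1 - exp(-k_deg·t_label)`
exactly (no short-window linear approximation), flagging `new ≥ total` or
`new ≤ 0` as NaN noise artifacts. Differential degradation is called at
1.75-fold with BOTH criteria required: half-life ratio ≥ 1.75 *and*
|Δnew − Δtotal| ≥ log2 1.75. Raising the fold can only shrink the
classes.

`shift_report` returns the six class-conditional medians and calls the
generating pattern from D_new and D_total (differences of medians between
the higher- and lower-degradation classes): both > 0.05 log2 → coupled;
D_total < −0.05 with |D_new| < 0.3·|D_total| → independent;
D_total < −0.05 with D_new > 0.05 and comparable magnitude → noise;
anything else, or an empty differential class, → no call. The 0.05
shift floor and 0.3 dominance ratio separate the three signatures by an
order of magnitude at the default generator settings (Model I realizes
|D_new|/|D_total| ≈ 0.15, Model II ≈ 1). The call is a set of explicit
sign/magnitude checks reported alongside the medians, never a p-value.
The non-ortholog null permutes the map's second column with a seeded
generator and re-runs the full chain.

The degradation-vs-level correlation uses Spearman by default. Sign
convention: positive Δdeg (here Δnew − Δtotal) means faster degradation
in condition 2, so a *positive* correlation with Δtotal indicates
transcriptional over-compensation (Model III) and a negative one the
independent model.

## Reproducibility

A single root seed drives everything; each operation derives its own
child stream from (seed, operation code), so stages never perturb one
another's draws and identical configs give byte-identical outputs. Every
output table carries a provenance header (version, config hash, full
config JSON, seed) sufficient to regenerate the file; a test re-runs the
pipeline from a parsed header and compares bytes.

## Problem sizes

Cohort sizes were chosen to make the qualitative claims statistically
unambiguous while keeping any single check within seconds: 4,000-gene
labeling cohorts (×20 seeds per model for the pattern-call confusion
check), 500 pairs per architecture, 10,000 genes for t-test calibration,
2,000 for power. Correlation standard errors at these sizes are below
0.05, an order of magnitude smaller than the effects asserted.

## What the generator does not emulate

No sequence-level simulation (promoters, motifs, probes): coupling acts
directly at the rate level. No microarray preprocessing artifacts beyond
multiplicative noise and the per-assay/per-gene distortions described. No
cell-cycle or condition dynamics: two static conditions only. Passing
tests therefore demonstrate correctness of the estimators and internal
consistency of the model-comparison logic under first-order kinetics with
log-normal noise — not robustness to the full messiness of hybridization
data (saturation, background, probe cross-reaction), nor to violations of
single-exponential decay, which the best-fit filter only partially
addresses.
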