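# promcoupling

Transcription and mRNA degradation are not independent: promoter
sequences can influence how fast a transcript is later degraded in the
cytoplasm, and changes in degradation are often accompanied by larger,
compensating changes in transcription. `promcoupling` implements the
quantitative toolkit for studying this coupling in three settings, plus a
synthetic-data generator with known ground-truth kinetics that stands in
for the original strain measurements and expression accessions:

1. **Arrest-course estimators** (`promcoupling.decay`) — after a global
   transcriptional arrest, the log2 ratio of mRNA levels between two
   strains declines linearly with slope `-(k_SW - k_WT)/ln2`. The module
   fits that slope by least squares, converts it to a degradation effect
   `Δdeg = log2((1/t½ − slope)/(1/t½))` using the native half-life t½,
   quantifies steady-state effects `Δswap = log2[(SW_g/WT_g)/(SW_c/WT_c)]`
   against a reference gene, and tests significance with a paired t-test
   over 20-minute interval changes `Δ_{i,i+20} = log2(m_{i+20}/m_i)`.
2. **Neighbor-pair analysis** (`promcoupling.pairs`) — divergently
   transcribed adjacent genes share their upstream intergenic region and
   potentially promoter elements. The module classifies consecutive gene
   pairs into divergent / convergent / tandem architectures from BED6 or
   GFF3 annotation, correlates per-gene degradation statistics within
   each architecture, bins pairs by intergenic length or co-expression
   (equal-count), and compares non-adjacent genes that share ≥ 3
   transcription-factor regulators against pairs sharing none,
   stratified on expression similarity.
3. **Δtotal/Δnew model comparison** (`promcoupling.coupling`) — with
   metabolic labeling, `new/total = 1 − exp(−k_deg·t_label)` encodes
   turnover. Centered log2 ratios of total (Δtotal) and nascent (Δnew)
   mRNA between two conditions, a dual 1.75-fold differential-degradation
   classifier, and class-conditional median shifts distinguish three
   generative models: independent transcription, measurement noise, and
   coupled transcription that over-compensates degradation changes.

The package is organized as a library (`src/promcoupling/`), numbered
analysis drivers (`analysis/01…04`), and a `promcoupling` command-line
pipeline (`simulate`, `decay-fit`, `pairs`, `coupling`, `run`, `report`)
driven by a YAML/JSON config with a single root seed; identical configs
produce byte-identical outputs. See `docs/methods.md` for the models,
assumptions and numerical choices.

## Worked example

```sh
python analysis/01_simulate_inputs.py
python analysis/02_swap_decay_analysis.py
```

prints, for a 12-gene simulated swap cohort (3 replicates, timepoints
0/20/40/60 min, measurement sd 0.1 log2):

```
decay-fit over 12 genes:
classification
increased          6
decreased          4
not_significant    2
median |delta_deg - truth| = 0.040 log2 units (n=12)
direction agreement among significant calls: 1.00
```

i.e. the fitted degradation effects deviate from the generator's true
log2 rate changes by ~0.04 log2 units, and every significant call points
in the true direction. The textbook single-course case is:

```python
>>> from promcoupling import decay
>>> decay.fit_decay_slope([0, 20, 40, 60], [0, -1, -2, -3]).slope
-0.05
>>> decay.delta_deg(-0.05, 20.0)   # native half-life 20 min
1.0
```

a slope of −0.05/min means the swap strain's relative mRNA level halves
every 20 minutes; against a 20-minute native half-life that is a 2-fold
(1 log2 unit) increase in degradation rate. Continuing with the pair and
turnover drivers:

```sh
python analysis/03_neighbor_pairs.py
python analysis/04_turnover_models.py
```

```
unbinned Pearson correlation of degradation changes:
  divergent  r=+0.341 p=1.9e-05 (n=150)
  convergent r=+0.046 p=0.58 (n=150)
  tandem     r=-0.129 p=0.11 (n=150)
divergent Spearman r across intergenic-length bins (short -> long): +0.612 +0.211 +0.222 -0.162
...
  independent  D_new=+0.327 D_total=-2.122 -> called independent
  noise        D_new=+1.040 D_total=-1.011 -> called noise
  coupled      D_new=+3.403 D_total=+1.019 -> called coupled
observed cohort called: coupled (shuffled-ortholog null: noise)
```

Only divergent pairs — the ones sharing an upstream region — correlate
in their degradation changes, most strongly at short intergenic
distances; and the labeling cohort generated under over-compensating
coupling (β = 2) is correctly identified by its median shifts, while
shuffling the ortholog map reproduces the noise signature.

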