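# Methods

This note documents the statistical model implemented by `noiseplast`, the
parameter defaults and the reasons behind them, the scope of the synthetic
generator, and the main numerical choices.

## 1. From events to population statistics

**Input.** An event table with one row per recorded cell:
`strain_id, condition_id, replicate_id, batch_id, fsc, ssc, yfp_raw`
(linear-scale instrument units). CSV is the canonical loss-free format;
minimal FCS 3.0 (list mode, float32) is supported for interchange, one
population per file.

**FSC gate.** For each (condition, batch) all strains are pooled into one
cumulative population. The mode of log10 FSC is the argmax of a Gaussian
kernel density estimate with Silverman's bandwidth
`0.9 · min(sd, iqr/1.349) · n^(−1/5)`. The gate is the closed interval
mode ± 0.1 log10 units (width exactly 0.2). A narrow gate removes most of
the cell-size contribution to total fluorescence without a per-event size
regression. The default half-width 0.1 and the per-(condition, batch)
pooling are fixed protocol choices, not tuned quantities.

**Background correction.** The autofluorescence level is the linear-scale
arithmetic mean of the gated reporter-free control strain in the same
(condition, batch) (the median is available via
`PipelineParams.autofluorescence_stat`). It is subtracted per event;
events with corrected intensity ≤ 0 are removed because their logarithm is
undefined. A control population needs ≥ 100 gated events
(`min_control_events`) for a stable mean.

**QC floor.** Populations retaining fewer than `min_events = 4000` events
after gating and background removal are discarded. At 4,000 events the
standard error of `V_pop` is about `V_pop/√(2·4000) ≈ 1.1%`, small against
the gene-to-gene differences of interest. When analysing reduced-size
simulations the floor should be scaled with the per-population event count
(the narrow gate keeps roughly half the events).

**E_pop / V_pop.** Mean and sample (n−1) standard deviation of log10
corrected fluorescence per population. Sample SDs are used throughout; at
≥ 4,000 events the denominator choice is negligible for `V_pop`, and for
plasticity over ~20 conditions it is the unbiased convention. A constant
population has `V_pop` exactly 0 (guarded against floating-point summation
residue).

**Replicate averaging.** `E_pop` and `V_pop` are averaged (unweighted)
over biological replicates per (gene, condition); conditions with fewer
than `min_replicates = 2` surviving populations are dropped. Averaging
after the per-population SD (rather than pooling events) keeps biological
replicates as the unit of measurement error.

## 2. Mean-compensated noise (DM_V)

Noise depends on mean expression: at low means the intrinsic
(birth/death counting) component gives log-scale SD falling with the mean,
while at high means an extrinsic floor dominates. To compare genes at
different expression levels, the trend of `V_pop` versus `E_pop` is
estimated and removed:

1. Pool all (gene, condition) points and sort by `E_pop` (stable sort with
   deterministic tie-breaking).
2. Running median of `V_pop` in a centred window of `window` points. The
   window shrinks symmetrically at the edges (no extrapolation). The
   median, not the mean, makes the trend robust to the long-tailed noise
   outliers typical of expression data. `window="auto"` uses the odd
   number nearest 15% of the point count, clipped to [11, 101] — wide
   enough to average over gene-level scatter, narrow enough to follow the
   intrinsic-noise bend — and is capped at half the data so at least two
   full windows exist.
3. Cubic smoothing spline through the running-median sequence.
   `smoothing="auto"` selects the penalty by generalised cross-validation;
   `smoothing=0` makes the trend interpolate the running median exactly
   (the configuration used by the oracle tests); a positive float is used
   directly.
4. `DM_V` is the vertical residual `V_pop − trend(E_pop)`; a gene's noise
   score is its unweighted mean `DM_V` over conditions.

The same operator applies to any (mean, SD) table via `dm_from_table`,
e.g. across-environment mRNA statistics.

`NoiseTrendModel` / `NoiseTrendResult` expose the fit statsmodels-style
(`fit()`, `residuals`, `predict()`, `summary()`).

## 3. Plasticity

A gene's plasticity is the sample SD of its replicate-averaged `E_pop`
across conditions, requiring `min_conditions = 5` conditions so the SD is
not dominated by a single pair. It is a log-scale, mean-free quantity, so
genes of different absolute expression are comparable.

## 4. Association analyses

All tests are non-parametric and two-sided, matching skewed cross-gene
distributions:

- **Spearman correlation** with average-rank ties. For n ≤ 9 the p-value
  is exact (full permutation enumeration); otherwise the t approximation
  with n−2 degrees of freedom.
- **Wilcoxon rank-sum** (Mann–Whitney) via scipy's `method="auto"`: exact
  for small tie-free samples, tie-corrected normal approximation
  otherwise.
- **Kruskal–Wallis** with tie correction; an all-identical input carries
  no evidence and is reported as p = 1.
- **Brown–Forsythe** variance comparison (Levene with median centring),
  robust to non-normality.
- **Cumulative rank-scan curve**: genes ranked by noise (descending); for
  each cutoff — the value of the gene at rank 6, 7, …, n — the mean ± SE
  (sample SD/√n) of a covariate over all genes at or above the cutoff.
  Starting at the 6th gene avoids meaningless 1–2 gene prefixes; ties at a
  cutoff are all included.
- **PCA** of the gene × condition mean-expression matrix: conditions
  missing more than 4 genes are excluded first, then only genes complete
  in the remaining conditions are kept; conditions are observations, each
  gene is centred; SVD gives scores, loadings and variance fractions
  (summing to 1).

## 5. Growth classification

Threshold = grand mean of sterile-control OD595 + 5 × (mean of per-set
sample SDs). Five SDs keeps the false-growth rate negligible under
approximate normality of sterile readings. A strain grows under a
condition iff a strict majority of replicate wells strictly exceeds the
threshold. Labels: grows everywhere / conditionally essential (grows
somewhere and fails somewhere) / no growth anywhere (flagged for manual
review — it may reflect a sick strain or an assay failure rather than
conditional essentiality).

## 6. Synthetic generator

Per gene g, condition c, cell i:

- Baseline `β_g ~ N(2.8, 0.35)` (log10 a.u.) — a realistic 2–3 decade
  dynamic range above an autofluorescence background of ~20 a.u.
- Regulator counts `msr_g ~ Poisson(2.0)` for nonessential genes,
  `Poisson(0.8)` for essential (essential genes tend to have fewer
  metabolic sensory regulators); `tr_g = msr_g + Poisson(1.5)`.
- Plasticity scale `P_g = softplus(intercept + 0.15·msr_g + N(0, 0.6))`
  with intercepts −1.5 (nonessential) / −2.2 (essential): essential genes
  are planted as less environmentally responsive. Condition effects
  `δ_gc = P_g · z_gc`, `z ~ N(0,1)`; true mean `L_gc = β_g + δ_gc`.
- Extrinsic noise `η_g = softplus(loc + 0.5·u_g)` with loc −2.0 / −2.5
  (essential genes have a lower noise floor). `u_g` is coupled to the
  plasticity latent through a Gaussian copula with target *rank*
  correlation 0.6 (nonessential) and 0.0 (essential); the latent Pearson
  value `r = 2·sin(πρ/6)` on empirical normal scores makes the planted
  Spearman correlation exact up to gene sampling error.
- Per cell: extrinsic deviation `N(0, η_g)` on the log10 scale; expected
  abundance `μ = 10^(L+e)`; intrinsic draw `Gamma(μ/b, b)` with burst size
  `b = 10`, giving the canonical low-mean `CV² = b/μ` regime and a
  mean-independent extrinsic floor at high expression.
- Cell size `10^N(φ_c, 0.04)` with condition-dependent `φ_c ~ N(2.5,
  0.15)`; FSC adds 0.02 log10 instrument noise; YFP is scaled by relative
  cell size, multiplied by 10^N(0, 0.02) instrument noise, plus
  log-normal(ln 20, 0.3) autofluorescence. The control strain emits
  autofluorescence only.
- Each biological replicate is measured on its own day (`batch_id`
  follows `replicate_id`), so gates and background are re-estimated per
  replicate as in a real screen.

Determinism: gene- and condition-level parameters come from dedicated
seed sequences; each population's events come from a substream keyed by
(seed, gene index, condition index, replicate index). For fixed truth
parameters, adding replicates never perturbs existing populations.

**Scope and limits.** The generator reproduces the statistical structure
the pipeline must handle (mean-dependent intrinsic noise, extrinsic floor,
cell-size confounding, background, batch structure, planted associations).
It does not model growth-rate coupling, cell-cycle phase, reporter
maturation kinetics, spectral spillover, instrument saturation, or doublet
events; conclusions about those phenomena cannot be tested with it. The
separate growth-assay generator plants well-separated OD distributions and
is not a model of marginal growth.

## 7. Numerical choices

- **KDE at scale.** The FSC mode uses binned Gaussian convolution (2,048
  bins, `scipy.ndimage.gaussian_filter1d`), numerically equivalent to a
  direct KDE at grid resolution but linear in the event count; pooled
  populations here reach ~10⁶ events. Unit tests cross-check the argmax
  against `scipy.stats.gaussian_kde` on dense grids.
- **Spline conditioning.** Long running-median knot sequences with nearly
  coincident abscissae can make the GCV normal equations numerically
  singular. Knots are collapsed onto at most 512 equal-count bins (means)
  before fitting — the running median is already smooth at that
  resolution — with progressively coarser fallbacks (256, 64 bins, then a
  plain interpolant) if the solver still fails.
- **Exact zero guard.** Sample SDs of constant vectors are returned as
  exactly 0.0 rather than the ~1e−16 summation residue, so the noise-free
  simulator limit yields `V_pop = 0` exactly.
- **Determinism.** All stochastic code uses `numpy.random.Generator`
  seeded explicitly; pipeline outputs are bit-reproducible for a given
  input. Sorting before the trend fit breaks ties deterministically.
- **Streaming.** The pipeline accepts an iterable of per-(condition,
  batch) chunks, keeping peak memory bounded by one chunk regardless of
  screen size.

## 8. Limitations

- `DM_V` is identified only up to the vertical placement of the trend:
  individual values are comparable within one fitted pool, not across
  separately fitted datasets.
- The trend fit assumes enough points (≥ 2 windows) and a mean range wide
  enough to see the intrinsic-noise bend; with few genes or a narrow
  expression range the compensation is weak and residuals retain mean
  dependence.
- The exact Spearman p-value is enumerated only for n ≤ 9 (9! ≈ 3.6×10⁵
  permutations); above that the t approximation is used, which is slightly
  anti-conservative for very small n with heavy ties.
- Replicate averaging with exactly two replicates gives noisy per-pair
  SDs; the pipeline reports `n_replicates` so downstream users can weight
  or filter.
- The growth classifier assumes sterile-well readings are roughly normal;
  heavy-tailed contamination would require a robust threshold instead.
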