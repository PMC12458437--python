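# Methods

## The estimand and its decomposition

For taxon *d* in sample *n*, absolute abundance factorizes as
`W_dn = Wpar_dn * Wperp_n`, with the composition `Wpar` on the simplex per
sample and the scale `Wperp` the total microbial load. The engine's
estimand is the absolute log2 fold change between two conditions
(indicator `x_n`),

```
theta_d = mean_{n: x_n=1} log2 W_dn - mean_{n: x_n=0} log2 W_dn
        = theta_par_d + theta_perp,
```

where `theta_par_d` is the same contrast on log2 compositions and
`theta_perp` the contrast on log2 loads, shared by all taxa. Because the
mean is linear, the identity is exact per Monte-Carlo replicate; the
implementation defines `theta` as the sum of the parts and tests the
equivalence with the direct group-mean contrast to 1e-10.

Sequence counts identify only `theta_par`; `theta_perp` is not identified
by the data. The engine therefore treats the analysis as a partially
identified model: inference proceeds jointly over draws from a measurement
model for composition and a *scale model* expressing the analyst's
knowledge (or assumption) about load.

## Measurement model

Per sample, composition replicates are drawn from the conjugate posterior
`Dirichlet(y_.n + prior_mass)`. Defaults: `prior_mass = 0.5` per cell (the
uniform-prior convention of Dirichlet-multinomial count frameworks) and
`S = 128` replicates, which keeps the Monte-Carlo error of averaged
adjusted p-values small relative to the 0.05 decision threshold at
desk-scale runtimes; both are configurable. Draws are independent across
samples (the measurement model factorizes over samples). Zero counts yield
strictly positive, stochastically small proportions — no pseudocount is
added to the data. A sample with zero total count is only meaningful with a
positive prior mass; it then draws from the prior alone and a warning is
logged.

## Scale models

All scale models return an `(S, N)` array of log2 loads; `gamma` is always
a standard deviation in log2 units.

- **TSS / PIM** (`tss_scale`): within replicate *s*, condition-0 samples
  get log2 load 0 and condition-1 samples a single shared draw
  `theta_perp(s) ~ N(0, gamma^2)`. `gamma = 0` is classic total-sum scaling
  (equal loads assumed); `gamma = 1` is the default Bayesian PIM prior —
  `2^{±1.96}` gives the implied central 95% fold interval 0.257–3.89, i.e.
  the prior asserts one condition's load is within a factor of roughly
  0.26–3.89 of the other's. One draw per replicate (no per-sample scale
  noise) is deliberate: the assumption concerns the *between-condition*
  shift, and per-sample variants would change what the prior states.
- **External** (`external_scale`): `N(log2 q_n, gamma^2)` per sample and
  replicate, for measured loads `q_n`; `gamma = 0` uses the measurements
  verbatim. Default `gamma = 0.5` reflects typical flow-cytometry/qPCR
  measurement uncertainty on the log2 scale.
- **Predicted** (`predicted_scale`): every replicate carries the identical
  prediction vector. This reproduces the rescale-by-predicted-load
  construction, which propagates no prediction uncertainty; the zero
  replicate-variance property is itself a diagnostic (it is what makes
  overconfident downstream calls possible). Predictions are not
  mean-centered — any constant modality offset cancels in between-group
  differences.

## Testing and averaging

Within each replicate, every taxon is tested across conditions with a
two-sided Wilcoxon rank-sum test on log2 absolute abundances, and
Benjamini–Hochberg adjustment is applied across taxa. The reported
per-taxon `p_adj` is the arithmetic mean of within-replicate adjusted
p-values (the alternative — average raw p, adjust once — is available as
`p_average="raw"` but is not the default, matching the convention of
Dirichlet-replicate DA frameworks). Significance is `p_adj < alpha`
(default 0.05); direction is the sign of mean `theta`, with exact zero
mapped to `0`.

Rank-sum details: the normal approximation is tie-corrected and applied
without continuity correction, vectorized across all (replicate, taxon)
slices; ties are detected per slice and corrected exactly when present
(with continuous Monte-Carlo draws they essentially never are). An exact
mode enumerates the permutation null with mid-ranks up to combined n = 16,
returning `P(|T - E T| >= |t_obs - E T|)`; above that the enumeration cost
is not justified given the normal approximation's accuracy. Two identical
groups give p = 1. BH is implemented as the vectorized step-up formula so
it can run along the replicate axis in one call.

## Load-anchored ground truth and scoring

With loads measured for every sample, reference calls are produced by the
engine under `external_scale(measured, gamma = 0.5)` — each log2
measurement treated as the mean of a normal with sd 0.5 to acknowledge
measurement error. Scoring a method against the reference: TP = both
significant with equal sign; FP = method significant while the reference is
not, *or* both significant with opposite signs (a wrong-sign discovery is a
false discovery; this also keeps the four counts an exact partition of the
taxon set); FN = reference-only significant; TN = neither. PPV, NPV and FDR
follow, undefined (NaN) on zero denominators; across-dataset medians are
taken over defined values only, with the undefined count reported. Truth
and method runs share alpha; their Monte-Carlo seeds are independent except
in oracle self-tests.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with known
ground truth on the absolute scale:

- baseline log abundances `mu_d ~ N(0, baseline_sd_log^2)` with
  `baseline_sd_log = 2` (natural log), giving the multi-order-of-magnitude
  between-taxon spread of gut profiles;
- a `floor(frac_diff * D)` subset of taxa receives an absolute effect of
  `effect_log2` log2 units with independent fair-coin signs (symmetric by
  default so no net compositional bias is built in);
- per-sample log-normal biological noise (`sample_sd_log = 1`);
- an explicit `scale_shift_log2` multiplying condition-1 totals, so the
  true `theta_perp` is controllable independently of taxon effects;
- true load = the per-sample total; measured load adds
  `N(0, 0.5^2)` on the log2 scale (matching the measurement-error level the
  ground-truth scale model assumes);
- sequencing depth log-normal around 20,000 and *independent of load* —
  depth carries no information about scale;
- counts multinomial at that depth from the sample's true proportions.

Effects are placed on absolute abundances because that is the scale on
which ground truth is defined; compositional truth then follows from
closure rather than being asserted. `truth_flags` marks taxa by their
injected per-taxon effects; note that a nonzero `scale_shift_log2`
additionally changes every taxon's absolute abundance, so load-anchored
reference calls on such datasets legitimately include effect-null taxa.

What the generator does **not** emulate: real taxon-taxon correlation,
zero inflation beyond multinomial sampling, amplicon-vs-shotgun error
profiles, contamination, or any distribution fit to real cohorts. Passing
benchmarks here show the machinery behaves as designed under its stated
assumptions, not that the same FDR levels will be observed on real data.

Overlap scenarios relabel a fresh dataset's taxa so that exactly
`round(rho * D)` carry identifiers from a training panel, for studying
zero-fill feature alignment and prediction collapse under covariate shift.

## Benchmark scenario

The scaled-down benchmark (tests and `scripts/acceptance.py`) uses 20
datasets with D = 100 taxa, N = 25 per group, S = 128 replicates, a 2-log2
between-condition load shift, and 20% differential taxa with |effect| = 4
log2 units. Differential taxa must be present for the comparison to be
well posed: with a *pure* load shift the count distribution is identical
between conditions, so composition-only callers (TSS and the PIM prior
alike) make essentially no discoveries and FDR (FP / discoveries) is
undefined — in that regime TSS's failure is a collapse of NPV (it misses
every shift-driven positive), which the suite checks separately. Effect
magnitude is set above the shift so that no taxon's true absolute change
sits exactly at zero: with |effect| = shift, every down-effect taxon would
be exactly null and truth signs would be decided by noise. Problem sizes
throughout (S = 128, 20 datasets, 50 recovery seeds at N = 50/group) are
chosen to keep the full suite at desk scale while leaving Monte-Carlo
error well inside the asserted margins.

## Numerical choices and edge cases

- Internal canonical scales: log2 for loads and fold changes in the
  engine; log10 for prediction-evaluation metrics. Converters live in
  `sridiff.io` and accept linear, log10 or log2 inputs (non-positive
  linear values are rejected).
- `mean_centered_r2` and `sample_correlation` return NaN with a logged
  warning when a variance is zero, so batch evaluation proceeds. A
  constant vector centers to exact zeros, making the constant-predictor
  identity R² = 0 exact in floating point.
- `mode_frequency` rounds to 6 decimals before counting equal predictions
  (float equality needs a convention; 6 decimals is far below any
  meaningful load difference).
- Feature alignment does not renormalize after zero-fill/drop by default
  (mirroring the silent behavior of audited prediction pipelines);
  `renormalize=True` is available and reported.
- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; every public sampler is bit-reproducible for a fixed seed, and
  derived seeds stay below 2^31.

## Known limitations

- Two-condition designs only; no covariates, pairing, or >2 groups.
- The measurement model has no taxon correlation (no logistic-normal
  variant) and no zero-inflation component.
- Scale models are global: no covariate-dependent or hierarchical load
  models, and ML predictions cannot yet carry uncertainty (they could, as
  informative priors, but that is future work).
- External DA tools are scored via their exported tables, not executed.
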