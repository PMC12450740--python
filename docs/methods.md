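# Methods

## Model and procedure

`wqsmix` estimates the joint association of `c` correlated, quantile-scored
exposure components with a continuous outcome observed repeatedly within
subjects. The mixture effect is a single slope on the weighted quantile sum
index `WQS = Σ_i w_i q_i`, with weights constrained to the unit simplex so
that each `w_i` is interpretable as the component's relative contribution.
In the stratified interaction form, weights are estimated separately per
stratum (`2c` parameters for two strata) and the fixed-effect structure
carries a reference slope `b1`, a stratum main effect, and an index-by-
stratum interaction `b12`; the second stratum's slope `b2 = b1 + b12` is
derived inside every fit, never from cross-fit medians (medians do not add).

Estimation is split in two stages with different error models, on the
argument that weight estimation is a mean-model problem (quasi-likelihood
consistency holds under a misspecified working covariance) while hypothesis
testing is not:

* **Training stage** (per split): simplex-constrained least squares assuming
  independent rows, repeated over an ensemble and averaged.
* **Holdout stage** (per split): random-intercept linear mixed model fitted
  by REML, conditioning on the training weights, giving variance components
  `σ_b²` (between subjects) and `σ_e²` (residual).

Repeated random splits (`rh`, default 30) give a distribution of holdout
estimates summarized by the median and the 2.5/97.5 percentiles (linear
interpolation between order statistics).

## Quantile scoring

Cut points are the empirical sample quantiles at `k/nq` (`k = 1..nq−1`)
under the linear-interpolation definition; a value's score is the number of
cut points strictly below it. Tied raw values therefore always share a
score, independent of row order. Scores are computed on the **full**
dataset before splitting, so holdout rows are scored on the same scale as
training rows; no outcome information is involved. Columns whose ties
collapse bins score fewer effective bins with a warning; constant columns
score 0 everywhere with a warning. Bins of distinct values differ in
occupancy by at most 1.

## Splitting

The split unit is the **subject**, so all of a subject's rows fall on one
side — a row-level split would leak the subject's random intercept from
training into holdout. A row-level mode exists for single-occasion data.
With a stratifying factor, training counts per stratum are allocated by
largest-remainder rounding of `train_fraction × n_stratum`, so stratum
proportions match the full data within rounding and no stratum can vanish
from either side. One master `SeedSequence` spawns a child generator per
split: plans are reproducible and splits are independent streams.

## Constrained estimation

The training objective is the residual sum of squares of

```
y = b0 + Σ_s slope_s · (Q w_s) · I(stratum = s) + g·I(s=2) + γ'z
```

minimized over softmax-reparameterized weights `w_s` (automatically on the
simplex), unconstrained linear coefficients, and per-stratum slopes bounded
by the declared direction. Parameterizing the slopes as `(b1, b2)` rather
than `(b1, b12)` turns the coupled constraint `b1 + b12 ≥ 0` into simple
bounds. L-BFGS-B with an analytic gradient does the minimization.

Numerical choices: initialization at uniform weights with linear
coefficients from OLS (slopes clipped to the feasible sign); `ftol = 1e-8`,
`gtol = 1e-5`, `maxiter = 1000`. The loose gradient tolerance is deliberate:
weights estimated at zero push their logits toward −∞ where the gradient
decays slowly, and the extra iterations change averaged ensemble weights by
less than 1e-3. On noiseless data the fit recovers generating weights to
≈1e-9 and matches a brute-force 1-simplex grid search to well under 1e-3.
The softmax map is translation-invariant (one flat direction); L-BFGS-B
handles this without regularization.

## Ensembles

* **Bootstrap** (`b = 100` default): resampling with replacement at the
  subject level (cluster bootstrap), since rows within a subject are
  correlated; a row-level mode exists. Final weights are the arithmetic
  mean of converged per-fit weights, renormalized per stratum. More than
  20% non-converged fits is an error.
* **Random subsets** (`b` subsets of size `⌊n_strata·√c⌋` by default;
  e.g. 10 for 30 components and 2 strata): used when parameters outnumber
  observations. Each replicate samples *original* components — not
  stratum-expanded parameters — and estimates weights for the sampled
  components in **both** strata, so every stratum is covered in every
  replicate. A component's final weight is its mean over the replicates
  that sampled it (then renormalized); per-fit weights are averaged on
  their subset simplices first and renormalized after, and a component
  never sampled in a converged fit is an error instructing more replicates.

By default each holdout's index uses its **own** training split's averaged
weights, preserving train/holdout separation per replicate; a grand-average
mode (one pooled weight vector across all training splits) is available for
sensitivity analysis.

## Holdout inference

statsmodels `MixedLM` fits the random-intercept model by REML. A boundary
estimate (`σ_b² → 0`) is a valid REML solution and is not flagged; only
optimizer failures are, and flagged fits are excluded from summaries (their
count is reported). With one occasion per subject the variance split is
unidentifiable — a warning is issued, and the fixed effects coincide with
OLS (verified to 1e-4).

The intra-subject correlation matrix is the pairwise Pearson correlation of
**marginal** residuals (outcome minus fixed-effect prediction) reshaped to
subjects × occasions; pairs with fewer than 3 contributing subjects are
reported missing. Marginal rather than conditional (BLUP) residuals are
used because the former retain the between-subject variance that the
correlation is meant to describe, and because empirical correlations can
show unequal off-diagonals that the compound-symmetry model value
`σ_b²/(σ_b² + σ_e²)` (also reported) cannot.

The significance flag marks a coefficient when its 2.5–97.5 percentile
interval across holdouts excludes zero; a heuristic "borderline" label marks
intervals whose endpoint nearest zero lies within 10% of the median's
magnitude. These are descriptive: see Limitations.

## Synthetic data generator

The generator emulates a small repeated-measures exposure study: default
shape 14 subjects × 3 occasions × 30 components in two equal strata,
mirroring a pilot-scale design. Exposures come from a Gaussian copula
(AR(1) correlation 0.5 by default, block structure available) with
lognormal marginals, since environmental concentrations are right-skewed;
quantile scoring is invariant to the monotone map, so this affects realism
only. The truth acts on the quantile-score scale — the outcome surface is
`b0 + b_s·Σ w_{s,i} q_i + stratum + covariates + u + e` — matching the
model the analysis estimates, which makes recovery well-posed. Default
signal parameters: `b1 = 0.5`, `b12 = 0.3`, three active components per
stratum with weights ∝ (0.5, 0.3, 0.2) on disjoint supports between strata
(so stratum-specific weight recovery is testable), `σ_b² = 0.6`,
`σ_e² = 0.4` (intra-subject correlation 0.6), a subject-level standard-
normal "age" covariate with slope 0.05, and a stratum main effect of 0.2.

What the generator does **not** emulate: within-subject correlation of
exposures across occasions (rows are drawn independently), missing data,
measurement error in components, non-Gaussian outcomes, and any
physiological dose-response structure. Passing tests therefore demonstrate
statistical correctness of the machinery under the stated model, not
robustness to those features of real data.

Problem sizes in the test suite and the reproduction script are scaled to
single-CPU runs: recovery checks use 120–200 subjects with 8–10 components,
15–30 bootstrap fits per split and 3–30 repeated holdouts; the null
calibration uses 200 replicates of 50 subjects at `rh = 10`.

## Known limitations

* **The percentile-interval significance flag is anticonservative under the
  null.** Holdout estimates from overlapping splits of one dataset are
  mutually correlated (two 60% holdouts share roughly a third of subjects),
  so the percentile interval is centered on the dataset's shared sampling
  noise and its width reflects only split-to-split spread. In simulations
  with zero mixture effect the flag fires in roughly 18–30% of replicates
  across a wide range of designs (including the pilot-style shape), not the
  nominal ≈5–10%. The flags should be read as descriptive stability
  summaries, not calibrated tests; formal inference should rely on the
  per-holdout mixed-model standard errors or an external replication.
* Estimated-weight noise attenuates the holdout index slightly; recovered
  intra-subject correlations run a few hundredths below the generating
  value when weights are estimated rather than known.
* Only a random intercept is supported; AR(1)/unstructured residual
  covariances and non-Gaussian outcomes are out of scope, as are penalized
  (lasso-type) estimation variants.
* The weight estimator is a local optimizer on a non-convex objective;
  with heavily correlated components different near-optimal weight vectors
  can fit equally well — the ensemble average is the stabilizer, and
  selection counts should be inspected when subsets are small.
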