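# Methods

## Model and assumptions

Occupancy is modelled as independent Bernoulli trials per site with
`logit P(y=1 | x) = β₀ + β'x`. All candidate models are plain
maximum-likelihood binomial GLMs — no regularization, no spatial random
effects, no detection model. The multimodel layer assumes the candidate
set brackets the data-generating process well enough that Akaike
weights meaningfully apportion support; with p retained predictors the
set is every non-empty subset (2^p − 1 models, capped at p = 20).

AICc uses the standard small-sample form
`−2 log L + 2K + 2K(K+1)/(n − K − 1)` with K = intercept + slopes; it
is undefined (and raised as an error) when `n − K − 1 ≤ 0`. Weights,
ΔAICc and the ranking are always computed from unrounded AICc values —
printing at 2 decimals can make a displayed cumulative weight reach a
level one model earlier or later than the unrounded sequence does.

## Averaging choices

- **Scope.** Coefficients and predictions are averaged over the 95%
  confidence set (shortest AICc-ranked prefix with cumulative weight ≥
  the level), with weights renormalized inside the set. A level of 1.0
  averages over all candidates.
- **Zero-substitution** is the default: a predictor absent from a
  member model contributes θᵢ = 0 with SEᵢ = 0. This shrinks weakly
  supported effects toward zero and is what makes an averaged estimate
  of exactly ~0 possible for a predictor that appears only in
  low-weight models. `mode="natural"` instead averages each predictor
  over the models that contain it, with weights renormalized among
  them.
- **Unconditional SE** is `sqrt(Σ wᵢ [SEᵢ² + (θᵢ − θ̄)²])`, so it is
  never smaller than the weighted within-model floor
  `sqrt(Σ wᵢ SEᵢ²)`, with equality iff all member estimates agree.
- **Prediction mean vs variance scales.** The mean map is the
  inverse-logit of the composite (averaged-coefficient) linear
  predictor. The variance components are computed from the per-model
  *response-scale* predictions: within-model variance is the weighted
  mean of delta-method variances `var_link · [p(1−p)]²`, between-model
  variance is the weighted squared deviation of the per-model
  probabilities from their weighted mean. The composite-mean
  probability is not algebraically identical to the weighted mean of
  member probabilities (the inverse-logit is nonlinear); centering the
  interval on the composite mean while sizing it from the per-model
  spread is a deliberate, documented choice — the two agree closely
  whenever the member models agree, which is exactly when the interval
  is narrow.
- The 95% multiplier is the conventional 1.96, not an exact normal
  quantile; CI bounds are clipped to [0, 1]; the between/within
  variance ratio is NaN where the within-model component is zero.

## Screening

"Weaker" in collinearity screening means a smaller absolute
point-biserial correlation between predictor and the 0/1 response.
Elimination is greedy on the largest remaining |r| pair; the comparison
with the threshold is strict (|r| > 0.70 triggers, equality survives).
Ties in strength are broken by predictor name order and logged in the
report. Screening operates on site values, not whole-raster values:
the sites are the modelling data. If every predictor is mutually
correlated above the threshold the strongest single predictor survives,
with a warning.

## Evaluation

AUC is the Mann–Whitney statistic (probability that a random presence
outscores a random absence, ties half credit), which equals trapezoidal
integration of the ROC curve — the test suite asserts the equivalence
as a dual-route check. The operating threshold minimizes
|sensitivity − specificity| over all distinct scores plus midpoints of
adjacent scores, smaller threshold winning ties; classification is
inclusive (score ≥ threshold ⇒ presence), which also governs range
maps. Kappa is the standard unweighted Cohen formula on the 2×2 table.
On the published confusion matrix (TP=12, FP=8, FN=2, TN=80) that
formula gives ≈ 0.649, whereas the source analysis printed 0.62; the
settings behind that value are unrecoverable, so this package reports
the standard formula and does not attempt to match the printed number.

## Projection and area accounting

Suitable area is (count of valid cells at or above the threshold) ×
nominal cell area, with no geodesic correction — appropriate for
~1 km² equal-area cells. Percent change versus the baseline is
`(baseline − scenario)/baseline × 100`, reported to 2 decimals, and is
undefined (NaN, flagged) when the baseline area is zero. Nodata cells
propagate through every output field.

## Synthetic study world

The generator emulates the structure of the motivating survey, not its
geography:

- ~23→6 correlated climate-like layers are reduced to six retained
  predictors by default (`BIO1, BIO2, BIO3, BIO12, BIO13, BIO14`
  analogues), standardized over cells, on a 100×100 grid of 1 km²
  cells.
- Spatial autocorrelation: white noise smoothed with a Gaussian kernel
  (σ = 2 cells). The temperature analogue additionally carries a
  dominant north–south gradient (cold north), mirroring a peninsula's
  thermal axis.
- Cross-layer correlation: the raw fields are empirically whitened
  with an order-preserving (Cholesky) transform and mixed with the
  Cholesky factor of the target correlation matrix, so the cellwise
  sample correlations equal the target essentially exactly (singular
  targets, e.g. a pair at r = 1, fall back to the symmetric square
  root). Non-PSD targets are rejected with the offending eigenvalue.
- Occupancy truth: logistic, intercept −2.8, temperature slope −1.5,
  driest-precipitation slope +0.5, others 0 on the standardized scale —
  a dominant negative temperature effect and a minor positive dry-month
  precipitation effect at prevalence ≈ 0.14, the rare-species regime of
  the motivating data. 204 sites are drawn without replacement and
  split 102/102.
- Train/test separation: sites are ordered by (y, x, id) and assigned
  alternately, so near and co-located sites land in different halves;
  the seed only chooses which half leads. This damps spatial
  autocorrelation between calibration and evaluation data without
  claiming to reproduce any particular published procedure.
- Futures are additive per-predictor shifts (default: the temperature
  analogue rises by 1.0–2.8 standardized units across four scenarios);
  they emulate scenario deltas only — no circulation-model structure,
  no precipitation pattern change, no topography.

What passing tests therefore show: the estimator chain is correct and
calibrated *under the generator's assumptions* (logistic truth in the
candidate set, independent Bernoulli sampling, additive shifts). They
do not show robustness to detection error, spatially structured
residuals, niche truncation, or dispersal limitation — none of which
the model represents.

## Numerical choices

- GLM fitting: statsmodels IRLS, coefficient-change tolerance 1e-8,
  at most 50 iterations. (Quasi-)separation is detected by a diverging
  coefficient norm (> 1e3) or a diverging standard error (> 1e3 — the
  observed information degenerates before the coefficients do) and the
  model is flagged non-converged; flagged and unfittable subsets are
  recorded and excluded from the weights with a warning. A constant
  response is returned as a flagged degenerate fit. Likelihood
  evaluations clip probabilities by 1e-12.
- Weight normalization treats non-finite AICc values as zero weight;
  an all-non-finite set is an error.
- The confidence-set cut uses a 1e-12 slack on the cumulative weight so
  a prefix summing to the level within rounding noise is included.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a
minute: the study-shaped world is 100×100 cells with 204 sites; the
parameter-recovery check uses n = 2000 sites; CI coverage uses 200
replicates of n = 204 over three predictors (7 candidates each). These
are the package's reference conditions, not tuning knobs.

## Known limitations

- Wald/normal-approximation intervals on a probability: coverage is
  approximate, especially near 0 or 1 and at small n.
- The candidate set is main-effects-only; no interactions, polynomials
  or splines.
- Raster I/O is ESRI ASCII grid only; coordinates are abstract planar
  units with no CRS handling.
- A single train/test split, as in the motivating design — no
  cross-validation.
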