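# Methods

## Model and assumptions

Topological regression treats the weights of response-space
nearest-neighbor regression as the estimand.  For anchors I\* and a
molecule m, the log-weight vector W̃_{·,m} is modeled as linear in the
squared chemical distances from m to every anchor, with Gaussian noise:
multivariate N_K(0, Σ) across anchors in the TR\* construction, iid
N(0, σ²) in the stacked univariate construction.  Exponentiating a
predicted log-weight alone would bias E(W) low (Jensen), so predictions
use the log-normal mean exp(μ̂ + Σ̂_jj/2) (inverse-distance weighting)
or the log-normal Laplace transform E exp(−β d²_Y) (Gaussian-kernel
weighting).  The key structural assumptions are: (a) rows of W̃ are
mutually independent given the distances; (b) responses are absolutely
continuous, so exact response ties have probability zero (an additive
guard ε = 1e−6 on squared response distances covers data with recorded
ties); (c) the chemical distance enters only through the squared
1 − Tanimoto distance (a `distance_power=1` switch uses 1 − TC unsquared,
since either convention is defensible for a non-Euclidean distance).

Predictions are the *normalized* weighted mean Σ W Y\*/Σ W, computed as
a softmax over log-weights; they are therefore always inside the anchor
activity range and numerically stable even when all raw weights
underflow.  An unnormalized mode exists behind a flag.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `nbits`, `radius` | 1024, 2 | folded ECFP4 fingerprint size / Morgan radius |
| `distance_power` | 2 | power applied to 1−TC before entering the design |
| `anchor_fraction` (TR\*) | 0.20 | disjoint anchors as a fraction of training |
| `anchor_fraction` (TR) | 0.50, capped at 2000 anchors | anchors sampled from training |
| `eps` | 1e−6 | guard added to squared response distances before log |
| `mode` | `gaussian_kernel` | weighting scheme of the packaged TR method |
| β grid | 32 log-spaced points, [1e−2, 1e2]/median(d²_Y) | bandwidth search space |
| `MonteCarloConfig.R` | 10 000 (≥ 1000 enforced) | Laplace-transform replicates |
| ensemble `t, μ_k, σ_k², clip` | 15, 0.6, 0.2, [0.30, 0.90] | member count and anchor-fraction distribution |

Anchor sets are sampled uniformly without replacement (no scheme is
canonical; uniform is the least informative choice) and seeded.  Anchors
with exactly duplicated distance columns (identical fingerprints) are
deduplicated in `fit_tr`, keeping the first; the low-level
`fit_univariate`/`fit_multivariate` raise a singular-fit error naming
the collinear anchor columns instead, since silent repair there would
mask caller bugs.

## Numerical choices

* **Per-column least squares.**  The stacked system routes every
  equation to exactly one coefficient column (anchor pairs to the column
  of the larger anchor position, observed from the smaller), so the fit
  decomposes into K independent OLS problems sharing a pooled σ̂²
  (MLE, divide by row count).  At anchor fractions ≥ 50% some columns
  have fewer rows than K+1 coefficients; these are solved by
  minimum-norm least squares and interpolate.  This is the
  overparameterized regime the ensemble exists to average over, not an
  error.  Collinearity of the anchor columns themselves is detected once
  on the full stacked design.
* **Bandwidth selection.**  β̂ minimizes the leave-one-out squared error
  of the Gaussian-kernel weighted-mean predictor in the response space
  over the log-spaced grid (the standard GWR bandwidth criterion); exact
  ties break toward the smallest β (the smoother model).  Constant
  responses make the criterion flat: the grid minimum is returned with a
  warning.
* **Monte-Carlo Laplace estimator.**  Implemented verbatim as the mean
  of exp(−β̂ d²⁽ʳ⁾ e^{μ̂}) over d²⁽ʳ⁾ ~ lognormal(0, σ̂²) — equivalent
  to drawing from lognormal(μ̂, σ̂²) — with the average computed through
  log-sum-exp.  For β̂ e^{μ̂} > 50 plain averaging cannot resolve the
  integrand's tail, so a deterministic point-mass evaluation at the mode
  of the effective log-normal, exp(−β̂ e^{μ̂−σ̂²}), is substituted with a
  warning; an importance sampler for that regime is a known improvement
  left out of scope.  Within a prediction call one set of R draws is
  shared across the K anchors (weights remain exchangeable across
  anchors and rankings are exact, since E(W) is monotone in μ̂).
* **Intervals.**  Univariate prediction intervals are the classical
  analytic t-intervals with pooled σ̂² and per-column leverage.  TR\*
  intervals use a parametric bootstrap: coefficient replicates from the
  asymptotic normal of B̂ (vec-covariance Σ̂ ⊗ (XᵀX)⁻¹) plus residual
  noise from N(0, Σ̂), pushed through exp, with empirical quantiles.
* **Graphs.**  Neighbor graphs are undirected and deduplicated; edge
  (i, j) requires j among i's top-k neighbors *and* similarity ≥ the
  mean off-diagonal similarity of the dataset (the diagonal is
  excluded from the mean).  The spanning tree uses Kruskal on 1 −
  similarity with ties broken by the lexicographic node pair, making the
  lead path deterministic; tie-broken activity extremes resolve to the
  lowest node id.
* **NRMSE** is normalized by the population standard deviation of the
  true responses (range and mean normalizations are available via the
  `norm` argument); comparability with results computed under a different
  normalizer is not claimed.
* **Anchor-count selection** compares AIC = 2p − 2logL and
  BIC = p log(n) − 2logL across nested anchor sets (first K of a master
  permutation), with p = K(K+1) + 1 and the iid-Gaussian stacked
  likelihood.  Because the stacked row set itself changes with K, the
  criteria are a pragmatic ranking device, not a likelihood-ratio
  ladder; a true "informative anchor count" exists only when the
  generative dependence is restricted to known columns, which is how the
  recovery test is constructed.

## What the synthetic generators do and do not emulate

`simulate_tr_data` draws squared distances from a squared Beta(2, 2)
(bell-shaped on [0, 1], mimicking squared Tanimoto distances), anchor
activities uniform on a pChEMBL-like range [4, 10], default noise
σ = 0.5, and builds responses through the model's own normalized
weighted mean — it is deliberately *correctly specified*, so coverage
and recovery tests measure the estimator, not model misfit.

`simulate_landscape` produces 5 clusters × 40 molecules of 512-bit
fingerprints: cluster templates at 12% bit density, members bit-flipped
at rate 1% (within-cluster Tanimoto ≈ 0.7+, matching realistic congeneric
series), cluster activity means spread over [4.5, 9.0] with σ = 0.2
noise, and 4 cliff molecules per cluster offset by Δ = 3 activity
units.  It captures cluster structure and cliffs but not real ChEMBL
activity distributions, assay noise heterogeneity, scaffold hierarchies
or fingerprint sparsity patterns — so passing tests demonstrate the
mechanism, not benchmark performance on real assay data.  Fingerprints
are injected directly (no SMILES), which keeps the full TR stack
testable without chemistry; the `chemio` path is exercised separately on
real SMILES.

Desk-scale study sizes used by the simulation studies: N=500, K=10 with
50 replicates for interval coverage; N=2000/8000, K=5 with 10 replicates
for recovery scaling; 20 landscape seeds for the graph comparison.

## Design choices where the design was open

* Duplicate SMILES collapse keeps the first occurrence (the cleaning
  rule specifies removal, not survivorship).
* Empty∩empty fingerprints count as identical (similarity 1): two
  featureless molecules are indistinguishable, and it avoids 0/0.
* B is stored (K+1)×K — one intercept row plus K slope rows per anchor
  column.
* Scaffold splits assign whole scaffold groups greedily, largest first,
  to the training side until only the test budget remains; the seed
  shuffles equal-size groups.
* Ensemble members average final response predictions, not weight
  vectors (members have different anchor sets, so weight-space averaging
  is undefined); fractions outside the clip range are clipped, not
  resampled.
* TR graph neighbors are the k anchors with the largest predicted
  weights, ranked by the fitted mean structure (exact, sampling-free).

## Known limitations

* No importance sampler for the large-β̂ Laplace-transform regime; the
  point-mass fallback is crude there.
* Only ECFP4/Tanimoto featurization is built in (arbitrary precomputed
  distance matrices are accepted).
* AIC/BIC anchor selection compares likelihoods across differently-sized
  stacked systems (see above).
* The scaffold splitter targets the test fraction only as closely as
  whole-scaffold assignment allows.
* MDS output is for visualization only and is never used in prediction.
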