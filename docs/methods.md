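# Methods

## Data model

The unit of analysis is an areal cell: region (or survey cluster) *i* and
survey period *t*.  Weighted deaths `Y_it` and weighted births at risk
`n_it` are obtained by summing `weight × death` and `weight` over the
birth records in the cell; DHS-style sampling weights are applied in
tabulation, before any modelling.  Weighted counts are therefore
real-valued; the Poisson log-likelihood is evaluated through the
log-gamma function so non-integer counts are admissible (an optional
rounding switch exists but is off by default, since tabulated weighted
counts are the natural quantity).

Expected counts use internal standardization over the whole panel,
`E_it = n_it · (Σ Y / Σ n)`, which forces `Σ E = Σ Y` (checked to 1e-9
relative tolerance); per-period standardization is available as a config
option, in which case conservation holds period by period.  `SMR_it =
Y_it / E_it`; cells with `E = 0` and `Y = 0` are flagged undefined, and
`E = 0` with `Y > 0` is an error.

Covariates aggregate per declared rule: weighted sum for counts, weighted
proportion for indicators, weighted median for "median"-style summaries.
Before model fitting the drivers standardize covariates to zero mean and
unit variance, so reported coefficients are per SD of the areal covariate.
An iterative VIF screen (drop the worst column while its VIF exceeds 10,
constants dropped first) guards against collinear covariate sets.

## Spatial structure

Region-level adjacency is queen contiguity from polygons (shared boundary
point suffices).  Cluster-level (point) adjacency is a distance band whose
threshold is the maximum nearest-neighbour distance, so every point has at
least one neighbour; distances are great-circle (haversine) when the layer
declares lon/lat and Euclidean otherwise — the metric choice is ours, as
is the queen rule, since contiguity conventions vary.  Weights are binary
or row-standardized; Moran/LISA default to row-standardized, matching
standard practice for autocorrelation tests.

## Autocorrelation inference

Global Moran's I = (n/S0)·Σ w_ij z_i z_j / Σ z_i² on the natural log of
the relative-risk surface (the SMR by default); zero SMRs are excluded
from the test with a logged count (a continuity-constant policy is
configurable).  Significance is by random permutation of values over
units, `p = (1 + #{I* ≥ I}) / (B + 1)`, one-sided "greater" by default to
match the hot-spot framing; two-sided and "less" alternatives are
available.  Local Moran uses the m2 = Σz²/n normalization so that
mean(local I) equals the global I exactly under row-standardized weights,
and conditional permutation (unit i held fixed, the rest shuffled over the
other locations).  Each unit's pseudo p is one-sided in the direction of
its observed statistic; classification is per-unit at α = 0.05 with no
multiplicity correction by default (a Benjamini–Hochberg option exists),
since published LISA cluster maps are conventionally uncorrected.

## Hierarchical models

Spatial (single-period) model: `ψ_i = α + x_i'β + μ_i + υ_i`;
spatiotemporal: `ψ_it = α + x_it'β + μ_i + υ_i + γ_t + φ_t`, with

- μ: intrinsic CAR over the adjacency graph — kernel
  `(n−G)/2·log τ_μ − τ_μ/2 Σ_{i~j}(μ_i − μ_j)²`, G the number of
  connected components; identified by sum-to-zero recentring;
- υ, φ: iid N(0, τ⁻¹) heterogeneity;
- γ: first-order random walk, `(T−1)/2·log τ_γ − τ_γ/2 Σ(γ_t − γ_{t−1})²`,
  sum-to-zero;
- α ~ N(0, τ₀⁻¹) with τ₀ = 0.001; β_j ~ N(0, 1000).

Precision hyperpriors follow the logGamma-on-log-precision convention,
i.e. Gamma(shape, rate) on the precision itself: τ_μ, τ_υ ~ Gamma(1, 5e-5);
τ_γ ~ Gamma(1, 1e-3); τ_φ ~ Gamma(1, 5e-4).  Every rate is explicit in
`ModelSpec`, so any alternative reading of these conventionally terse
prior specifications is a one-line change.  ICAR propriety is handled by
recentring rather than a ridge, keeping the intrinsic model exact and the
conjugate τ_μ update at rank n − G.

### Sampler

Inference is a self-contained Metropolis-within-Gibbs sampler.

- α and each β_j: adaptive random-walk Metropolis.
- μ: single-site adaptive Metropolis, vectorized over a greedy coloring of
  the adjacency graph (no two units updated simultaneously are
  neighbours, so the blocked accept/reject is a valid kernel).  γ uses the
  parity (odd/even t) coloring of the RW1 chain; υ and φ update all sites
  at once (iid priors, row/column-separable likelihood).
- Precisions: exact conjugate Gamma draws (τ_υ shape a + n/2, τ_μ shape
  c + (n−G)/2, τ_γ shape + (T−1)/2, τ_φ shape + T/2).
- Proposal scales adapt toward 0.44 acceptance during burn-in only
  (Robbins–Monro with diminishing step), so the post-burn-in kernel is
  fixed.

Three additional exact moves address the slow directions single-site
updates cannot traverse:

1. **Scaling moves** (non-centred precision updates): propose
   `(f, τ) → (f·e^{ε/2}, τ·e^{−ε})` per random-effect block.  The Gaussian
   kernel exponent is invariant, so the acceptance ratio is the likelihood
   change times the Gamma hyperprior ratio times e^{−ε}.  This traverses
   the funnel between a field and its precision, which conjugate draws
   alone mix extremely slowly (the field collapses, the precision
   explodes, and the pair gets stuck).
2. **Split interweaving**: the likelihood identifies only μ + υ (and
   γ + φ); the shift c in (μ+c, υ−c) has an exact Gaussian full
   conditional with precision τ_μL + τ_υI (L the graph Laplacian) and is
   Gibbs-drawn each sweep; likewise (γ+c, φ−c) with the RW1 structure
   matrix.  ψ is untouched, so no likelihood evaluation is needed.
3. **Level exchange**: the flat direction between the intercept and each
   iid block, (α, υ) → (α+c, υ−c), is Gibbs-drawn from its normal full
   conditional.  Without it the intercept's credible intervals understate
   the genuine non-identifiability between α and the realized means of
   the iid fields.

After these moves μ and γ are recentred to sum to zero, the subtracted
means absorbed into α.  With a translation-invariant field prior this
recentring is a pure reparameterization up to the intercept prior factor,
i.e. exact in the vague-τ₀ limit in which the model operates — the
standard treatment for intrinsic CAR fields.  Sampler correctness is
checked by a Geweke-style comparison of the marginal-conditional and
successive-conditional simulators (run with proper moderate priors and
small exposures so every marginal has testable moments and the chain can
traverse the prior).

Defaults are 2 chains × 20,000 iterations (10,000 burn-in, thinning 5)
with split-R̂ and bulk ESS reported via ArviZ; a `McmcConfig.smoke()`
preset (1 chain, 3,000/1,200/2) is used for simulation studies and smoke
runs.  An effective-sample-size floor can be configured; falling below it
warns in the fit metadata rather than failing the fit.

### Outputs

`ModelFit` reports posterior means with central 95% credible intervals;
smoothed relative risks are posterior means of `exp(ψ_it)` with interval
bounds from the same draws.  Variance components are summarized as draws
of 1/τ, on the variance scale by default or on the natural-log scale as
an option — both conventions appear in published tables and the raw draws
are retained either way.  The pointwise log-likelihood matrix over
retained draws feeds model evaluation; cells with E = 0 and Y = 0
contribute zero log-likelihood and are excluded from the CPO set.

## Model comparison

DIC uses the plug-in deviance at the posterior mean of the latent linear
predictor ψ (the natural focus for disease-mapping models, and computable
from stored draws).  WAIC uses the log-sum-exp lppd and the summed
posterior variance penalty.  CPO is the harmonic-mean estimator computed
through log-sum-exp of negated log-likelihoods, with a stability flag when
a single draw carries more than half of the harmonic-mean weight and
exclusion (with warning) of numerically zero CPOs; LPML = Σ log CPO, and
model ranking is by largest LPML with smaller DIC breaking ties.  PSIS
smoothing and refit-based cross-validation are out of scope.

## Synthetic data

The generator draws geography (contiguous grid polygons with queen
adjacency, or uniform points with distance-band adjacency, regenerated
with an incremented seed if disconnected), then latent effects from the
model's own priors — μ from the intrinsic CAR restricted to the sum-zero
subspace (eigendecomposition of the graph Laplacian), γ as a centred
random-walk path (centring leaves the increment variance 1/τ_γ intact),
υ and φ iid — then `Y_it ~ Poisson(E_it e^{ψ_it})` with design exposures
jittered ±30% around a configured mean, and finally individual birth
records whose aggregation reconstructs the panel, with log-normal
sampling weights of mean 1.

Default emulation scale is 30 units × 5 periods with mean exposure 100 —
larger than a national region layout so parameter-recovery studies are
stable.  The `gdhs_scale` preset is 10 regions × 5 periods with mean
exposure 15, matching the magnitude of a national DHS round (a few
thousand births, on the order of a hundred neonatal deaths per round).
Default covariate generators produce one count (Poisson), one proportion
(Beta) and one median-style continuous (Normal) areal covariate, echoing
the covariate classes such analyses aggregate.  The baseline mortality
rate defaults to 33 per 1000 live births.

What the generator does **not** emulate: real Ghanaian geography,
two-stage cluster sampling beyond the weight distribution, stratification,
non-response, or recall error in birth histories.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to survey-design misspecification.

## Numerical choices and degenerate inputs

- Row-standardized weight rows of isolated units are all zero (warned);
  isolated units are flagged NS in LISA and rejected by the CAR models
  (error naming the unit).
- Permutation pseudo p-values are bounded below by 1/(B+1); ties between
  a permuted and the observed statistic count as "as extreme", with the
  observed local Moran evaluated through the same subset-dot expression
  as the permuted values so exact ties do not resolve on float noise.
- Duplicate point coordinates are forced adjacent with a warning.
- Choropleth bins are pooled quantiles across all periods (one fixed
  scale per surface), ties assigned to the lower bin.
- Master seed → per-stage seeds by SHA-256 of "seed:stage-name", kept
  below 2³¹; all generators accept explicit seeds and are bitwise
  reproducible.

## Problem sizes in the shipped studies

The analysis drivers and the acceptance script run the 10 × 5 GDHS-scale
preset end to end; recovery studies use 30 units × 5 periods with 30–50
replicates at smoke MCMC settings, chosen to give stable coverage
estimates at a few minutes of single-CPU runtime.  Permutation-test
calibration uses 1000 i.i.d. replicates on a fixed 30-unit graph with 199
permutations each.

## Known limitations

- The sampler is exact up to the recentring treatment of the intrinsic
  fields (vague-intercept-prior limit); with a deliberately informative
  intercept prior the reported intercept would mix the constrained and
  unconstrained parameterizations.
- Harmonic-mean CPO is noisy for influential observations; the stability
  flag reports, but does not repair, such points.
- Weighted counts enter the Poisson likelihood as-is; design-based
  variance inflation (effective sample size corrections) is not applied.
- Space–time interaction terms beyond the additive decomposition, Leroux
  priors, and continuous-surface (SPDE-style) geostatistics are out of
  scope.
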