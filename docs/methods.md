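# Methods

## Model

The package models a binary land-management choice through a latent
spatial autoregressive (SAR) process,

    y* = ρ W y* + Xβ + ε,   ε ~ N(0, σ²I_n),   y_i = 1(y*_i > 0),

with σ² fixed at 1 throughout: a binary outcome carries no scale
information, so the error variance is not identified and the usual
probit normalization applies.  ρ captures spatial autocorrelation in
the choice — both genuine neighbour influence and unobserved spatially
structured conditions — and is given a uniform prior on (0, 1)
(configurable); β has independent N(0, 1) priors by default.

## Spatial weights

Parcel longitude/latitude are projected to planar kilometres by an
equirectangular projection about the centroid latitude
(R = 6371.0088 km).  For study regions of a few degrees the distortion
is far below anything that could alter neighbour topology; a guard
rejects extents above 10° unless overridden.  The points are Delaunay
triangulated (scipy/Qhull); owners sharing a triangle edge are
neighbours; W is row-standardized to w_ij = 1/|N(i)|.  Coincident
points receive a deterministic 1e-6 km jitter (fixed internal seed) so
the triangulation is well defined; fully collinear inputs raise an
error rather than silently dropping points.  Models fit on the
residential subsample re-triangulate on that subsample's points: W
must be n×n for the estimation sample, and a sub-matrix of the full-W
would neither be row-standardized nor a triangulation.

## MCMC

Sampling cycles three exact conditional blocks, all driven by one
seeded `numpy` Generator:

* **Latent utilities.**  Given (β, ρ) the latent vector is
  N(μ, H⁻¹) with H = (I−ρW)'(I−ρW) and Hμ = (I−ρW)'Xβ.  One
  single-site Gibbs sweep per iteration updates each y*_i in index
  order from its univariate truncated-normal conditional
  N((b_i − Σ_{j≠i} H_ij y*_j)/H_ii, 1/H_ii), truncated to (0,∞) if
  y_i = 1 and (−∞,0] otherwise.  The sweep is a compiled (numba)
  kernel; truncated normals use naive rejection in the bulk and the
  Robert (1995) translated-exponential rejection sampler in the tail.
  H's three sparsity components (I, W+W', W'W) are aligned on one CSR
  pattern at setup, so updating H for a new ρ is a vector operation.

* **Coefficients.**  (I−ρW)y* = Xβ + ε is a linear model with known
  unit variance, so β | y*, ρ ~ N(b̄, B̄) with
  B̄ = (X'X + T⁻¹)⁻¹ and b̄ = B̄(X'(I−ρW)y* + T⁻¹m); B̄ and its
  Cholesky factor are precomputed once per run.

* **Spatial dependence.**  ρ is drawn by griddy Gibbs: the conditional
  log-kernel log|I−ρW| − ½‖(I−ρW)y* − Xβ‖² is evaluated on a fixed
  grid (default step 0.001 on the prior support, endpoints excluded),
  exponentiated after subtracting its maximum, integrated by the
  trapezoid rule, and sampled by inverse-CDF with linear interpolation
  within grid cells.  The log-determinants come from the eigenvalues
  of W, computed once per weight matrix (n here is a few hundred; the
  quadratic form reduces to a − 2ρb + ρ²c with three scalars per
  iteration).  Griddy Gibbs was preferred over Metropolis–Hastings
  because it needs no tuning and is deterministic given the seed.

Defaults are 20,000 iterations with a 5,000-iteration burn-in.
Initialization: β at the probit MLE (zeros if that fit fails), ρ at
the support midpoint, y* at ±0.5 by outcome — this shortens burn-in
without affecting the stationary distribution.  A divergence guard
aborts if the latent vector leaves ±1e8 or turns non-finite.

Posterior "p-values" are reported as the two-sided normal tail at
|posterior mean|/posterior SD.  This is a summary convention, not a
frequentist test — it is the only construction that can attach a
p-value to ρ, whose prior excludes 0 — and the posterior sign
probability is reported alongside.

`convergence_check` compares repeated runs: a parameter passes when
the spread of posterior means is within 5% of the parameter's scale
(the larger of |mean| and the posterior SD, so near-zero coefficients
are judged on the posterior scale) or within 0.5 combined Monte-Carlo
SEs (ESS-adjusted via arviz); posterior variances must agree within
10%.  Variances get the looser band because variance estimates are
considerably noisier than means at equal chain length.

## Effects decomposition

The impact matrix of covariate r is S_r = diag(φ(η)) (I−ρW)⁻¹ β_r with
η = (I−ρW)⁻¹Xβ: average direct = n⁻¹ tr(S_r), average total = grand
row mean, indirect = total − direct (additive by construction).  By
default η is left unscaled; the option `normalize_variance=True`
divides the index by the reduced-form standard deviations
σ_i = √[(A⁻¹A⁻ᵀ)_ii] (and scales the density accordingly), the
variant used by parts of the spatial-probit literature.  Effects are
evaluated at the posterior means by default (deterministic given the
draws); `mode="draws"` averages the decomposition over evenly thinned
retained draws instead.  As ρ → 0 the decomposition converges to the
*average* pdf-scaled probit effect n⁻¹Σφ(x_i'β)β_r; the standard
probit effects table instead reports the conventional at-means effect
φ(x̄'β)β_r — the two differ by Jensen's inequality, which matters when
comparing columns across model types.

For the ordinary probit, dummy covariates also use the pdf-scaled
derivative by default (the discrete-change Φ(·|x_r=1) − Φ(·|x_r=0) is
available by flag); classification uses a fixed 0.5 threshold with
ties classified as unwilling.

## Synthetic data

The generator reproduces the survey conditions the package is designed
around: n = 242 owners over a 200×150 km region (uniform by default,
Gaussian blobs optionally, matching the ~3–60 km Delaunay neighbour
distances such a density produces); binary covariates Bernoulli at the
observed sample frequencies (sawlog objective 0.14, past harvest 0.45,
age>55 0.75, male 0.82, …), with the two income indicators drawn from
a single categorical so they are never both set; road distances normal
truncated at zero at the observed means/SDs (service centre
100.9 ± 41.6 mi, national-forest boundary 13.9 ± 15.3 mi, sawmill
access 8.63 ± 4.98 mi — note truncation raises the realized sawmill
mean to ≈9.1); county sawtimber volume standardized N(0, 1); absentee
status Bernoulli(0.25) independent of the rest.  Outcomes come from
the latent SAR process at ρ = 0.167 and the published spatial-probit
coefficients.  Two generating parameters are not published and were
fixed once by design: the market-access-squared coefficient (0.004,
placing the turning point of the quadratic access effect near the mean
sawmill distance) and the intercept (−0.55, calibrated by a one-off
large-n simulation so the generated WTH base rate matches the observed
0.29; single n = 242 draws range over ≈0.24–0.37 across seeds).

What the generator does **not** emulate: correlation between distance
covariates (the survey reports only marginal moments; an independence
assumption is used), covariate dependence of absentee status,
county-level clustering of parcels (off by default), geocoding error,
and road-network rather than planar distances.  Passing tests
therefore demonstrate correctness of the estimation machinery under
the assumed data-generating process, not robustness to the messiness
of real survey data.

## Verification strategy and problem sizes

Every computational claim is checked against an independent route:
probit MLE against exhaustive 2-D grid search; the impact matrix
against finite differences of the reduced-form choice probability;
Delaunay output against a brute-force empty-circumcircle scan;
log-determinants against closed forms; the conjugate β step against
least squares; the griddy ρ step against the uniform distribution under
a flattened kernel; and the full sampler against (i) the probit MLE
with ρ fixed at 0 and (ii) seeded recovery experiments (20 replicates
at n = 500, ρ = 0.4, 5,000 draws/1,000 burn-in: coverage of the 95%
interval ≥ 90% and |bias(ρ̂)| < 0.05).  These sizes keep the full
suite within about two minutes while leaving Monte-Carlo error well
below the tolerances tested.

One subtlety: with ρ fixed at 0 the posterior mean of β equals the
probit MLE only up to a finite-sample term.  Under the informative
N(0, 1) prior, or under strongly imbalanced covariates with large
coefficients, that term (shrinkage and likelihood skewness,
~0.02–0.05 here) dwarfs Monte-Carlo error — verified by running an
independent ensemble sampler (emcee) on the identical posterior, which
reproduces the Gibbs means, not the MLE.  The reduction test therefore
uses a diffuse prior and a balanced moderate-effect design, where the
long-chain gap is ≈0.001 and agreement at 3 Monte-Carlo SEs is the
right criterion.

## Known limitations

* Dense eigenvalue log-determinants and dense (I−ρW)⁻¹ in the effects
  limit the practical n to a few thousand — ample for owner surveys of
  this kind.
* Single-site Gibbs mixes slowly for strongly collinear covariate
  pairs (e.g. a distance and its square on small samples); posterior
  means remain correct but need longer chains.
* No spatial-error or SAC specifications, no heteroskedastic probit,
  no marginal-likelihood machinery; k-nearest-neighbour and
  distance-band weights are deliberately out of scope.
* A single n ≈ 242 dataset identifies ρ only loosely (posterior SD
  ≈ 0.1); replication-style comparisons of ρ̂ against its generating
  value are made in posterior-SD units, not as point equality.
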