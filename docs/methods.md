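# Methods

## The model

`arealrisk` maps disease risk over a set of areas (counties, districts,
lattice cells) joined by a contiguity graph.  Observed case counts follow

    Y_i ~ Poisson(E_i * theta_i),        log(theta_i) = b0 + x_i' beta + b_i,

where `E_i` is the expected count under internal standardization
(`E_i = pop_i * sum(Y)/sum(pop)`, so `sum(E) = sum(Y)` exactly and
`theta_i` is a relative risk against the study-wide rate), `x_i` are area
covariates on their raw scale (an RR of `exp(beta_j)` per raw unit), and
`b_i` is a spatial random effect.  Four random-effect structures are
compared: none (plain GLM), IID Gaussian, intrinsic CAR, and the BYM
convolution in its scaled (BYM2) form

    b = sigma * ( sqrt(phi) * u + sqrt(1 - phi) * v ),

with `u` an intrinsic CAR field rescaled so the geometric mean of its
constrained marginal variances is one, `v` standard normal, `sigma` the
marginal SD of the combined effect and `phi in [0,1]` the structured
fraction of its variance.  The variance scaling is what makes `sigma` and
`phi` interpretable and comparable across graphs.  A negative-binomial
likelihood (size parameterization, `Var = mu + mu^2/theta_nb`) is available
for overdispersion comparisons.

The ICAR field is improper: its precision `Q = D - A` has one null vector
per connected component.  We impose one sum-to-zero constraint per
component; isolated areas (graph components of size one) carry no
structured effect at all and are flagged.  Working in the eigenbasis of the
scaled precision turns all of this into bookkeeping: null eigenvectors are
the per-component constants, so dropping (ICAR) or down-weighting (BYM)
those modes implements the constraints exactly.

## Inference

Fitting follows the nested-Laplace recipe for latent Gaussian models:

1. For a candidate hyperparameter vector `theta` (log sigma, logit phi, and
   log NB size when applicable) the latent field — intercept, slopes and
   spatial modes — is maximized by Newton iterations with step halving
   (gradient max-norm < 1e-6 at convergence).
2. A Gaussian approximation at the mode yields the Laplace evidence:
   likelihood x latent prior / Gaussian density at the mode, times the
   hyperprior.
3. The evidence is evaluated on a regular grid centered at the numerically
   located hyperparameter mode, spanning +/-3 approximate posterior SDs per
   dimension (finite-difference Hessian; default 9 grid points per
   dimension, 7 for the NB dimension).  Grid weights are normalized
   evidence values; they sum to one and peak in the grid interior.
4. Latent marginals are weight-mixed Gaussians over the grid.  Means, SDs
   and quantiles (bisection on the mixture CDF) are reported; fixed-effect
   RRs are exponentiated quantiles.  The `kld` column gives the
   Kullback-Leibler divergence of each fixed-effect mixture from a single
   moment-matched Gaussian — a diagnostic for how far the posterior is from
   Gaussian (values near zero mean the simple summary is safe).

This is the plain Gaussian flavor of the Laplace family: no skewness
correction is applied to the latent marginals.  At the count sizes typical
of area data (hundreds to tens of thousands of cases per area) the Gaussian
approximation is excellent, as the GLM-limit and calibration checks in the
test suite verify.

DIC and WAIC come from posterior draws (default 1000): a grid point is
sampled by weight, then the latent field from its Gaussian conditional;
both criteria carry Monte-Carlo standard errors.  Posterior fitted-count
draws feed grouped count aggregation (e.g. state totals with 95%
intervals); group means are additive by construction because sums are taken
per draw.

## Priors

* Marginal SD: penalized-complexity (exponential) prior with
  `P(sigma > 1) = 0.01` — the base model is "no random effect", and one
  unit of log-risk SD is already a very strong spatial signal.
* Mixing fraction: the exact PC prior for `phi` is graph-dependent; we use
  a one-parameter `Beta(a, 1)` prior with `a` solved from the stated tail
  mass `P(phi < 0.5) = 2/3`, favoring unstructured variance a priori.
* Fixed effects: Gaussian, precision 0.001 (intercept 1e-6).  Setting both
  to 1e-6 gives the flat-prior limit that reproduces maximum likelihood.
* NB size: lognormal, `log(theta_nb) ~ N(0, 3^2)` — weakly informative.

All are configurable through `PcPriors` / `ModelSpec`.

## Covariate screening

The funnel mirrors standard county-study practice: (1) pairwise Pearson
filter at |r| > 0.6, dropping the member of each offending pair with the
larger mean absolute correlation against the rest (ties: later column);
(2) stepwise-forward selection under BIC with a Poisson GLM and the
log-expected-count offset, stopping at the first non-improving step;
(3) iterative VIF filter at VIF > 10 (perfect collinearity leaves first);
(4) a negative-binomial scan of all pairwise products among the survivors
with Benjamini-Hochberg adjustment at 0.05.  Missing covariate cells are
completed beforehand by chained-equation sweeps (10 by default, random
forest or linear regressors, seeded); a single completed dataset feeds the
model rather than pooled multiple imputations, since the completed table is
model input, not an inferential target.

## Cluster statistics

Global Moran's I uses row-standardized weights and a full-relabeling
permutation test, two-sided around the analytic expectation `-1/(n-1)`.
Local Moran (LISA) uses conditional permutation — the area's own value held
fixed, neighbors redrawn without replacement from the remaining `n-1`
values — with 999 permutations by default.  The reported pseudo p is the
observed-tail probability **doubled** (capped at 1): the tail is chosen
after seeing the statistic, and without the fold the realized type-I rate
under exchangeable nulls is about twice the nominal level (we measured
~10% at alpha = 0.05; folded, it is ~5% and the suite requires <= 7%).
Quadrant labels HH/LL/LH/HL come from the signs of the standardized value
and its spatial lag (values exactly at the mean count as Low) and are only
assigned where significant, optionally after BH adjustment across areas.
Getis-Ord Gi* uses self-included binary weights and the standard z-score;
labels at |z| = 1.96 and 2.58.  In the pipeline, LISA is applied to
posterior-mean RRs and Gi* to Pearson residuals.

## Risk tiers

Posterior-mean RRs are expressed in SD units from a center — the reference
risk RR = 1 by default (`sample_mean` optional) — with the sample SD of the
RR vector as scale.  Bands are cut at +/-0.5, 1.5, 2.5 SD (left-closed,
right-open upward); tiers use the strict upper rule: above 1.5 SD tier 1
(intensive programs), 0.5–1.5 tier 2 (outreach), -0.5–0.5 tier 3 (regular
surveillance), at or below -0.5 below-reference.  The two conventions
disagree only on the measure-zero cut points themselves; band labels there
follow the left-closed rule, tiers the strict rule.

## The synthetic generator

`synthetic_data` draws lattices whose data-generating process is exactly
the model above: scaled-ICAR structured field (sampled exactly via the
precision eigendecomposition), IID noise, Gaussian covariates with
controllable mutual correlation (shared-factor construction, exact when all
covariates request the same pairwise r) and controllable correlation with
the structured field (what makes the spatial-confounding diagnostic
testable), uniform populations, counts Poisson around `E * exp(eta)`, and
MCAR masking of covariate cells (one cell in each of `round(f * n)` rows;
the default 1.62% mirrors a typical county-survey gap).

Defaults imitate the shape of US county data: seven percent/index-scale
covariates with realistic means and spreads, populations 5k–200k, a
baseline rate of 0.1 cases per person at risk, `sigma = 0.5`,
`phi = 0.57`.  What the generator does **not** emulate: survey design
effects, spatially varying populations, age structure, raster-derived
exposures, real county geometries, or missingness that is informative.
Passing tests therefore certify the statistical machinery under its own
assumptions, not robustness to the messiness of real surveillance data.

## Numerical choices and problem sizes

* Eigen-decomposition of the scaled ICAR precision once per graph; all
  variants and constraints live in that basis.  Dense linear algebra
  throughout — designed for hundreds to a few thousand areas.
* Hyperparameter search: Nelder-Mead on the Laplace evidence
  (xatol 0.02), warm-started Newton inner loops, theta clamped to
  generous bounds (log sigma in [-10, 5], logit phi in [-12, 12]) so the
  search cannot escape to degenerate corners.
* Mixture quantiles by 70-step bisection; KLD by 1001-point quadrature
  over +/-8 SD.
* Validation experiments run on 12x12 to 20x20 lattices with 10–50
  replicates and 4- or 5-point grids per hyperparameter dimension; these
  sizes give comfortable statistical margins for every threshold while
  keeping the whole suite quick on one CPU.  The thresholds themselves
  (bias < 0.02, coverage in [0.90, 0.99], win fractions >= 90%, type-I
  <= 7%, oracle agreement 0.02 / 1e-10 / 1e-8) are fixed properties being
  verified, not tunables.

## Known limitations

* Pearson residuals of a smoothed spatial fit are mildly *negatively*
  autocorrelated by construction (shrinkage borrows from neighbors, so the
  residual at an area moves opposite to its neighborhood), and the effect
  grows with the information in the counts.  The residual Moran test in the
  report should therefore be read as "no **positive** residual structure
  left", not as an exact uniform-p null check.

* No skewness-corrected (full simplified-Laplace) latent marginals; the
  `kld` column is the guardrail.
* The unstructured-field posterior SD uses a conservative decomposition
  (`var(v) = var(b) - var(u)` floored at zero) rather than tracking the
  full structured/unstructured posterior covariance.
* Proper-CAR (fixed rho) is available but not part of the default
  comparison; rho is never estimated.
* No spatiotemporal extension, zero-inflated likelihoods, distance-band or
  k-nearest-neighbor weights, or scan statistics.
* Internal standardization is the only expected-count scheme; external or
  age-standardized references must be supplied via the `E` column.
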