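# Methods

## Model

Conditional on a moderator, (X, Y) is bivariate normal with
moderator-dependent moments connected through three link functions: a log
link for each standard deviation and the Fisher link
log((1+ρ)/(1−ρ)) = 2 atanh(ρ) for the correlation.  The links guarantee
σ > 0 and |ρ| < 1 for any real coefficients, so the likelihood is
unconstrained in coefficient space.  The design is intercept + indicator
columns for a categorical moderator and intercept + z for a continuous
one; extra columns (e.g. polynomial terms in z) are accepted by the
design-matrix contract but are not exercised by the shipped tests.

Means are modelled with the same design as the variance submodels.  The
likelihood requires means, and per-group (or linear-in-z) means keep the
categorical moment solution exact; in every shipped simulation the
population means are 0, so the mean submodel costs only degrees of
freedom.  All moment estimators use the ML convention (divisor n), which
makes the moment and ML solutions of the saturated model coincide exactly
and turns several identities into machine-precision invariants rather
than approximations.

The scientific quantity is θ = δ_y − δ_x (slope coefficients of the two
log-SD submodels, or indicator contrasts in the categorical case):
θ = ½·log of the variance-ratio ratio between two moderator states, and
exp(θ) equals the ratio of slope ratios to correlation ratios.  θ = 0 is
the equal-variance-ratio (EVR) condition under which moderation of slopes
and of correlations are the same hypothesis.

## Estimation

**Categorical, saturated.**  Closed form: per-group sample moments.  The
coefficient covariance is assembled analytically from the per-group
5×5 inverse information of (μ_x, μ_y, log σ_x, log σ_y, fisher(ρ)); for
the saturated bivariate normal the observed and expected information
coincide at the MLE (the Hessian depends on the data only through moments
the MLE matches), and the test suite verifies the assembled covariance
against a finite-difference observed-information computation on the
row-level likelihood.  Two useful consequences, both exact:
var(θ̂) per group pair is (1−r²_1)/n_1 + (1−r²_i)/n_i, and the variance of
a fitted Fisher-link coefficient is 4/n (the classical var(atanh r) = 1/n
with divisor n rather than n−3).

**Categorical, constrained.**  `HOV_X`, `HOV_Y`, `EVR` and `EQUAL_RHO`
are linear equality constraints on the per-group vector
(log σ_x, log σ_y, fisher ρ); they are imposed by a linear
reparameterization T and the profile objective is maximized by L-BFGS-B
with the analytic score, starting from the least-squares projection of
the saturated solution, with one jittered restart on failure
(convergence: |∇ℓ|∞ ≤ 1e−5 after L-BFGS-B's own ftol 1e−15 / gtol 1e−10).
`EQUAL_SLOPE` is nonlinear in this parameterization and is fitted by
reparameterizing ρ_i = β σ_x,i / σ_y,i with a shared β (clamped to
|ρ| ≤ 1 − 1e−10), so that every model in a comparison ladder shares one
likelihood and the LR χ² differences are internally nested.  Means drop
out at their sample values in all of these fits because they are never
constrained.

The Monte-Carlo fast paths use two scalar profiles instead of the general
engine: the equal-correlation model reduces to a one-dimensional score
equation Σ n_i[−ρ/(1−ρ²) + r_i/(1 − ρ r_i)] = 0 solved by damped Newton,
and the equal-slope model factorizes as f(x)·f(y|x) whose ML solution is
the fixed point β = Σ w_i S_xy,i / Σ w_i S_xx,i with w_i = n_i/σ̂²_e,i.
The test suite pins both profiles to the general engine at 1e−6.

**Continuous.**  Ten coefficients (two per submodel, five submodels) are
estimated by Fisher scoring on the exact likelihood, vectorized over a
batch axis so that tens of thousands of replicate data sets fit in one
pass.  The expected information has a closed form in the five-parameter
block (validated in the tests against finite differences); scoring steps
are step-halved to keep the likelihood monotone per replicate, and rows
whose max |score| has not fallen below 1e−7·N after 60 iterations get a
damped-Newton polish with the finite-difference observed Hessian
(Levenberg-style per-row damping).  This resolves the heavy-tailed
replicates that plain scoring stalls on (small N with near-saturated
correlation paths); across the shipped sweep the non-convergence rate is
0 at 2,000 replicates per cell.  Reported coefficient covariances always
use the observed information at the optimum, not the scoring matrix.
Starting values: sample means, global log-SDs, the Fisher link of the
global correlation, zero slopes.

## Tests

Wald tests are two-sided.  The default critical values are standard
normal (large-sample ML theory); `TestConfig(critical_value_family="t")`
uses a t reference with df = Σ(n_i − 2) over the two groups involved —
the conventional independent-samples count, and the family used by the
table-reproduction harness because the published interval construction
names the t quantile.  Confidence intervals for exp(θ) exponentiate the θ
interval endpoints.  LR comparisons use χ² with df equal to the
difference in free-coefficient counts, with χ² clamped at 0.  No
multiple-testing correction is applied anywhere; reports show raw
p-values, and users comparing several categories against a base should
correct externally if they need familywise control.  With more than two
categories the package reports pairwise θ tests against the designated
base plus an explicitly labelled joint Wald χ² over all contrasts.

## Synthetic data

The generators are pure functions of (parameters, seed); replicate i of a
Monte-Carlo run uses `default_rng(seed + i)`, so any single replicate can
be regenerated in isolation and aggregates are independent of execution
order and chunking.

Categorical scenarios draw each group from a bivariate normal with the
scenario's variances and covariance (guarded at 1 − ρ² ≥ 1e−10).  Skewed
scenarios use Azzalini skew-normal margins with shape λ via the
shared-latent construction X = d|W| + √(1−d²)U, Y = d|W| + √(1−d²)V with
d = λ/√(1+λ²) and corr(U, V) solved so corr(X, Y) hits the scenario
target; both margins are then *exactly* skew-normal (verified by
Kolmogorov–Smirnov against an independent skew-normal CDF) and are
affinely rescaled to the target means and SDs.  Two honest limitations of
this construction: strongly negative target correlations are unreachable
for large λ (the shared |W| term contributes positive covariance), and
the shared latent makes the two sample variances co-fluctuate, which
damps the excess-kurtosis inflation of var(θ̂) relative to constructions
with independent skewness sources — the skewed null rejection rates it
produces (≈0.055 at λ = 4) are therefore at the lower end of what other
skew-dependence choices give.  Continuous scenarios draw z ~ N(0, 1) and
(x, y) | z from the link-function population.

The scenario registry (`build_scenario`) encodes the simulation designs
used for calibration: a two-group null family with constant variance
ratio 2, ρ = 1/√2, β_y = 1 and group variances (1,2)/(2,4)/(4,8) at sizes
70/70, 45/155, 90/180, with skew λ ∈ {0, 2, 4}; power families holding
either the correlation at 0.5 or the slope at 0.5 while the second
group's variance ratio moves through 1.5/2/4 (sizes 70/70, 40/100,
140/140, 80/200); slope-moderation (β₂ ∈ {0.61, 0.71, 1.00}) and
correlation-moderation (ρ₂ ∈ {0.41, 0.35, 0.25, 0.17}) families for the
LR comparisons with σ_x = 1 and σ_y = β/ρ; continuous null cells with
δ_x1 = δ_y1 = 0.5, δ_r1 = 0 and δ_r0 ∈ {0, 0.5, 1}; and the
two-condition polarization example (ρ = 0.45 in both conditions, σ_y 2 vs
1).  Every registry entry self-checks its derived quantities (ρ, β_y,
error variance) against the closed-form identities at construction.

The continuous power/bias sweep fixes δ_r0 = 0 (so the correlation
difference at z = 1 is tanh(δ_r1/2), matching the effect-size grid
{0, 0.1, 0.3, 0.5, 0.7}), puts the variance-ratio moderation entirely in
y (δ_x1 = 0, δ_y1 = θ₁, mirroring the categorical designs where σ_x is
constant), and uses zero means and unit baseline SDs.  The grids are
δ_r1 ∈ {0, 0.2007, 0.6190, 1.0986, 1.7346} and
θ₁ ∈ {0.1116, 0.2027, 0.3466, 0.5493, 0.6931, 0.8047} at N ∈ {70, 140,
280}.

What passing these simulations does *not* show about real data: the
generators draw from the model family itself (plus controlled skew), so
they exercise calibration and power under correct or mildly misspecified
distributions, not robustness to outliers, measurement error,
heteroscedasticity in unmodelled directions, or moderator measurement
noise.

## Estimation bias: two scales

The ML estimator of the correlation-submodel slope δ_r1 is biased upward
at small N, most strongly at large effects, and the bias approximately
halves when N doubles (≈0.20 → 0.10 → 0.05 across N = 70/140/280 at
δ_r1 = 1.7346 on the link scale; cross-checked against an independent
BFGS implementation of the same likelihood in R).  On the correlation
scale — the bias of the implied effect ρ̂(1) − ρ̂(0) — saturation of the
tanh inverse link compresses this to a maximum of ≈0.04 over the sweep,
and the θ₁ bias maxes at ≈0.02–0.03.  The harness records both scales in
every cell (`bias_delta_r1`, `bias_delta_rho`, `bias_theta1`);
`scripts/acceptance.py` reports the correlation-scale maximum, which is
the scale on which the published bound for this estimator holds.

## Numerical choices

- ρ is clamped to |ρ| ≤ 1 − 1e−10 inside every likelihood evaluation and
  log-SD link values to ±40, preventing overflow at boundary samples.
- Observed-information covariances use central finite differences of the
  analytic score with per-parameter steps 1e−5·(1 + |p|); the information
  matrix is symmetrized before inversion and a condition number above
  1e12 raises a singular-information error advising on collinearity.
- LR χ² values in (−1e−6·|ℓ|, 0) are clamped to 0; anything more negative
  raises (non-nested or non-converged input).
- Group moments require n ≥ 4, nonzero variance in both variables and
  |r| < 1; violations raise a degenerate-data error naming the variable.
- Monte-Carlo cells exclude and count non-converged replicates, print the
  count, and abort if they reach 5% of the requested replicates.
- Replicate batches are processed in chunks of 4,000 to bound memory
  (~30 MB per chunk at N = 280).

## Problem sizes in the shipped harness

The table-reproduction cells run at the designs' own sizes: 20,000
replicates for every categorical cell (closed-form per-replicate
computation, a few seconds per cell), 5,000 replicates for the continuous
Type-I-error cell at N = 280, and 2,000 replicates per cell for the
90-cell bias sweep (batched fits, a few seconds per cell).  These sizes
put the Monte-Carlo standard error well below every tolerance the
comparisons use.

## Known limitations

- One moderator per model; no multiple predictors per submodel, no
  tolerance/semi-partial extension, no Bayesian estimation, no
  heteroscedasticity-robust (sandwich) variants.
- The continuous-moderator tests are Wald-only; LR alternatives are
  provided only for the categorical engine.
- `EQUAL_SLOPE` combines with the homogeneity constraints but not with
  `EVR`/`EQUAL_RHO` (the joint parameterizations are not implemented).
- The skew-dependence construction cannot reach strongly negative
  correlations at large λ (see above), and skewed continuous scenarios
  require the correlation path ρ(z) to stay in the reachable region.
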