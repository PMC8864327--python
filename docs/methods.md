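# Methods

## Data model

The unit of analysis is the tooth site or surface, not the patient.  Each
arm is one 2×2 table (TP/FP/FN/TN) for a study × technology (× optional
dataset label and positivity threshold).  The diseased margin `tp + fn` and
sound margin `tn + fp` must both be ≥ 1.  No clustering adjustment is made
for multiple sites per patient: the models treat the site-level tables as
given, matching how such data are reported.  When a study contributes
several data sets for one technology (e.g. analog and digital radiographs),
deduplication keeps the data set with the largest total site count; ties
break to the lexicographically smallest dataset label so the rule is
deterministic and auditable.  Eligibility filtering runs *after*
deduplication (the alternative order is defensible; this one guarantees the
retained data set is the largest among all of a study's candidates).

## Likelihood and random-effect structures

Given study-level random effects, arms contribute independent binomial
margins.  This conditional-independence assumption is forced by the data:
comparative accuracy studies essentially never report the 2×4
cross-classification of two index tests against the reference standard, so
the within-study correlation between tests' *errors* is not identifiable;
what is identifiable, and modelled, is the between-study correlation
structure of the operating points.

Within-person variants (complete designs, T technologies, random-effect
dimension 2T per study): M1 unstructured covariance; M2 block-diagonal
(separate bivariate models); M3 the shared-heterogeneity decomposition
`nu = u + w` with a single study-level (Se, Sp) correlation `rho_c`.  M3's
implied covariance is compound-symmetric — invariant to permuting
technologies — with diagonal `tau² + sigma²`, within-margin off-diagonal
`tau²`, and every cross-margin entry `rho_c·tau_se·tau_sp`.  We place the
(Se, Sp) correlation at the study level (u) only, with the w terms
independent; this realizes "one shared correlation and shared between-study
heterogeneity" while letting the two margins have distinct intrastudy
correlation coefficients `ICC = tau²/(tau²+sigma²)`.  Whether the original
formulation also correlated the w terms is not decidable from the main
text we worked from; the ICC definition used here is the one stated with
the reported results.

NMA variants (incomplete networks, ≥ 2 technologies per study): arm-based,
one bivariate random effect per realized arm, covariance per technology
(M1-NMA) or shared (M2-NMA).  There is deliberately no study-level
intercept shared across technologies — without paired tables it is not
identified — which is the key structural difference from the within-person
analysis, and the reason NMA between-technology contrasts can be biased by
systematic differences between the studies evaluating different
technologies.  Sparse technologies borrow strength only under M2-NMA,
through the shared variances.  A single-technology table is accepted as the
degenerate "bivariate" model (the two NMA variants coincide there).

## Priors

Defaults, all overridable through the prior configuration: logit-scale
summary means ~ Normal(0, 1.5²) (weakly informative on the probability
scale: ±1 SD spans roughly 0.18–0.82); heterogeneity SDs ~ half-Normal(1);
correlations ~ LKJ(2), i.e. mild shrinkage toward identity.  For M1's full
correlation matrix the sampler parameterizes the Cholesky factor through
canonical partial correlations of a C-vine with the level-dependent Beta
exponents that make the implied matrix prior exactly LKJ(η).  These
defaults are standard for DTA meta-analysis; they are not claimed to match
any particular published analysis' appendix priors.

## Sampling

The sampler is Hamiltonian Monte Carlo, run in lockstep across chains
(positions are a chains × dim matrix; one numpy pass advances all chains).
Random effects are non-centered; SDs are sampled on the log scale and
correlations via atanh, with exact Jacobians.  Gradients are analytic for
every block except M1's partial correlations, which use central finite
differences (checked against full finite differences in the test suite).
Warmup uses the standard windowed scheme — step-size-only buffer, doubling
windows that re-estimate a diagonal inverse metric from the window draws
(regularized variance; the momentum mass is its reciprocal) with a
step-size re-initialization after each update, and a terminal dual-averaging
polish at a 0.9 target acceptance.  Trajectory lengths are jittered
uniformly on [1, 48] leapfrog steps to break resonances.  Energy errors
above 1000 count as divergences; divergence-dominated runs attach a warning
but still return draws.

Defaults: 4 chains × 1,000 warmup + 1,000 kept draws.  The convergence gate
(split R-hat < 1.05 and ESS ≥ 100 for every reported parameter, computed
with arviz) mirrors the stopping rule of the analysis this package
implements; a failed gate triggers one automatic retry with doubled
iterations, doubled maximum trajectory length, and a 0.95 acceptance
target.  The gate is evaluated on the
reported structural parameters; per-study random effects are integrated
over rather than stored.

## Marginal likelihoods and cross-validation

Leave-one-study-out CV needs `p(y_i | θ)` with study i's random effects
integrated out.  The integrand is log-concave, so each integral uses
mode-centred, Hessian-rescaled (adaptive) Gauss–Hermite quadrature: damped
Newton to the conditional mode, then a product grid rotated by the Cholesky
factor of the negative Hessian — 9 nodes per dimension for the
2-dimensional per-arm integrals (NMA, M2), 3 per dimension for the
2T-dimensional within-study integrals (M1, M3).  Against brute-force
integration the 2-D rule is exact to ~1e-7 and the 6-D rule to ~1e-2 in log
density, ample for elpd comparisons.  PSIS-LOO (arviz) is the default CV
estimator at the study level (studies are the exchangeable unit); if any
Pareto-k exceeds 0.7 an exact K-fold refit (default K = 10) is available.
Following the source analysis' logic, |Δelpd| ≤ 2·SE(Δ) counts as "no
evidence of a difference" and the simplest model is preferred
(M3 ≺ M2 ≺ M1; M2-NMA ≺ M1-NMA).

## Summaries

Summary operating points are posterior medians of `expit(mu)` (robust to
logit-scale skew); credible intervals are equal-tailed 2.5/97.5
percentiles.  Prediction intervals push one fresh random-effect draw per
posterior draw through the per-technology marginal 2×2 covariance implied
by the fitted variant, then take the same percentiles — by construction
they contain the credible intervals.  Pairwise differences are centred on
the posterior mean of the per-draw probability-scale differences, so they
are exactly antisymmetric; with median-based points the
difference-of-points identity holds only approximately (within ~0.02 in the
test suite).  ROC-space credible and prediction regions are the convex
contour of the 95% deepest draws by Mahalanobis distance on the logit
scale — deterministic given draws; one of several defensible
constructions, whose testable contract is containment: ~95% of fresh
predictive draws fall inside the prediction contour.

Consequence tables: at prevalence p and cohort N (default 1,000),
`D = round(N·p)`, `TP = round(D·Se)`, `FN = D − TP`, `TN = round((N−D)·Sp)`,
`FP = (N−D) − TN`, rounding halves away from zero; interval columns apply
the same maps to the credible endpoints, order-reversed for FN and FP.
Two print issues in the source table this mirrors are worth noting for
anyone comparing digit-by-digit: the fluorescence true-positive upper bound
reads "2330" where the arithmetic gives 230, and the fluorescence-minus-
visual specificity difference is printed with a sign inconsistent with the
summary points; the package computes the arithmetic values.

Threshold-stratified analysis: the single-technology table is binned by
numeric positivity threshold ([e_k, e_{k+1}), last bin closed); each bin
gets an independent bivariate fit; bins with < 3 studies are flagged
low-information, arms without numeric thresholds are excluded with a
warning.

## Synthetic cohorts

The generator draws, per study, a total site count uniform on a configured
range, a diseased margin Binomial(N, prevalence) — resampled while either
margin is zero, which keeps the margin invariants exact and is seed-stable —
and study random effects from the configured covariance (full matrix or
hierarchical components).  All technologies within a study share the same
margins: the within-person design verifies the same sites once.  Latent
per-study operating points are returned separately so recovery tests never
re-derive them.

Two factory configurations define the study conditions used throughout the
tests and the acceptance script:

* `analysis1_config` — 19 studies, complete {fluorescence, visual, imaging}
  design, prevalence 0.66, 50–250 sites per study (mean 150, ≈ 2,850 sites
  total).  True summary means are the published within-person operating
  points; heterogeneity `tau_se=1.0, sigma_se=1.2, tau_sp=1.05,
  sigma_sp=1.1` gives total logit-scale SDs ≈ 1.56 per margin — wide enough
  to reproduce prediction intervals spanning roughly (0.1, 0.98) — and
  intrastudy correlations near 0.41 (Se) and 0.48 (Sp), the reported
  neighbourhood; `rho_c = −0.4` encodes the usual Se/Sp trade-off (its value
  is not published; DTA meta-analyses typically estimate a moderate negative
  correlation).
* `analysis2_config` — 64 studies, incomplete 5-technology network with the
  fluorescence/visual/imaging triple as the most common configuration and
  electrical/transillumination the sparsest, prevalence 0.70, 120–650 sites
  per study (≈ 24,600 sites total), shared NMA heterogeneity
  `s_se = s_sp = 1.2, rho = −0.4`.

What the generator does *not* emulate: case-control recruitment, imperfect
or heterogeneous reference standards, covariate effects (dentition, tooth
surface, in vivo vs in vitro), patient-level clustering of sites, and
continuous index-test readings (thresholds are labels only).  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the models' own assumptions, not robustness of the models
to these real-data complications.

## Numerical choices and limitations

Binomial terms use the `k·eta − n·softplus(eta)` form with precomputed
normalizing constants; degenerate probabilities (0/1) are handled exactly
in the public densities.  Covariance assembly tolerates numerically
singular (zero-variance) components, so degenerate draws collapse
prediction intervals onto credible intervals rather than failing.
Quadrature adds 1e-10 jitter to random-effect covariances.  Recovery runs
in the tests and the acceptance script use the default sampler settings
(4 chains × 1,000 kept draws per fit), which clear the convergence gate
comfortably at these problem sizes.

Known limitations: M1 fits are the slowest (finite-difference gradients for
the correlation block) and M1's 2T-dimensional marginal likelihood uses the
coarsest quadrature; no inconsistency (direct-vs-indirect) decomposition is
computed for the network; no meta-regression on covariates; MCMC is the
only inference mode.
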