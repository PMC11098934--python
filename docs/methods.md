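# Methods

## Model

One trial laid out as an alpha design (t treatments, r replicates, b
incomplete blocks of k plots per replicate) follows

    y_ijl = mu + tau_i + gamma_j + rho_l(j) + eps_ijl,

with fixed treatment effects and independent random effects
gamma_j ~ N(0, sigma_r²), rho_l(j) ~ N(0, sigma_b²),
eps ~ N(0, sigma_e²).  The analysis never touches the plot data directly
once the per-trial sequential (treatments-first) ANOVA is computed: the
stratum sums of squares (SS_r, SS_b, SS_e) with degrees of freedom
(v_r, v_b, v_e) are sufficient for the variance components, and
conditionally on sigma,

    SS_i / E(MS_i) ~ chi-squared(v_i),  independently for i in {r, b, e},

with E(MS_r) = sigma_e² + c1·sigma_b² + c2·sigma_r²,
E(MS_b) = sigma_e² + c3·sigma_b², E(MS_e) = sigma_e².  Because treatments
are fitted *before* the design effects, these laws are central; the package
treats the scaled chi-squared form as its modelling assumption and verifies
it by simulation (means, variances and KS tests agree exactly on the
designs in scope).

The design constants are computed as normalised traces of the sequential
projection increments: with B_i an orthonormal basis of stratum i's rank
increment and Z the relevant incidence matrix, c = ||Zᵀ B_i||²_F / v_i.
For resolvable designs this gives c1 = k and c2 = b·k exactly; c3 ≤ k
depends on the treatment-block concurrence pattern (1.5 for the 6-variety,
2-replicate, block-of-3 design).  The trace formulation coincides with the
classical tabular EMS algorithm for sequential (Type I) expectations and is
much easier to verify — a Monte-Carlo regression of MS_b on sigma_b² is the
oracle in the tests.

Note on the likelihood: the Gamma form is the standard
log-density with shape v/2 and scale 2 (the chi-squared special case).  The
per-stratum density of SS itself follows from the change of variable
W = SS/E(MS), contributing the extra −log E(MS) term.

## Cross-trial priors

Four families describe how sigma varies across trials, all built on a
standard trivariate normal latent z so that quadrature and MCMC share one
unconstrained scale:

* **lognormal** — log sigma² ~ MVN(theta, phi); sigma(z) = exp(theta + Lz),
  L = chol(phi).
* **lognormal (constrained parameterisation)** — same law; phi is carried
  as exp(lambda_ii) variances and tanh(lambda_ij) (inverse Fisher z)
  correlations, making every real 9-vector admissible up to joint positive
  definiteness.
* **gamma** — sigma_i² = beta_i · Q_gamma(alpha_i, Phi(z̃_i)) with
  z̃ = R^{1/2} z (spectral square root, eigenvalue floor 1e-10): Gamma
  marginals, Gaussian copula with correlation R.  Latent means and
  variances are fixed at 0 and 1, so only the three correlations of R are
  free beyond (alpha, beta).
* **inverse_gamma** — the reciprocal of the gamma construction, i.e.
  inverse-Gamma(alpha_i, scale 1/beta_i) marginals; the latent map is
  monotone decreasing.  The IG scale convention is fixed as
  reciprocal-of-Gamma(alpha, beta) throughout.

All four guarantee strictly positive variance components, which is the
point: no stratum can be estimated out of the model.

## Empirical Bayes

The marginal likelihood of trial t integrates the conditional SS likelihood
over the latent scale,

    L_t(eta) = ∫ exp( l(SS_t | sigma(z)) ) phi_3(z) dz,

and Σ_t log L_t is maximised over the hyper-parameters eta.  The integral
uses tensor Gauss–Hermite quadrature (7 nodes per dimension by default),
adaptively recentred at each trial's conditional mode with scaling from the
mode's curvature.  Numerical choices that matter:

* The mode search is a damped Newton iteration run vectorised across all
  trials, with finite-difference derivatives (step 1e-4), a trust-region
  cap of 2 on the step norm, and warm starts between optimiser evaluations.
* The negative Hessian's eigenvalues are floored at 0.25.  The integrand is
  likelihood × standard-normal prior and the prior alone contributes +1
  curvature per latent dimension, so flat or convex likelihood directions
  (common when v_r = 1) would otherwise blow the quadrature's scaling
  covariance up by orders of magnitude — this floor was the decisive
  robustness fix, verified against dense-grid and Monte-Carlo oracles.
* Hyper-parameters are optimised on the unconstrained scale (theta plus
  log-variance/Fisher-z lambda for both lognormal parameterisations;
  log alpha, log beta, Fisher-z of R for gamma families) by L-BFGS-B with
  restarts, followed by a budgeted Powell polish; the search runs on a
  5-node grid and the reported value and predictions on the configured
  grid.  The raw-phi surface defeats quasi-Newton line searches (measured,
  not conjectured), which is why the barrier parameterisation is only used
  to reject inadmissible points.
* Starting values are method-of-moments: nonpositive ANOVA estimates are
  floored at 1e-3·MS_e before taking logs (they are the motivating
  phenomenon, so floors are routine); theta starts at log(mean estimate) −
  phi/2 because the raw estimates are marginally unbiased, and the log-scale
  covariance is clipped to a moderate range.

Per-trial predictions are posterior means (ratio of quadrature sums) — the
MSE-optimal point prediction, matching the MSE scoring of the evaluation
protocol.  AIC = −2·loglik + 2·9 (every family exposes nine free
hyper-parameters).

## Fully Bayesian

A Metropolis-within-Gibbs sampler re-derived from the hierarchy (not
transcribed from any external code):

* lognormal families: per-trial u_t = log sigma_t² by random-walk
  Metropolis; theta from its conjugate normal full conditional (flat
  hyperprior); phi from IW(nu + n, Omega + Σ_t (u_t − theta)(u_t − theta)ᵀ)
  with the operational hyperprior nu = 3, Omega = I.  The inverse-Wishart
  draw uses a Bartlett decomposition and is validated against the analytic
  posterior mean — the sampler's primary validity gate.
* gamma / inverse-gamma: alpha and beta are fixed at their marginal-ML (EB)
  estimates; the correlated latents z̃_t move by random-walk Metropolis and
  the three Fisher-z correlation parameters of R by a joint Metropolis step
  with a flat prior on the Fisher-z scale.

Proposal scales adapt toward ~30% acceptance during burn-in and freeze
afterwards.  Defaults are the operational schedule (10,000 iterations,
1,000 burn-in, thinning 10 → 900 retained per chain); the original analysis
reported a single run, but Gelman–Rubin needs several chains, so the default
is 4 chains with over-dispersed starts.  The PSRF uses the classical
between/within estimator — note it equals sqrt((n−1)/n) < 1, not exactly 1,
for identical chains.  On 2-replicate designs the replicate-level
hyper-parameters mix slowly (each trial contributes one replicate df); this
is a property of the posterior geometry, visible in the PSRF, not a sampler
defect.  An FB "AIC" is reported by convention as −2× the marginal
likelihood evaluated at the posterior means of the hyper-parameters + 2·9.

## Mixed model stage

`reml_fit` maximises the residual log-likelihood directly (Nelder-Mead on
log variances) and compares the full fit against the three boundary
candidates (sigma_r² = 0, sigma_b² = 0, both), flagging boundary solutions —
mirroring the stratum-dropping behaviour of standard packages that the
hierarchical approach is designed to avoid.  It agrees with an independent
nested grid search to 1e-4 and with statsmodels' MixedLM to its
convergence tolerance.  `gls_blue` solves generalised least squares at any
plugged-in sigma, which equals the Henderson mixed-model-equation solution
(checked to 1e-10) and interpolates between the unadjusted
(sigma_b² → 0) and intra-block (sigma_b² → ∞) estimators.  Treatment
effects are reported as estimated means via one-hot treatment coding;
pairwise differences are coding-invariant.

## Simulator and what a green test establishes

`simulate_trial` draws sigma from the stated prior, then effects and plot
errors as independent normals, exactly the analysis model.  The stated
generating world: lognormal prior with theta = log(0.2, 0.4, 1.0) and
phi = 0.25·I (variance components in response-units², error variance ~1,
block variance ~0.4 — mid-range for cereal variety trials on a dt/ha
scale), treatment effects tau ~ N(0, 1) centred, so genetic variance is
comparable to error variance.  The tau scale only matters for realism:
scoring uses treatment-difference *errors*, which are invariant to it.
Scenario A is 6 varieties / 2 replicates / blocks of 3; scenario B is 100
varieties / 2 replicates / blocks of 10.

Because the simulator implements the analysis model itself, green
simulation tests establish internal correctness (estimators recover what
generated the data; orderings among methods under correct specification),
not robustness to spatial trend, outliers or negative intra-block
correlation, which real uniformity-trial data could exhibit and the model
excludes by construction.

Two scale choices worth flagging:

* The hyper-parameter recovery check runs on a many-replicate layout
  (t=12, r=16, k=4).  With 2-replicate designs the replicate stratum has a
  single df per trial and the maximum-likelihood estimate of phi_rr is
  still far from its target at n=500 (verified against a Monte-Carlo
  oracle of the marginal likelihood); the estimator is consistent (checked
  at n=3000), just slow in that direction.  The method-comparison claims
  for 2-replicate designs are covered by the directional scenario tests
  instead.
* The method-comparison acceptance run uses n=200 trials and a reduced
  MCMC budget (2,000 iterations, 500 burn-in, 2 chains) to keep desk-scale
  runtimes; the operational schedule remains available through MCMCConfig.

## Known limitations

* Equal block sizes and resolvable designs only; no row-column structure,
  no spatial or AR(1) residuals.
* The FB stage samples the SS-level hierarchy, not the plot-level model;
  treatment effects enter only through the plug-in GLS stage (the exact
  flat-prior limit of a vague normal prior on cultivar effects).
* Degenerate block strata (k = t) are carried as absent, not errors; such
  trials are excluded from hierarchical fitting with a logged count.
* No standard errors for hyper-parameters, and no bridge/path-sampling
  marginal likelihoods for FB model comparison — the FB "AIC" is a labelled
  plug-in convention.
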