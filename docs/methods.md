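# Methods

## The model

`frailsurv` analyses clustered right-censored time-to-event data — its
motivating application is the time from a woman's birth to her first birth,
recorded in years, for married women grouped into regions.  Subject *j* of
cluster *i* has conditional hazard

    h_ij(t | z_i) = z_i · h0(t) · exp(x_ij′β),

where `h0` is a parametric baseline hazard, `x_ij` is a dummy-coded
covariate vector (reference level omitted), and `z_i > 0` is a *shared
frailty*: one unobserved multiplicative risk factor per cluster, drawn from
a gamma distribution with mean 1 and variance θ (shape 1/θ, rate 1/θ).
θ = 0 recovers independence; θ > 0 induces within-cluster dependence with
Kendall's tau = θ/(θ+2).

Five baseline families are supported — exponential, Gompertz, Weibull,
log-normal, log-logistic — parameterized on the hazard scale (for the
Weibull, S(t) = exp(−λt^γ), so λ is a rate-like coefficient, not a
`(t/scale)` scale).  The Weibull PH fit can be re-expressed in accelerated
failure time form with `weibull_ph_to_aft` (for the Weibull the two are
reparameterizations of the same model).

Censoring is assumed independent and noninformative; only right censoring
is handled.

## Marginal likelihood and maximum likelihood

Because the frailty is gamma, it integrates out analytically.  With d_i
events and risk mass A_i = Σ_j H0(t_ij)·exp(x_ij′β) in cluster i, the
cluster's marginal log-likelihood is

    Σ_j δ_ij [log h0(t_ij) + x_ij′β]
      + Σ_{k=0}^{d_i−1} log(1 + kθ)  −  (1/θ + d_i) log(1 + θ A_i).

The middle sum is the lgamma ratio lgamma(1/θ+d_i) − lgamma(1/θ) −
d_i·log(1/θ) written exactly for integer d_i; together with `log1p` it is
numerically stable for θ from 1e−300 up, and θ = 0 evaluates the
independent likelihood, so the function is continuous at the boundary.
The closed form is verified in the test suite against adaptive quadrature
of the frailty integral on random small datasets for all five families
(absolute tolerance 1e−8 on the log-likelihood).

`fit_ml` maximizes this over (baseline parameters, β, θ) with L-BFGS-B on
unconstrained transforms (log for positive parameters, log θ for the
frailty variance), multi-start (a moment-based start, a null/exponential
start, and perturbed copies; deterministic given the start seed).
Standard errors come from the numerically differentiated observed
information at the optimum, moved to the natural scale by the delta
method; a fitted θ below 1e−4 is reported with a boundary flag and no SE,
since the Wald approximation is meaningless on the boundary.  AIC =
−2·loglik + 2P and BIC = −2·loglik + P·log n are stored and asserted as
identities.

With only r clusters, θ̂ estimates the dispersion of the r *realized*
frailties; at r = 11 its sampling distribution is wide and right-skewed,
so single-dataset recovery checks for θ should be read with that in mind
(the reported SE reflects it).

## Bayesian estimation

Priors: independent N(0, 1e5) on each regression coefficient; Gamma(shape
1, rate 0.001) — mean 1000 — on positive baseline parameters; N(0, 1e5) on
real-valued baseline parameters (log-normal μ, Gompertz shape,
log-logistic location), chosen to match the coefficient prior since all
three are unbounded log-scale locations; Gamma(0.001, rate 0.001) on the
frailty precision 1/θ.  All are deliberately vague; on data of a few
hundred subjects and up the likelihood dominates.

The sampler is Metropolis-within-Gibbs with frailty data augmentation:

* **Frailties** have the conjugate full conditional z_i ~ Gamma(1/θ + d_i,
  rate 1/θ + A_i) and are drawn exactly.
* **β** (in sub-blocks of at most four coefficients), the **baseline
  parameters** (jointly) and **log θ** move by adaptive random-walk
  Metropolis on unconstrained transforms,
  with the positivity Jacobians in the acceptance ratio.  Proposal
  covariances are seeded from the inverse observed information at the
  starting point and then adapted (Robbins-Monro scale + empirical
  covariance) **during burn-in only**, so the post-burn-in kernel is fixed
  and valid.  Acceptance targets are 0.35-0.44.  A single joint β block was
  tried first and mixed too slowly (integrated autocorrelation ~100 for a
  13-coefficient model) to satisfy the MC-error rule at the default run
  length; small sub-blocks bring every parameter under the 5% rule there.
* Internally the sampler works on time divided by its geometric mean.
  Every supported family maps to itself under time scaling, the transform
  is unit-triangular on the unconstrained scale, and priors are always
  evaluated on the original-scale parameters; stored draws are mapped
  back.  This removes most of the scale/shape ("λ–γ ridge") posterior
  correlation that otherwise cripples random-walk mixing.

Defaults mirror the source methodology: 2 chains, 21,000 iterations each
with 1,000 burn-in, thinning 1 (20,000 stored per chain), overdispersed
starts at the ML fit plus chain-scaled perturbations.  Runs are bitwise
reproducible given the seed.

**Summaries.**  Posterior mean, SD, median, equal-tailed 95% interval; the
Monte-Carlo error of each mean uses batch means with 50 batches per chain.
A coefficient is flagged significant when its 95% interval excludes zero.
The run-length rule — MC error below 5% of the posterior SD for every
monitored parameter — is exposed as `mc_error_ok`; shorter exploratory
runs will fail it for the slowest-mixing parameters (λ, γ), which is the
rule working as intended.

**DIC.**  Dbar is the posterior mean of −2·log-likelihood, Dhat the
deviance at the posterior means, pD = Dbar − Dhat, DIC = Dbar + pD.  The
deviance uses the *marginal* (frailty-integrated) likelihood by default so
frailty and no-frailty models are on the same footing; a conditional
focus (given the sampled frailties) is available via `focus="conditional"`.
Dbar subsamples at most 500 stored draws — the deviance is smooth and this
introduces error orders of magnitude below model-comparison differences.

**Convergence diagnostics.**  The Brooks-Gelman-Rubin potential scale
reduction factor is computed over growing iteration windows (each window
discards its first half).  The classic estimator carries an (n−1)/n factor
that puts duplicated chains slightly *below* 1; values below 1 are pure
finite-sample artifacts and are reported as exactly 1.0.  Trace, density
and BGR panels are written per parameter with deterministic filenames.

## Nonparametric module

Kaplan-Meier uses simultaneous decrement at ties, with Greenwood pointwise
variance; the implementation is cross-checked against lifelines in the
tests.  The median is the smallest grid time with Ŝ ≤ 0.5; its confidence
interval inverts the log(−log) transformed pointwise band (each endpoint
is the first crossing of 0.5 by the corresponding band limit) — the method
is a documented choice, as is usual when the source of a printed interval
is unstated.  An undefined median (Ŝ never reaching 0.5) is returned as
NaN, not raised.  The K-sample log-rank test is the standard unweighted
chi-square with hypergeometric tie variance, delegated to lifelines and
verified against a hand-tabulated oracle.

## The synthetic generator

`ScenarioSpec.edhs_default()` encodes the published structure of the
EDHS 2016 first-birth sample as fixed study conditions: 11 regions with
the published relative sizes (deterministic largest-remainder allocation),
covariate marginals taken from the published counts, the fitted regime
Weibull(λ = e^−17.75, γ = 6.097) with the published posterior-mean
coefficients, frailty variance θ = 0.95, and independent administrative
censoring calibrated to 24.5%.  Event times are drawn by inverting
S(t|z,x) at a unit-exponential draw; everything is reproducible from one
seed, including byte-identical CSV output.

Censoring is uniform on (0, w) by default (exponential optional); w is
calibrated by Monte-Carlo root finding with common random numbers and a
fixed inner seed, targeting the *expected* censored fraction with the
frailty integrated out.  With 11 shared frailties of variance ~1, the
realized censored fraction of any single dataset varies around the target
with SD ≈ 0.016 at n = 8810 — far above binomial noise; checks on the
censored fraction therefore average a few replicates.

What the generator does **not** emulate: covariates are drawn
independently across variables (only marginals are published, not a joint
law); there are no survey weights or two-stage sampling; the real survey's
censoring mechanism (interview date) is assumed, not observed.  Passing
recovery tests on these data therefore demonstrates correctness of the
estimation machinery under the model's assumptions, not robustness to the
real data's correlation structure.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at reduced, fixed sizes
chosen once: parameter recovery at n = 3000 with 2 chains × 4,000 stored
draws; the DIC model-selection sweep at n = 500 and θ = 0.8 over 50
replicates with one short chain per model (the DIC gap under that much
heterogeneity is hundreds of units, so short chains suffice); the
MC-error rule on a reduced three-covariate fixture at n = 600 with
2 × 16,000 stored draws, the length at which the 5% rule is met — run
length chosen to satisfy the stopping rule, exactly how such rules are
used in practice.  The acceptance script runs the frailty model at the
full default length (2 × 20,000).

## Known limitations

* Gamma is the only frailty law; no inverse-Gaussian, log-normal or
  positive-stable alternatives, no time-varying covariates, no left
  truncation or interval censoring.
* θ̂ at 11 clusters is noisy by nature; neither the Wald interval nor the
  posterior concentrates faster than r allows, and the posterior SD of θ
  does not shrink with n (only with the number of clusters).
* The random-walk sampler is adequate for the model's dimension (≈16
  parameters) but is not an HMC/NUTS replacement for much larger models.
* A defective Gompertz (negative shape) has finite total hazard; sampling
  from it raises rather than returning infinite times.
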