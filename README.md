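# frailsurv

Gamma shared-frailty parametric survival models for clustered
time-to-event data, fitted by marginal maximum likelihood (AIC/BIC model
comparison) and by Metropolis-within-Gibbs MCMC (DIC, posterior summaries,
convergence diagnostics) — with a synthetic-data generator that emulates
the clustered structure of the EDHS 2016 time-to-first-birth sample, so
every stage is testable without any restricted microdata.

## Who this is for

Epidemiologists and biostatisticians analysing time-to-event outcomes
(time to first birth, disease onset, recovery) where subjects are grouped
into clusters — regions, facilities, families — and the clusters plausibly
carry unobserved shared risk.  Ignoring that heterogeneity biases hazard
ratios toward the null and understates uncertainty; a shared frailty term
absorbs it.

## The model

Subject *j* of cluster *i* has hazard

    h_ij(t | z_i) = z_i · h0(t) · exp(x_ij′β),      z_i ~ Gamma(1/θ, 1/θ),

with a parametric baseline `h0` (exponential, Gompertz, Weibull,
log-normal or log-logistic, on the hazard scale — e.g. Weibull
S(t) = exp(−λt^γ)), dummy-coded covariates, and a mean-1 gamma frailty
with variance θ shared within each cluster.  Within-cluster dependence is
Kendall's τ = θ/(θ+2).  The gamma frailty integrates out of the likelihood
in closed form, which gives fast exact ML fitting; the Bayesian route uses
vague priors (N(0, 1e5) on β, Gamma(1, 0.001) on positive baseline
parameters, Gamma(0.001, 0.001) on the frailty precision) and a
Metropolis-within-Gibbs sampler with conjugate frailty updates.
Kaplan-Meier estimation, median survival with a log(−log) interval, and
the K-sample log-rank test round out the pipeline.  See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
from frailsurv import (ScenarioSpec, generate, fit_ml, compare_ml,
                       run_mcmc, summarize_posterior, compute_dic,
                       hazard_ratio_table, kendalls_tau)

# simulate a clustered dataset in the fitted study regime
ds, report = generate(ScenarioSpec.edhs_reduced(n=1500, theta=0.8), seed=3)

# marginal-ML comparison across baseline families
fits = [fit_ml(ds, fam, with_frailty=wf, n_starts=2)
        for fam in ("exponential", "weibull", "lognormal")
        for wf in (False, True)]
print(compare_ml(fits).head(2).to_string(index=False))
```

prints (the frailty Weibull — the generating family — wins by ~136 AIC
points over the runner-up):

```
                    model    family  frailty       loglik  n_params         AIC         BIC  converged  best
  weibull (gamma frailty)   weibull     True -2924.460668         6 5860.921335 5892.800657       True  True
lognormal (gamma frailty) lognormal     True -2992.244258         6 5996.488516 6028.367838       True False
```

and the fitted frailty variance `theta = 0.846` (truth 0.8) gives
`kendalls_tau(0.846) = 0.297`: moderately strong within-region clustering
of first-birth timing.  The Bayesian stage takes the same dataset:

```python
res = run_mcmc(ds, "weibull", n_iter=21_000, burn_in=1_000, n_chains=2, seed=3)
summary = summarize_posterior(res)
print(hazard_ratio_table(summary, list(ds.design_columns)).round(3))
print(compute_dic(res, ds))
```

Hazard ratios are `exp(posterior mean)` with exponentiated 95% credible
intervals — e.g. a rural-residence coefficient of 0.21 renders as
HR ≈ 1.23, a 23% higher hazard of first birth for rural women; an interval
excluding 1 is flagged significant.  `compute_dic` returns Dbar, Dhat,
pD = Dbar − Dhat and DIC = Dbar + pD on the frailty-integrated deviance,
so the frailty and no-frailty rows are directly comparable.

The `examples/` directory holds one short script per capability
(simulate/describe, KM + log-rank, ML comparison, Bayesian fit); each
prints its numbers with a line on what they mean.  A thin CLI mirrors the
pipeline: `frailsurv simulate | describe | km | logrank | fit-ml |
fit-bayes | pipeline`.

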