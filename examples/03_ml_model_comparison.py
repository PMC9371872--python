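"""Fit parametric frailty models by marginal maximum likelihood and rank
them by AIC/BIC.

The gamma frailty integrates out of the likelihood in closed form, so the
marginal fit needs no sampling.  On data generated with real between-region
heterogeneity the gamma-frailty variant of the true family should win.
"""

from frailsurv import ScenarioSpec, compare_ml, fit_ml, generate, kendalls_tau

ds, report = generate(ScenarioSpec.edhs_reduced(n=1500, theta=0.8), seed=3)

fits = [
    fit_ml(ds, family, with_frailty=wf, n_starts=2)
    for family in ("exponential", "weibull", "lognormal")
    for wf in (False, True)
]
table = compare_ml(fits)
print(table.to_string(index=False))
print("\nthe lowest-AIC row is flagged best; the frailty variant beats the "
      "independent one when regions really are heterogeneous")

best = next(r for r in fits if r.family == "weibull" and r.with_frailty)
print(f"\nfitted frailty variance theta = {best.theta:.3f} "
      f"(truth {report.truth['theta']}); "
      f"Kendall's tau = {kendalls_tau(best.theta):.3f}")
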