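"""Kaplan-Meier estimation and log-rank comparisons on simulated data.

Prints the median time to first birth with its 95% confidence interval
(log(-log) band inversion) and a per-covariate log-rank table.  With frailty
variance 0.8 between regions, the region test should reject strongly.
"""

from frailsurv import ScenarioSpec, generate, kaplan_meier, median_survival
from frailsurv.nonparam import logrank_report

ds, _ = generate(ScenarioSpec.edhs_reduced(n=4000, theta=0.8), seed=2)

km = kaplan_meier(ds)
med = median_survival(km, confidence=0.95)
print(f"median time to event: {med.median:.1f} years "
      f"(95% CI {med.lower:.1f}, {med.upper:.1f})")
print("interpretation: half the simulated women have had the event "
      "by this age; the interval reflects Greenwood pointwise uncertainty")

print("\nlog-rank tests (chi-square, df = K-1):")
print(logrank_report(ds).to_string(index=False))
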