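"""Published structure of the EDHS 2016 time-to-first-birth sample.

These constants encode the printed study structure — regional censored/event
counts, covariate marginal frequencies, reference categories, and the fitted
Weibull-gamma-frailty regime — that the synthetic generator emulates and the
descriptive bookkeeping checks use.  They are study conditions, not tuning
knobs.
"""

from __future__ import annotations

import numpy as np

from .dataset import CovariateCodebook

#: region -> (censored count, event count); totals 2158 censored + 6652 events = 8810
REGION_COUNTS: dict[str, tuple[int, int]] = {
    "Tigray": (184, 668),
    "Afar": (136, 617),
    "Amhara": (290, 711),
    "Oromia": (261, 962),
    "Somali": (150, 752),
    "Benishangul": (183, 550),
    "SNNPR": (267, 867),
    "Gambela": (159, 480),
    "Harari": (128, 382),
    "Addis Ababa": (231, 323),
    "Dire Dawa": (169, 340),
}

N_TOTAL = 8810
N_EVENTS = 6652
N_CENSORED = 2158
CENSORING_FRACTION = N_CENSORED / N_TOTAL  # 0.2449...

#: reference category is listed first for every covariate
CODEBOOK = CovariateCodebook(
    {
        "contraceptive_use": ["Yes", "No"],
        "residence": ["Urban", "Rural"],
        "age_first_marriage": ["<18", "18-34", ">34"],
        "working": ["No", "Yes"],
        "husband_education": ["No education", "Primary", "Secondary or above"],
        "mother_education": ["No education", "Primary", "Secondary or above"],
        "media_access": ["No", "Yes"],
        "household_head": ["Male", "Female"],
        "wealth_index": ["Poor", "Middle", "Rich"],
    }
)

#: marginal category counts (censored + event columns of the descriptive table)
COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "contraceptive_use": {"Yes": 1161 + 3298, "No": 997 + 3354},
    "residence": {"Urban": 746 + 1331, "Rural": 1412 + 5321},
    "age_first_marriage": {"<18": 1443 + 4070, "18-34": 707 + 2575, ">34": 8 + 7},
    "working": {"No": 1233 + 4770, "Yes": 925 + 1882},
    "husband_education": {
        "No education": 1020 + 3130,
        "Primary": 603 + 2158,
        "Secondary or above": 535 + 1364,
    },
    "mother_education": {
        "No education": 1338 + 4079,
        "Primary": 524 + 1767,
        "Secondary or above": 296 + 806,
    },
    "media_access": {"No": 1349 + 4931, "Yes": 809 + 1721},
    "household_head": {"Male": 1716 + 5444, "Female": 442 + 1208},
    "wealth_index": {"Poor": 700 + 3359, "Middle": 287 + 962, "Rich": 1171 + 2331},
}

#: marginal category probabilities derived from the counts
COVARIATE_PROBS: dict[str, dict[str, float]] = {
    cov: {cat: n / N_TOTAL for cat, n in counts.items()}
    for cov, counts in COVARIATE_COUNTS.items()
}

#: relative cluster (region) sizes
CLUSTER_NAMES = list(REGION_COUNTS)
CLUSTER_PROBS = np.array(
    [sum(REGION_COUNTS[r]) / N_TOTAL for r in CLUSTER_NAMES], dtype=float
)

#: posterior-mean regression coefficients of the fitted Weibull-gamma-frailty
#: model, keyed by design column name (reference levels carry no coefficient)
POSTERIOR_MEAN_BETA: dict[str, float] = {
    "contraceptive_use[No]": 0.1134,
    "residence[Rural]": 0.2112,
    "age_first_marriage[18-34]": -1.385,
    "age_first_marriage[>34]": -2.864,
    "working[Yes]": 0.005898,
    "husband_education[Primary]": 0.09979,
    "husband_education[Secondary or above]": 0.1148,
    "mother_education[Primary]": 0.1826,
    "mother_education[Secondary or above]": -0.05222,
    "media_access[Yes]": -0.1168,
    "household_head[Female]": -0.1682,
    "wealth_index[Middle]": -0.05626,
    "wealth_index[Rich]": -0.00962,
}

#: fitted Weibull baseline: log-hazard intercept (constant) and shape
WEIBULL_LOG_LAMBDA = -17.75
WEIBULL_SHAPE = 6.097

#: fitted frailty variance (between-region heterogeneity)
FRAILTY_VARIANCE = 0.95
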