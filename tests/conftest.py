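import numpy as np
import pandas as pd
import pytest

from frailsurv.dataset import CovariateCodebook, SurvivalDataset
from frailsurv.frailty import fit_ml
from frailsurv.bayes import run_mcmc, summarize_posterior
from frailsurv.simulate import ScenarioSpec, generate


def make_dataset(times, events, clusters=None, groups=None) -> SurvivalDataset:
    """Hand-build a small dataset; one optional binary-ish covariate 'g'."""
    n = len(times)
    frame = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "cluster": clusters if clusters is not None else ["c1"] * n,
        }
    )
    if groups is not None:
        frame["g"] = list(groups)
        cats = sorted(set(groups))
        if len(cats) < 2:
            cats = cats + ["_unused"]
        codebook = CovariateCodebook({"g": cats})
    else:
        codebook = CovariateCodebook({})
    return SurvivalDataset(frame, codebook)


def random_small_dataset(rng, n=30, n_clusters=3, max_time=3.0) -> SurvivalDataset:
    frame = pd.DataFrame(
        {
            "time": rng.uniform(0.2, max_time, n),
            "event": rng.integers(0, 2, n),
            "cluster": rng.choice([f"c{i}" for i in range(n_clusters)], n),
            "g": rng.choice(["a", "b"], n),
        }
    )
    return SurvivalDataset(frame, CovariateCodebook({"g": ["a", "b"]}))


@pytest.fixture(scope="session")
def reduced_fixture():
    """A moderate synthetic dataset in the fitted study regime (theta=0.8),
    with its ML fit — shared across MCMC-based tests."""
    scenario = ScenarioSpec.edhs_reduced(n=600, theta=0.8)
    ds, report = generate(scenario, seed=0)
    fit = fit_ml(ds, "weibull", with_frailty=True, n_starts=1)
    return {"scenario": scenario, "ds": ds, "report": report, "fit": fit}


@pytest.fixture(scope="session")
def reduced_mcmc(reduced_fixture):
    """The default-length posterior run on the reduced fixture (2 chains)."""
    res = run_mcmc(
        reduced_fixture["ds"],
        "weibull",
        n_iter=17_000,
        burn_in=1_000,
        n_chains=2,
        seed=0,
        init=reduced_fixture["fit"].spec,
    )
    return {"result": res, "summary": summarize_posterior(res)}
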