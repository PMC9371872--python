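"""Kaplan-Meier estimation, median survival, and the K-sample log-rank test.

The product-limit estimator and its Greenwood variance are computed directly
(they are needed in a raw per-event-time form for the log(-log) median band);
the K-sample log-rank chi-square is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .dataset import SurvivalDataset

__all__ = [
    "KMEstimate",
    "MedianSurvival",
    "LogRankResult",
    "kaplan_meier",
    "km_from_arrays",
    "median_survival",
    "log_rank",
    "logrank_report",
]


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate on the grid of distinct event times.

    ``survival[i]`` is S-hat just after ``times[i]``; ``variance`` is the
    Greenwood pointwise variance of S-hat.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S-hat (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([1.0], self.survival))
        return padded[idx]


class MedianSurvival(NamedTuple):
    median: float
    lower: float
    upper: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.median)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def km_from_arrays(time, event) -> KMEstimate:
    """Kaplan-Meier from raw (time, event) arrays; ties decrement simultaneously."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("cannot estimate a survival curve from no records")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = time.size
    n_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        n_risk[i] = np.sum(time >= t)
        n_events[i] = np.sum((time == t) & (event == 1))
    surv = np.cumprod(1.0 - n_events / n_risk)
    # Greenwood: var = S^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = n_events / (n_risk * (n_risk - n_events))
        inc[~np.isfinite(inc)] = 0.0  # S-hat is 0 there anyway
    var = surv**2 * np.cumsum(inc)
    return KMEstimate(
        times=event_times,
        n_risk=n_risk,
        n_events=n_events,
        survival=surv,
        variance=var,
        n=n,
    )


def kaplan_meier(ds: SurvivalDataset) -> KMEstimate:
    """Kaplan-Meier estimate of the dataset's pooled survival function."""
    return km_from_arrays(ds.time, ds.event)


def median_survival(km: KMEstimate, confidence: float = 0.95) -> MedianSurvival:
    """Median survival time with a log(-log)-transformed confidence interval.

    The median is the smallest grid time with S-hat <= 0.5.  The interval is
    obtained by inverting the pointwise log(-log) band: each endpoint is the
    smallest time at which the corresponding band limit drops to 0.5.  When
    S-hat never reaches 0.5 the median (or an endpoint) is NaN — an undefined
    median is a value, not an exception.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    s = km.survival
    t = km.times

    def first_crossing(curve: np.ndarray) -> float:
        hit = np.nonzero(curve <= 0.5)[0]
        return float(t[hit[0]]) if hit.size else float("nan")

    z = stats.norm.ppf(0.5 + confidence / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_loglog = np.sqrt(km.variance) / np.abs(s * np.log(s))
        upper = s ** np.exp(-z * se_loglog)  # upper band on S
        lower = s ** np.exp(z * se_loglog)
    # where S-hat is exactly 0 or 1 the transform is degenerate: band collapses
    degenerate = ~np.isfinite(se_loglog)
    upper[degenerate] = s[degenerate]
    lower[degenerate] = s[degenerate]
    # the lower survival band crosses 0.5 earlier -> lower median bound
    return MedianSurvival(
        median=first_crossing(s),
        lower=first_crossing(lower),
        upper=first_crossing(upper),
    )


def log_rank(ds: SurvivalDataset, group_covariate: str) -> LogRankResult:
    """K-sample log-rank test across the levels of a covariate (or 'cluster').

    Unweighted statistic with hypergeometric tie handling; df = K - 1.
    """
    if group_covariate == "cluster":
        groups = ds.frame["cluster"].astype(str)
    elif group_covariate in ds.codebook.covariates:
        groups = ds.frame[group_covariate].astype(str)
    else:
        raise KeyError(f"unknown grouping covariate {group_covariate!r}")
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    res = multivariate_logrank_test(ds.time, groups, ds.event)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=n_groups - 1,
        p_value=float(res.p_value),
    )


def logrank_report(ds: SurvivalDataset, covariates: list[str] | None = None) -> pd.DataFrame:
    """Per-covariate log-rank statistics (the survival-comparison table)."""
    if covariates is None:
        covariates = ["cluster"] + ds.codebook.covariates
    rows = []
    for cov in covariates:
        res = log_rank(ds, cov)
        rows.append(
            {
                "variable": cov,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
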