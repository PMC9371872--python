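"""Gamma shared-frailty proportional-hazards model and maximum likelihood.

The conditional hazard for subject j of cluster i is

    h_ij(t | z_i) = z_i * h0(t) * exp(x_ij' beta),

with z_i ~ Gamma(shape 1/theta, rate 1/theta) — mean 1, variance theta —
shared by all subjects of the cluster.  theta = 0 recovers the independent
(no-frailty) parametric PH model.  Because the frailty is gamma, it integrates
out in closed form: with d_i the number of events and
A_i = sum_j H0(t_ij) exp(x_ij' beta), the cluster's marginal log-likelihood is

    sum_j delta_ij [log h0(t_ij) + x_ij' beta]
      + sum_{k=0}^{d_i - 1} log(1 + k theta)  -  (1/theta + d_i) log(1 + theta A_i)

(the middle sum is lgamma(1/theta + d_i) - lgamma(1/theta) - d_i log(1/theta)
written in a form that is exact for integer d_i and stable as theta -> 0).

Within-cluster dependence is summarized by Kendall's tau = theta/(theta + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .baselines import (
    POSITIVE_PARAMS,
    PARAM_NAMES,
    BaselineSpec,
    cumulative_hazard,
    log_hazard,
    pack_params,
    unpack_params,
)
from .dataset import SurvivalDataset

__all__ = [
    "FrailtyModelSpec",
    "kendalls_tau",
    "conditional_hazard",
    "frailty_log_density",
    "complete_data_loglik",
    "marginal_loglik",
    "MLFitResult",
    "fit_ml",
    "compare_ml",
    "weibull_ph_to_aft",
]


@dataclass(frozen=True)
class FrailtyModelSpec:
    """Baseline family + regression coefficients + frailty variance.

    ``theta = 0`` means no frailty (independence across clusters).
    """

    baseline: BaselineSpec
    beta: np.ndarray
    theta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if self.theta < 0.0:
            raise ValueError("frailty variance theta must be >= 0")


def kendalls_tau(theta: float) -> float:
    """Kendall's tau induced by gamma frailty variance theta: theta/(theta+2)."""
    if theta < 0.0:
        raise ValueError("theta must be >= 0")
    return theta / (theta + 2.0)


def conditional_hazard(spec: FrailtyModelSpec, z: float, x, t) -> np.ndarray:
    """h(t | z, x) = z * h0(t) * exp(x' beta)."""
    if np.any(np.asarray(z) <= 0.0):
        raise ValueError("frailty z must be > 0")
    x = np.asarray(x, dtype=float)
    return z * np.exp(log_hazard(spec.baseline, t) + x @ spec.beta)


def frailty_log_density(z, theta: float) -> np.ndarray:
    """Log density of the mean-1 gamma frailty: Gamma(shape 1/theta, rate 1/theta)."""
    if theta <= 0.0:
        raise ValueError("theta must be > 0")
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0.0):
        raise ValueError("z must be > 0")
    return stats.gamma.logpdf(z, a=1.0 / theta, scale=theta)


def _linear_predictor(spec: FrailtyModelSpec, ds: SurvivalDataset) -> np.ndarray:
    X = ds.design
    if X.shape[1] != spec.beta.size:
        raise ValueError(
            f"beta has {spec.beta.size} entries but the design matrix has "
            f"{X.shape[1]} columns"
        )
    return X @ spec.beta


def complete_data_loglik(
    spec: FrailtyModelSpec, ds: SurvivalDataset, frailties
) -> float:
    """Log-likelihood conditional on the cluster frailty values.

    sum_ij  delta_ij log[z_i h0(t_ij) e^{x'beta}]  -  z_i H0(t_ij) e^{x'beta}
    """
    z = np.asarray(frailties, dtype=float)
    if z.shape != (ds.r,):
        raise ValueError(f"expected {ds.r} frailty values, got shape {z.shape}")
    if np.any(z <= 0.0):
        raise ValueError("all frailties must be > 0")
    eta = _linear_predictor(spec, ds)
    cl = ds.cluster_index
    delta = ds.event
    lh0 = log_hazard(spec.baseline, ds.time)
    H0 = cumulative_hazard(spec.baseline, ds.time)
    event_part = float(np.sum(delta * (np.log(z[cl]) + lh0 + eta)))
    risk_part = float(np.sum(z[cl] * H0 * np.exp(eta)))
    return event_part - risk_part


def _cluster_stats(spec: FrailtyModelSpec, ds: SurvivalDataset):
    """Per-cluster event counts d_i, frailty-free risk mass A_i, and the
    summed event log-hazard term."""
    eta = _linear_predictor(spec, ds)
    cl = ds.cluster_index
    delta = ds.event
    lh0 = log_hazard(spec.baseline, ds.time)
    H0 = cumulative_hazard(spec.baseline, ds.time)
    A = np.bincount(cl, weights=H0 * np.exp(eta), minlength=ds.r)
    d = ds.cluster_events
    event_term = float(np.sum(delta * (lh0 + eta)))
    return d, A, event_term


def marginal_loglik(spec: FrailtyModelSpec, ds: SurvivalDataset) -> float:
    """Observed-data log-likelihood with the gamma frailty integrated out.

    Continuous in theta at 0 (theta = 0 evaluates the independent model).
    """
    d, A, event_term = _cluster_stats(spec, ds)
    theta = spec.theta
    if theta == 0.0:
        return event_term - float(A.sum())
    # sum_{k<d_i} log1p(k*theta), exact rewrite of the lgamma ratio
    dmax = int(d.max()) if d.size else 0
    cum = np.concatenate(
        ([0.0], np.cumsum(np.log1p(theta * np.arange(dmax, dtype=float))))
    )
    ratio_term = float(cum[d].sum())
    tail = float(np.sum((1.0 / theta + d) * np.log1p(theta * A)))
    return event_term + ratio_term - tail


@dataclass
class MLFitResult:
    """Point estimates, observed-information standard errors, and AIC/BIC."""

    family: str
    with_frailty: bool
    baseline: BaselineSpec
    beta: pd.Series
    theta: float
    loglik: float
    n_params: int
    aic: float
    bic: float
    se: pd.Series
    converged: bool
    theta_boundary: bool
    n: int
    data_key: str = ""
    n_starts_used: int = 0

    @property
    def spec(self) -> FrailtyModelSpec:
        return FrailtyModelSpec(self.baseline, self.beta.to_numpy(), self.theta)

    @property
    def label(self) -> str:
        return f"{self.family} ({'gamma frailty' if self.with_frailty else 'no frailty'})"


def _baseline_moment_init(family: str, ds: SurvivalDataset) -> BaselineSpec:
    """Crude moment-matching starting values from the observed times."""
    t = ds.time
    delta = ds.event
    t_ev = t[delta == 1]
    if t_ev.size == 0:
        t_ev = t
    rate = max(delta.sum(), 1) / t.sum()
    logt = np.log(t_ev)
    s = float(np.std(logt))
    s = max(s, 0.05)
    med = float(np.median(t_ev))
    if family == "exponential":
        return BaselineSpec("exponential", {"lam": rate})
    if family == "weibull":
        gamma = float(np.clip((np.pi / np.sqrt(6.0)) / s, 0.2, 50.0))
        lam = np.log(2.0) / med**gamma
        return BaselineSpec("weibull", {"lam": lam, "gamma": gamma})
    if family == "gompertz":
        return BaselineSpec("gompertz", {"lam": rate / 2.0, "theta": 0.05})
    if family == "lognormal":
        return BaselineSpec("lognormal", {"mu": float(np.mean(logt)), "sigma": s})
    # log-logistic: sd(log T) = pi / (k sqrt(3)); median solves e^theta med^k = 1
    k = float(np.clip((np.pi / np.sqrt(3.0)) / s, 0.2, 50.0))
    return BaselineSpec("loglogistic", {"theta": -k * np.log(med), "k": k})


def _numerical_hessian(fun, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; fine for the smooth log-likelihoods here."""
    p = x0.size
    H = np.empty((p, p))
    f0 = fun(x0)
    steps = h * np.maximum(1.0, np.abs(x0))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = steps[i]
        H[i, i] = (fun(x0 + ei) - 2.0 * f0 + fun(x0 - ei)) / steps[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = steps[j]
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H


THETA_BOUNDARY = 1e-4  # fitted theta below this is reported as a boundary solution


def fit_ml(
    ds: SurvivalDataset,
    family: str,
    with_frailty: bool = True,
    n_starts: int = 3,
    start_seed: int = 0,
) -> MLFitResult:
    """Maximize the marginal likelihood over (baseline params, beta, theta).

    Positivity is enforced through log transforms; optimization is
    multi-start quasi-Newton (moment-based, null-model, and perturbed starts)
    and is deterministic given ``start_seed``.
    """
    if ds.event.sum() < 1:
        raise ValueError("cannot fit: no events in the dataset")
    X = ds.design
    if X.shape[1] > 0:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(ds.n), X]))
        if rank < X.shape[1] + 1:
            raise ValueError("design matrix is rank-deficient (degenerate covariates)")
    k = X.shape[1]
    names = PARAM_NAMES[family]
    nb = len(names)

    def unpack(vec: np.ndarray) -> FrailtyModelSpec:
        base = unpack_params(family, vec[:nb])
        beta = vec[nb : nb + k]
        theta = float(np.exp(vec[-1])) if with_frailty else 0.0
        return FrailtyModelSpec(base, beta, theta)

    def negloglik(vec: np.ndarray) -> float:
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                ll = marginal_loglik(unpack(vec), ds)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    base0 = pack_params(_baseline_moment_init(family, ds))
    rate = max(ds.event.sum(), 1) / ds.time.sum()
    null_base = {
        "exponential": BaselineSpec("exponential", {"lam": rate}),
        "weibull": BaselineSpec("weibull", {"lam": rate, "gamma": 1.0}),
        "gompertz": BaselineSpec("gompertz", {"lam": rate, "theta": 1e-3}),
        "lognormal": BaselineSpec(
            "lognormal",
            {"mu": float(np.mean(np.log(ds.time))), "sigma": float(np.std(np.log(ds.time)) + 0.05)},
        ),
        "loglogistic": BaselineSpec("loglogistic", {"theta": float(np.log(rate)), "k": 1.0}),
    }[family]
    rng = np.random.default_rng(start_seed)
    starts = [
        np.concatenate([base0, np.zeros(k), [np.log(0.1)] if with_frailty else []]),
        np.concatenate(
            [pack_params(null_base), np.zeros(k), [np.log(0.5)] if with_frailty else []]
        ),
    ]
    for _ in range(max(0, n_starts - 2)):
        starts.append(starts[0] + 0.3 * rng.standard_normal(starts[0].size))

    best = None
    for x0 in starts[:n_starts]:
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    spec = unpack(best.x)
    loglik = -float(best.fun)
    n_params = best.x.size
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(ds.n)

    # observed information on the unconstrained scale -> delta method
    param_labels = list(names) + list(ds.design_columns) + (
        ["theta"] if with_frailty else []
    )
    se_nat = np.full(n_params, np.nan)
    theta_boundary = bool(with_frailty and spec.theta < THETA_BOUNDARY)
    try:
        H = _numerical_hessian(negloglik, best.x)
        cov = np.linalg.inv(H)
        var_unc = np.diag(cov)
        grad_nat = np.ones(n_params)
        for i, name in enumerate(names):
            if name in POSITIVE_PARAMS:
                grad_nat[i] = spec.baseline[name]  # d(e^u)/du = value
        if with_frailty:
            grad_nat[-1] = spec.theta
        with np.errstate(invalid="ignore"):
            se_nat = np.sqrt(np.maximum(var_unc, 0.0)) * np.abs(grad_nat)
    except np.linalg.LinAlgError:
        pass
    if theta_boundary:
        se_nat[-1] = np.nan  # SE on the boundary is not meaningful

    beta_names = list(ds.design_columns)
    values = list(spec.baseline.values()) + list(spec.beta) + (
        [spec.theta] if with_frailty else []
    )
    se = pd.Series(se_nat, index=param_labels)
    return MLFitResult(
        family=family,
        with_frailty=with_frailty,
        baseline=spec.baseline,
        beta=pd.Series(spec.beta, index=beta_names),
        theta=spec.theta,
        loglik=loglik,
        n_params=n_params,
        aic=float(aic),
        bic=float(bic),
        se=se,
        converged=bool(best.success),
        theta_boundary=theta_boundary,
        n=ds.n,
        data_key=ds.data_key(),
        n_starts_used=min(n_starts, len(starts)),
    )


def compare_ml(results: list[MLFitResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (lowest first); flags the best row.

    All results must come from the same dataset.
    """
    if not results:
        raise ValueError("no results to compare")
    keys = {r.data_key for r in results}
    if len(keys) > 1:
        raise ValueError("results were fitted on different datasets")
    rows = [
        {
            "model": r.label,
            "family": r.family,
            "frailty": r.with_frailty,
            "loglik": r.loglik,
            "n_params": r.n_params,
            "AIC": r.aic,
            "BIC": r.bic,
            "converged": r.converged,
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values("AIC", kind="mergesort").reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table


def weibull_ph_to_aft(lam: float, gamma: float, beta) -> dict:
    """Convert Weibull PH parameters to the AFT parameterization.

    PH: S(t) = exp(-lam t^gamma e^{x'b});  AFT: log T = mu + x'a + sigma*W with
    W standard Gumbel(min).  Then sigma = 1/gamma, mu = -log(lam)/gamma and
    the AFT coefficients are a = -beta / gamma.
    """
    beta = np.asarray(beta, dtype=float)
    return {
        "sigma": 1.0 / gamma,
        "intercept": -np.log(lam) / gamma,
        "coefficients": -beta / gamma,
    }
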