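"""Parametric baseline hazard families.

Five families are supported: exponential, Gompertz, Weibull, log-normal and
log-logistic.  Everything is parameterized on the *hazard scale*:

* exponential  h(t) = lam
* Gompertz     h(t) = lam * exp(theta * t)
* Weibull      h(t) = lam * gamma * t**(gamma - 1),  S(t) = exp(-lam * t**gamma)
* log-normal   h(t) = f(t) / S(t),  S(t) = 1 - Phi((log t - mu) / sigma)
* log-logistic S(t) = 1 / (1 + exp(theta) * t**k)

Note the Weibull ``lam`` multiplies ``t**gamma`` directly (it is *not* the
``(t/scale)**shape`` convention used by e.g. scipy's ``weibull_min``); a
conversion is the caller's job.  All likelihood-facing quantities are computed
in log space so that large times and extreme shapes do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "BaselineSpec",
    "log_hazard",
    "hazard",
    "log_survival",
    "survival",
    "cumulative_hazard",
    "inverse_cumulative_hazard",
    "log_pdf",
    "pdf",
    "sample",
    "pack_params",
    "unpack_params",
]

FAMILIES = ("exponential", "gompertz", "weibull", "lognormal", "loglogistic")

#: ordered parameter names per family
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("lam",),
    "gompertz": ("lam", "theta"),
    "weibull": ("lam", "gamma"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("theta", "k"),
}

#: parameters constrained to be strictly positive (the rest are real-valued)
POSITIVE_PARAMS = frozenset({"lam", "gamma", "sigma", "k"})


@dataclass(frozen=True)
class BaselineSpec:
    """A baseline family tag plus its parameter values.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Mapping from parameter name to value; the required names are given by
        ``PARAM_NAMES[family]``.  Scale/shape parameters (``lam``, ``gamma``,
        ``sigma``, ``k``) must be strictly positive.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown baseline family {self.family!r}; expected one of {FAMILIES}"
            )
        names = PARAM_NAMES[self.family]
        got = tuple(self.params)
        if set(got) != set(names):
            raise ValueError(
                f"{self.family} baseline requires parameters {names}, got {got}"
            )
        for name in names:
            value = float(self.params[name])
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value}")
            if name in POSITIVE_PARAMS and value <= 0.0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value}")

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])

    def values(self) -> np.ndarray:
        """Parameter values in the family's canonical order."""
        return np.array([self[p] for p in PARAM_NAMES[self.family]], dtype=float)

    @classmethod
    def from_values(cls, family: str, values) -> "BaselineSpec":
        names = PARAM_NAMES[family]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(names),):
            raise ValueError(f"{family} expects {len(names)} parameters")
        return cls(family, dict(zip(names, values)))


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0) or np.any(~np.isfinite(t)):
        raise ValueError("time must be strictly positive and finite")
    return t


def log_hazard(spec: BaselineSpec, t) -> np.ndarray:
    """log h0(t); vectorized over ``t`` (t > 0)."""
    t = _check_time(t)
    f, p = spec.family, spec.params
    if f == "exponential":
        return np.full_like(t, np.log(p["lam"]))
    if f == "gompertz":
        return np.log(p["lam"]) + p["theta"] * t
    if f == "weibull":
        return np.log(p["lam"]) + np.log(p["gamma"]) + (p["gamma"] - 1.0) * np.log(t)
    if f == "lognormal":
        z = (np.log(t) - p["mu"]) / p["sigma"]
        log_f = stats.norm.logpdf(z) - np.log(p["sigma"]) - np.log(t)
        return log_f - stats.norm.logsf(z)
    # log-logistic: h = e^theta k t^(k-1) / (1 + e^theta t^k)
    logt = np.log(t)
    return (
        p["theta"]
        + np.log(p["k"])
        + (p["k"] - 1.0) * logt
        - np.logaddexp(0.0, p["theta"] + p["k"] * logt)
    )


def hazard(spec: BaselineSpec, t) -> np.ndarray:
    return np.exp(log_hazard(spec, t))


def log_survival(spec: BaselineSpec, t) -> np.ndarray:
    """log S0(t); vectorized over ``t`` (t > 0)."""
    t = _check_time(t)
    f, p = spec.family, spec.params
    if f == "exponential":
        return -p["lam"] * t
    if f == "gompertz":
        theta = p["theta"]
        if theta == 0.0:  # exponential limit, avoids 0/0
            return -p["lam"] * t
        return -(p["lam"] / theta) * np.expm1(theta * t)
    if f == "weibull":
        return -p["lam"] * np.exp(p["gamma"] * np.log(t))
    if f == "lognormal":
        return stats.norm.logsf((np.log(t) - p["mu"]) / p["sigma"])
    return -np.logaddexp(0.0, p["theta"] + p["k"] * np.log(t))


def survival(spec: BaselineSpec, t) -> np.ndarray:
    return np.exp(log_survival(spec, t))


def cumulative_hazard(spec: BaselineSpec, t) -> np.ndarray:
    """H0(t) = -log S0(t) = integral of the hazard over (0, t]."""
    return -log_survival(spec, t)


def inverse_cumulative_hazard(spec: BaselineSpec, u) -> np.ndarray:
    """Solve H0(t) = u for t (u >= 0).  Closed form for every family.

    Raises
    ------
    ValueError
        If some ``u`` exceeds the total integrated hazard (possible only for
        a defective Gompertz with negative shape).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0):
        raise ValueError("cumulative hazard values must be >= 0")
    f, p = spec.family, spec.params
    if f == "exponential":
        return u / p["lam"]
    if f == "gompertz":
        theta = p["theta"]
        if theta == 0.0:
            return u / p["lam"]
        arg = theta * u / p["lam"]
        if np.any(arg <= -1.0):
            raise ValueError(
                "Gompertz with negative shape is defective: requested cumulative "
                "hazard exceeds the total integrated hazard"
            )
        return np.log1p(arg) / theta
    with np.errstate(divide="ignore"):
        logu = np.log(u)
    if f == "weibull":
        return np.exp((logu - np.log(p["lam"])) / p["gamma"])
    if f == "lognormal":
        # S(t) = exp(-u)  =>  t = exp(mu + sigma * Phi^{-1}(1 - e^{-u}))
        with np.errstate(over="ignore"):
            q = stats.norm.isf(np.exp(-u))
        return np.where(u == 0.0, 0.0, np.exp(p["mu"] + p["sigma"] * q))
    # log-logistic: e^theta t^k = e^u - 1
    with np.errstate(divide="ignore"):
        t = np.exp((np.log(np.expm1(u)) - p["theta"]) / p["k"])
    return np.where(u == 0.0, 0.0, t)


def log_pdf(spec: BaselineSpec, t) -> np.ndarray:
    """log f0(t) = log h0(t) + log S0(t)."""
    return log_hazard(spec, t) + log_survival(spec, t)


def pdf(spec: BaselineSpec, t) -> np.ndarray:
    return np.exp(log_pdf(spec, t))


def sample(spec: BaselineSpec, n: int, rng) -> np.ndarray:
    """Draw ``n`` event times by inversion of the survival function.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed; identical
    seeds give identical draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    e = rng.exponential(size=int(n))  # -log U, U ~ Uniform(0,1)
    return inverse_cumulative_hazard(spec, e)


def rescale_time(spec: BaselineSpec, c: float) -> BaselineSpec:
    """Parameters of the same family on the rescaled time axis t' = t / c.

    Returns the spec' with S'(t') = S(c t'); every family is closed under
    time scaling.  ``rescale_time(spec', 1/c)`` inverts the map.
    """
    if c <= 0:
        raise ValueError("time scale must be > 0")
    f, p = spec.family, spec.params
    if f == "exponential":
        return BaselineSpec(f, {"lam": p["lam"] * c})
    if f == "weibull":
        return BaselineSpec(f, {"lam": p["lam"] * c ** p["gamma"], "gamma": p["gamma"]})
    if f == "gompertz":
        return BaselineSpec(f, {"lam": p["lam"] * c, "theta": p["theta"] * c})
    if f == "lognormal":
        return BaselineSpec(f, {"mu": p["mu"] - np.log(c), "sigma": p["sigma"]})
    return BaselineSpec(f, {"theta": p["theta"] + p["k"] * np.log(c), "k": p["k"]})


# -- unconstrained-parameter transforms (used by the ML and MCMC fitters) ----

def pack_params(spec: BaselineSpec) -> np.ndarray:
    """Map a spec's parameters to an unconstrained real vector (log of positives)."""
    out = []
    for name in PARAM_NAMES[spec.family]:
        v = spec[name]
        out.append(np.log(v) if name in POSITIVE_PARAMS else v)
    return np.array(out, dtype=float)


def unpack_params(family: str, vec) -> BaselineSpec:
    """Inverse of :func:`pack_params`."""
    names = PARAM_NAMES[family]
    vec = np.asarray(vec, dtype=float)
    params = {
        name: float(np.exp(v)) if name in POSITIVE_PARAMS else float(v)
        for name, v in zip(names, vec)
    }
    return BaselineSpec(family, params)
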