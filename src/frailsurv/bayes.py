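"""Bayesian estimation of the gamma shared-frailty model.

Sampler: Metropolis-within-Gibbs with frailty data augmentation.  The cluster
frailties have a conjugate full conditional,

    z_i | rest  ~  Gamma(shape 1/theta + d_i,  rate 1/theta + A_i),

with d_i the cluster's event count and A_i = sum_j H0(t_ij) exp(x_ij' beta);
they are drawn exactly (Gibbs).  The remaining parameters move in three
adaptive random-walk Metropolis blocks — beta jointly, the baseline
parameters jointly, and log theta — on unconstrained transforms (log for
positive parameters, with the Jacobian in the acceptance ratio).  Proposal
scales and covariances adapt only during burn-in, so the post-burn-in kernel
is a fixed, valid Metropolis kernel targeting 25-40% acceptance.

Priors: N(0, 1e5) on each regression coefficient, Gamma(shape 1, rate 0.001)
on positive baseline parameters (mean 1000), N(0, 1e5) on real-valued baseline
parameters, and Gamma(0.001, rate 0.001) on the frailty precision 1/theta.

Outputs: posterior summaries (mean, SD, batch-means MC error, median,
equal-tailed 95% interval, significance flag), DIC with the deviance based on
the frailty-integrated marginal likelihood (so frailty and no-frailty models
are comparable; a conditional-focus variant is available), the
Brooks-Gelman-Rubin potential-scale-reduction diagnostic over iteration
windows, and trace/density/BGR plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .baselines import (
    PARAM_NAMES,
    POSITIVE_PARAMS,
    BaselineSpec,
    cumulative_hazard,
    log_hazard,
    pack_params,
    rescale_time,
    unpack_params,
)
from .dataset import SurvivalDataset
from .frailty import (
    FrailtyModelSpec,
    complete_data_loglik,
    frailty_log_density,
    marginal_loglik,
)

__all__ = [
    "PriorSpec",
    "log_posterior",
    "frailty_conditional",
    "gibbs_update_frailties",
    "AdaptiveRandomWalk",
    "metropolis_step",
    "PosteriorChain",
    "McmcResult",
    "run_mcmc",
    "summarize_posterior",
    "mc_error_ok",
    "DICReport",
    "compute_dic",
    "bgr_statistic",
    "bgr_diagnostic",
    "convergence_plots",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the noninformative priors."""

    beta_variance: float = 1e5
    location_variance: float = 1e5  # real-valued baseline parameters
    baseline_shape: float = 1.0
    baseline_rate: float = 0.001
    frailty_precision_shape: float = 0.001
    frailty_precision_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in (
            "beta_variance",
            "location_variance",
            "baseline_shape",
            "baseline_rate",
            "frailty_precision_shape",
            "frailty_precision_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # -- log prior densities (up to nothing: normalization constants kept) --
    def log_prior_beta(self, beta: np.ndarray) -> float:
        return float(
            np.sum(stats.norm.logpdf(beta, scale=np.sqrt(self.beta_variance)))
        )

    def log_prior_baseline(self, spec: BaselineSpec) -> float:
        total = 0.0
        for name in PARAM_NAMES[spec.family]:
            v = spec[name]
            if name in POSITIVE_PARAMS:
                a, b = self.baseline_shape, self.baseline_rate
                total += a * np.log(b) - special.gammaln(a) + (a - 1.0) * np.log(v) - b * v
            else:
                total += stats.norm.logpdf(v, scale=np.sqrt(self.location_variance))
        return float(total)

    def log_prior_theta(self, theta: float) -> float:
        """Induced density on theta of Gamma(a, rate b) on the precision 1/theta."""
        if theta <= 0:
            return -np.inf
        a, b = self.frailty_precision_shape, self.frailty_precision_rate
        return float(
            a * np.log(b) - special.gammaln(a) - (a + 1.0) * np.log(theta) - b / theta
        )


def log_posterior(
    spec: FrailtyModelSpec,
    frailties,
    ds: SurvivalDataset,
    priors: PriorSpec,
) -> float:
    """Complete-data log-posterior (up to an additive constant).

    complete-data log-likelihood + frailty log-densities + log-priors.
    Constraint violations return ``-inf`` (a rejected state), not an exception.
    """
    z = np.asarray(frailties, dtype=float)
    if spec.theta <= 0.0 or np.any(z <= 0.0):
        return -np.inf
    try:
        ll = complete_data_loglik(spec, ds, z)
    except ValueError:
        return -np.inf
    lp = (
        ll
        + float(frailty_log_density(z, spec.theta).sum())
        + priors.log_prior_beta(spec.beta)
        + priors.log_prior_baseline(spec.baseline)
        + priors.log_prior_theta(spec.theta)
    )
    return lp if np.isfinite(lp) else -np.inf


def frailty_conditional(theta: float, d, A):
    """(shape, rate) of the exact frailty full conditional per cluster.

    A cluster with no subjects (d = A = 0) reduces to the Gamma(1/theta,
    1/theta) prior.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    a = 1.0 / theta
    return a + np.asarray(d, dtype=float), a + np.asarray(A, dtype=float)


def gibbs_update_frailties(
    spec: FrailtyModelSpec, ds: SurvivalDataset, rng: np.random.Generator
) -> np.ndarray:
    """Exact Gibbs draw of all cluster frailties given the other parameters."""
    eta = ds.design @ spec.beta
    H0 = cumulative_hazard(spec.baseline, ds.time)
    A = np.bincount(ds.cluster_index, weights=H0 * np.exp(eta), minlength=ds.r)
    shape, rate = frailty_conditional(spec.theta, ds.cluster_events, A)
    return rng.gamma(shape, 1.0 / rate)


# ---------------------------------------------------------------------------
# adaptive random-walk machinery
# ---------------------------------------------------------------------------


class AdaptiveRandomWalk:
    """Random-walk proposal with Robbins-Monro scale and empirical-covariance
    shape adaptation (adaptation is switched off after burn-in)."""

    def __init__(
        self,
        dim: int,
        scale: float = 0.1,
        target: float = 0.3,
        chol: np.ndarray | None = None,
    ):
        self.dim = dim
        self.log_scale = float(np.log(scale))
        self.target = target
        self._count = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim))
        self._chol: np.ndarray | None = chol
        self.accepted = 0
        self.proposed = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def step(self, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(self.dim)
        if self._chol is not None:
            eps = self._chol @ eps
        return self.scale * eps

    def record(self, accepted: bool) -> None:
        self.proposed += 1
        self.accepted += int(accepted)

    def adapt(self, x: np.ndarray, accepted: bool, rate: float = 0.05) -> None:
        """Call only during burn-in."""
        self.log_scale += rate * ((1.0 if accepted else 0.0) - self.target)
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.outer(delta, x - self._mean)
        if self.dim > 1 and self._count >= 20 * self.dim and self._count % 100 == 0:
            cov = self._m2 / (self._count - 1)
            cov += 1e-9 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else np.nan

    def reset_counters(self) -> None:
        self.accepted = 0
        self.proposed = 0


def metropolis_step(x, log_target, block: AdaptiveRandomWalk, rng, adapting=False):
    """One random-walk Metropolis update; returns (new_x, new_lp, accepted).

    ``log_target`` is evaluated on the unconstrained scale and must include
    any Jacobian terms.  A zero proposal scale degenerates to always accepting
    the unchanged state.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lp_cur = log_target(x)
    prop = x + block.step(rng)
    lp_prop = log_target(prop)
    log_ratio = lp_prop - lp_cur
    accepted = bool(np.log(rng.uniform()) < log_ratio) if np.isfinite(lp_prop) else False
    block.record(accepted)
    if adapting:
        block.adapt(x, accepted)
    if accepted:
        return prop, lp_prop, True
    return x, lp_cur, False


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class GibbsSampler:
    """Holds the dataset-derived arrays and block target densities."""

    def __init__(
        self,
        ds: SurvivalDataset,
        family: str,
        priors: PriorSpec,
        with_frailty: bool = True,
        prior_time_scale: float = 1.0,
    ):
        # ``prior_time_scale`` = c means ``ds`` carries times already divided
        # by c; priors are always evaluated on the original-time-scale
        # parameters (the likelihood is invariant up to constants).
        self.ds = ds
        self.c = float(prior_time_scale)
        self.family = family
        self.priors = priors
        self.with_frailty = with_frailty
        self.t = ds.time
        self.delta = ds.event.astype(float)
        self.X = ds.design
        self.cl = ds.cluster_index
        self.r = ds.r
        self.d = ds.cluster_events.astype(float)
        self.k = self.X.shape[1]
        self.nb = len(PARAM_NAMES[family])

    # cached hazard pieces for a baseline vector
    def baseline_pieces(self, bvec: np.ndarray):
        spec = unpack_params(self.family, bvec)
        return log_hazard(spec, self.t), cumulative_hazard(spec, self.t)

    def log_target_beta(self, beta, z, H0):
        eta = self.X @ beta
        with np.errstate(over="ignore"):
            risk = np.sum(z[self.cl] * H0 * np.exp(eta))
        if not np.isfinite(risk):
            return -np.inf
        return (
            float(self.delta @ eta) - float(risk) + self.priors.log_prior_beta(beta)
        )

    def original_scale_spec(self, bvec) -> BaselineSpec:
        return rescale_time(unpack_params(self.family, bvec), 1.0 / self.c)

    def log_target_baseline(self, bvec, z, exp_eta):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                lh0, H0 = self.baseline_pieces(bvec)
                risk = np.sum(z[self.cl] * exp_eta * H0)
        except (ValueError, FloatingPointError):
            return -np.inf
        if not (np.all(np.isfinite(H0)) and np.isfinite(risk)):
            return -np.inf
        spec_orig = self.original_scale_spec(bvec)
        # Jacobian of unconstrained(scaled) -> natural(original): the time
        # rescaling is unit-triangular on the unconstrained scale, leaving
        # only the log transforms of the positive original parameters.
        jac = sum(
            np.log(spec_orig[name])
            for name in PARAM_NAMES[self.family]
            if name in POSITIVE_PARAMS
        )
        return (
            float(self.delta @ lh0)
            - float(risk)
            + self.priors.log_prior_baseline(spec_orig)
            + float(jac)
        )

    def log_target_log_theta(self, lt, z):
        lt = float(lt)
        if lt > 50.0 or lt < -50.0:
            return -np.inf
        theta = np.exp(lt)
        a = 1.0 / theta
        dens = (
            self.r * (a * np.log(a) - special.gammaln(a))
            + (a - 1.0) * float(np.sum(np.log(z)))
            - a * float(np.sum(z))
        )
        return dens + self.priors.log_prior_theta(theta) + lt  # + Jacobian

    def draw_frailties(self, rng, theta, H0, exp_eta):
        A = np.bincount(self.cl, weights=H0 * exp_eta, minlength=self.r)
        shape, rate = frailty_conditional(theta, self.d, A)
        return rng.gamma(shape, 1.0 / rate)

    def complete_log_posterior(self, bvec, beta, theta, z, lh0, H0, eta):
        """Cheap assembly of the stored log-posterior trace from cached pieces."""
        ll = float(
            np.sum(self.delta * (np.log(z[self.cl]) + lh0 + eta))
            - np.sum(z[self.cl] * H0 * np.exp(eta))
        )
        lp = ll + self.priors.log_prior_beta(beta) + self.priors.log_prior_baseline(
            self.original_scale_spec(bvec)
        )
        if self.with_frailty:
            lp += float(frailty_log_density(z, theta).sum())
            lp += self.priors.log_prior_theta(theta)
        return lp


@dataclass
class PosteriorChain:
    """Stored draws for one chain (post burn-in, thinned)."""

    draws: np.ndarray  # (n_stored, n_params), natural scale
    names: list[str]
    log_post: np.ndarray
    acceptance: dict[str, float]
    frailties: np.ndarray | None = None  # (n_stored, r) if stored

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.names)


@dataclass
class McmcResult:
    chains: list[PosteriorChain]
    family: str
    with_frailty: bool
    seed: int
    n_iter: int
    burn_in: int
    thin: int
    cluster_labels: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return self.chains[0].names

    def stacked(self) -> np.ndarray:
        return np.vstack([c.draws for c in self.chains])

    def param(self, name: str) -> np.ndarray:
        """(n_chains, n_stored) matrix for one parameter."""
        j = self.names.index(name)
        return np.stack([c.draws[:, j] for c in self.chains])

    @property
    def n_stored(self) -> int:
        return self.chains[0].draws.shape[0]


def run_mcmc(
    ds: SurvivalDataset,
    family: str,
    priors: PriorSpec | None = None,
    n_iter: int = 21_000,
    burn_in: int = 1_000,
    n_chains: int = 2,
    thin: int = 1,
    seed: int = 0,
    with_frailty: bool = True,
    init: FrailtyModelSpec | None = None,
    store_frailties: bool = True,
    progress: "callable | None" = None,
) -> McmcResult:
    """Metropolis-within-Gibbs sampling of the posterior.

    ``n_iter`` counts total iterations per chain including the ``burn_in``
    (must exceed it); ``(n_iter - burn_in) // thin`` draws are stored per
    chain.  Chains start from an ML fit (or ``init``) with chain-specific
    overdispersed perturbations and are bitwise reproducible given ``seed``.
    """
    if priors is None:
        priors = PriorSpec()
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    # Sample internally on geometric-mean-scaled time: every family is closed
    # under time scaling, and the rescaling removes most of the scale/shape
    # posterior correlation (the lam-gamma ridge) that cripples random-walk
    # mixing.  Draws are mapped back to the original scale before storage.
    c_time = float(np.exp(np.mean(np.log(ds.time))))
    scaled_frame = ds.frame.copy()
    scaled_frame["time"] = scaled_frame["time"] / c_time
    ds_scaled = SurvivalDataset(scaled_frame, ds.codebook)
    sampler = GibbsSampler(
        ds_scaled, family, priors, with_frailty, prior_time_scale=c_time
    )
    if init is None:
        from .frailty import fit_ml

        ml = fit_ml(ds, family, with_frailty=with_frailty, n_starts=1)
        init = ml.spec
    base_bvec = pack_params(rescale_time(init.baseline, c_time))
    base_beta = np.asarray(init.beta, dtype=float)
    base_lt = float(np.log(max(init.theta, 0.05))) if with_frailty else 0.0

    # Seed the block proposals with the curvature of the marginal likelihood
    # at the starting point; the lam-gamma ridge of several baselines makes
    # identity proposals mix very slowly otherwise.  Adaptation refines this
    # during burn-in.
    chol_beta = chol_base = None
    try:
        from .frailty import _numerical_hessian

        nb = len(PARAM_NAMES[family])

        def _negll(vec):
            try:
                base = unpack_params(family, vec[:nb])
                theta = float(np.exp(vec[-1])) if with_frailty else 0.0
                spec = FrailtyModelSpec(base, vec[nb : nb + base_beta.size], theta)
                with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                    ll = marginal_loglik(spec, ds_scaled)
                return -ll if np.isfinite(ll) else 1e12
            except (ValueError, FloatingPointError):
                return 1e12

        x0 = np.concatenate([base_bvec, base_beta, [base_lt]] if with_frailty
                            else [base_bvec, base_beta])
        H = _numerical_hessian(_negll, x0)
        cov = np.linalg.inv(H + 1e-8 * np.eye(H.shape[0]))
        cov = (cov + cov.T) / 2.0
        # guard against a non-PD Hessian away from the optimum
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 1e-10, None)
        cov = V @ np.diag(w) @ V.T
        if base_beta.size:
            chol_beta = np.linalg.cholesky(
                cov[nb : nb + base_beta.size, nb : nb + base_beta.size]
                + 1e-12 * np.eye(base_beta.size)
            )
        chol_base = np.linalg.cholesky(cov[:nb, :nb] + 1e-12 * np.eye(nb))
    except np.linalg.LinAlgError:
        pass

    names = (
        list(PARAM_NAMES[family])
        + list(ds.design_columns)
        + (["theta"] if with_frailty else [])
    )
    n_stored = (n_iter - burn_in) // thin
    chains: list[PosteriorChain] = []
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chain]))
        # overdispersed starts: ML point +/- chain-scaled perturbation
        pert = 0.05 * (1 + chain)
        bvec = base_bvec + pert * rng.standard_normal(base_bvec.size)
        beta = base_beta + pert * rng.standard_normal(base_beta.size)
        lt = base_lt + pert * rng.standard_normal()
        z = np.ones(sampler.r)

        # beta moves in sub-blocks of <= 4 coefficients (a 13-dim joint
        # random walk mixes too slowly to meet the MC-error rule at the
        # default run length); low-dimensional blocks target a higher
        # acceptance rate
        beta_groups = [
            list(range(i, min(i + 4, sampler.k))) for i in range(0, sampler.k, 4)
        ]
        blocks = {
            "baseline": AdaptiveRandomWalk(
                sampler.nb,
                scale=2.38 / np.sqrt(sampler.nb) if chol_base is not None else 0.02,
                target=0.4,
                chol=None if chol_base is None else chol_base.copy(),
            ),
        }
        for gi, idx in enumerate(beta_groups):
            sub_chol = None
            if chol_beta is not None:
                cov_b = chol_beta @ chol_beta.T
                sub = cov_b[np.ix_(idx, idx)] + 1e-12 * np.eye(len(idx))
                try:
                    sub_chol = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    sub_chol = None
            blocks[f"beta{gi}"] = AdaptiveRandomWalk(
                len(idx),
                scale=2.38 / np.sqrt(len(idx)) if sub_chol is not None else 0.02,
                target=0.35,
                chol=sub_chol,
            )
        if with_frailty:
            blocks["theta"] = AdaptiveRandomWalk(1, scale=0.1, target=0.44)

        lh0, H0 = sampler.baseline_pieces(bvec)
        eta = sampler.X @ beta if sampler.k else np.zeros(ds.n)

        draws = np.empty((n_stored, len(names)))
        lp_trace = np.empty(n_stored)
        zs = np.empty((n_stored, sampler.r)) if store_frailties else None
        stored = 0
        for it in range(n_iter):
            adapting = it < burn_in
            if adapting and it == burn_in - 1:
                for b in blocks.values():
                    b.reset_counters()
            if with_frailty:
                theta = float(np.exp(lt))
                z = sampler.draw_frailties(rng, theta, H0, np.exp(eta))
            # beta sub-blocks
            if sampler.k:
                for gi, idx in enumerate(beta_groups):

                    def sub_target(v, idx=idx):
                        b2 = beta.copy()
                        b2[idx] = v
                        return sampler.log_target_beta(b2, z, H0)

                    new_sub, _, _ = metropolis_step(
                        beta[idx], sub_target, blocks[f"beta{gi}"], rng, adapting
                    )
                    beta = beta.copy()
                    beta[idx] = new_sub
                eta = sampler.X @ beta
            # baseline block
            exp_eta = np.exp(eta)
            bvec, _, _ = metropolis_step(
                bvec,
                lambda bv: sampler.log_target_baseline(bv, z, exp_eta),
                blocks["baseline"],
                rng,
                adapting,
            )
            lh0, H0 = sampler.baseline_pieces(bvec)
            # theta block
            if with_frailty:
                lt_arr, _, _ = metropolis_step(
                    np.array([lt]),
                    lambda v: sampler.log_target_log_theta(v[0], z),
                    blocks["theta"],
                    rng,
                    adapting,
                )
                lt = float(lt_arr[0])
            if it >= burn_in and (it - burn_in) % thin == 0 and stored < n_stored:
                spec_b = sampler.original_scale_spec(bvec)
                row = list(spec_b.values()) + list(beta)
                if with_frailty:
                    row.append(float(np.exp(lt)))
                draws[stored] = row
                lp_trace[stored] = sampler.complete_log_posterior(
                    bvec, beta, float(np.exp(lt)) if with_frailty else 0.0,
                    z, lh0, H0, eta,
                )
                if zs is not None:
                    zs[stored] = z
                stored += 1
            if progress is not None and (it + 1) % 1000 == 0:
                progress(chain, it + 1)
        chains.append(
            PosteriorChain(
                draws=draws,
                names=names,
                log_post=lp_trace,
                acceptance={k: b.acceptance_rate for k, b in blocks.items()},
                frailties=zs,
            )
        )
    return McmcResult(
        chains=chains,
        family=family,
        with_frailty=with_frailty,
        seed=seed,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        cluster_labels=ds.cluster_labels,
    )


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics
# ---------------------------------------------------------------------------


def _batch_means_se(per_chain: list[np.ndarray], n_batches: int = 50) -> float:
    """Monte-Carlo standard error of the pooled mean via batch means."""
    means = []
    for x in per_chain:
        nb = min(n_batches, max(1, x.size // 2))
        blen = x.size // nb
        if blen == 0:
            continue
        trimmed = x[x.size - nb * blen :]
        means.extend(trimmed.reshape(nb, blen).mean(axis=1))
    means = np.asarray(means)
    if means.size < 2:
        return 0.0
    return float(np.std(means, ddof=1) / np.sqrt(means.size))


def summarize_posterior(result: McmcResult, params: list[str] | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, SD, MC error, median, 95% interval.

    ``significant`` flags rows whose equal-tailed 95% interval excludes 0.
    """
    if result.n_stored == 0:
        raise ValueError("no stored draws to summarize")
    names = params if params is not None else result.names
    rows = []
    start = result.burn_in + 1
    for name in names:
        per_chain = [c.draws[:, result.names.index(name)] for c in result.chains]
        x = np.concatenate(per_chain)
        lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "mc_error": _batch_means_se(per_chain),
                "median": float(med),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "start": start,
                "sample": int(x.size),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def mc_error_ok(summary: pd.DataFrame, fraction: float = 0.05) -> pd.Series:
    """The 5%-of-SD Monte-Carlo-error convergence rule, per parameter."""
    sd = summary["sd"]
    ok = summary["mc_error"] < fraction * sd
    ok[sd == 0] = summary["mc_error"][sd == 0] == 0
    return ok


@dataclass(frozen=True)
class DICReport:
    """Deviance information criterion decomposition.

    dbar: posterior mean deviance; dhat: deviance at the posterior means;
    p_d = dbar - dhat (effective parameters); dic = dbar + p_d.
    """

    dbar: float
    dhat: float

    @property
    def p_d(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.p_d


def _row_spec(result: McmcResult, row: np.ndarray) -> FrailtyModelSpec:
    nb = len(PARAM_NAMES[result.family])
    base = BaselineSpec.from_values(result.family, row[:nb])
    if result.with_frailty:
        return FrailtyModelSpec(base, row[nb:-1], float(row[-1]))
    return FrailtyModelSpec(base, row[nb:], 0.0)


def compute_dic(
    result: McmcResult,
    ds: SurvivalDataset,
    focus: str = "marginal",
    max_draws: int = 500,
) -> DICReport:
    """DIC from the stored chains.

    ``focus='marginal'`` (default) evaluates the deviance on the
    frailty-integrated likelihood, making frailty and no-frailty models
    directly comparable; ``focus='conditional'`` conditions on the sampled
    frailties.
    """
    if focus not in ("marginal", "conditional"):
        raise ValueError("focus must be 'marginal' or 'conditional'")
    all_draws = result.stacked()
    step = max(1, all_draws.shape[0] // max_draws)
    sub = all_draws[::step]
    if focus == "conditional" and result.with_frailty:
        if any(c.frailties is None for c in result.chains):
            raise ValueError("conditional DIC requires stored frailty draws")
        zs = np.vstack([c.frailties for c in result.chains])
        z_sub = zs[::step]
        devs = [
            -2.0 * complete_data_loglik(_row_spec(result, row), ds, z)
            for row, z in zip(sub, z_sub)
        ]
        mean_spec = _row_spec(result, all_draws.mean(axis=0))
        dhat = -2.0 * complete_data_loglik(mean_spec, ds, zs.mean(axis=0))
    else:
        devs = [-2.0 * marginal_loglik(_row_spec(result, row), ds) for row in sub]
        mean_spec = _row_spec(result, all_draws.mean(axis=0))
        dhat = -2.0 * marginal_loglik(mean_spec, ds)
    return DICReport(dbar=float(np.mean(devs)), dhat=float(dhat))


def bgr_statistic(chains: np.ndarray) -> float:
    """Potential scale reduction factor for an (m_chains, n_draws) matrix.

    Classic between/within formulation; values below 1 arise only from the
    (n-1)/n finite-sample factor and are reported as exactly 1.0 (so
    duplicated chains give 1.0).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least two draws per chain")
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)  # B/n
    if within == 0.0:
        return 1.0 if between_over_n == 0.0 else np.inf
    var_hat = (n - 1) / n * within + (1.0 + 1.0 / m) * between_over_n
    return float(max(np.sqrt(var_hat / within), 1.0))


def bgr_diagnostic(
    result_or_chains, parameter: str | None = None, n_windows: int = 20
) -> pd.DataFrame:
    """BGR statistic over growing iteration windows (for convergence plots).

    Each window uses the second half of the first ``t`` draws.  Returns a
    DataFrame with columns ``iteration`` and ``bgr``; the last row is the
    full-chain value.
    """
    if isinstance(result_or_chains, McmcResult):
        if parameter is None:
            raise ValueError("parameter name required with an McmcResult")
        chains = result_or_chains.param(parameter)
    else:
        chains = np.asarray(result_or_chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains")
    n = chains.shape[1]
    ends = np.unique(np.linspace(max(4, n // n_windows), n, n_windows).astype(int))
    rows = [
        {"iteration": int(t), "bgr": bgr_statistic(chains[:, t // 2 : t])}
        for t in ends
    ]
    return pd.DataFrame(rows)


def convergence_plots(
    result: McmcResult, outdir, params: list[str] | None = None
) -> list[str]:
    """Write one history/density/BGR panel per monitored parameter (PNG).

    Filenames are deterministic: ``diag_<sanitized parameter>.png``.
    """
    import re
    from pathlib import Path

    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = params if params is not None else result.names
    paths = []
    multi = len(result.chains) >= 2
    for name in names:
        fig = Figure(figsize=(9, 3))
        FigureCanvasAgg(fig)
        axes = fig.subplots(1, 3 if multi else 2)
        ax_tr, ax_de = axes[0], axes[1]
        samples = []
        for c, chain in enumerate(result.chains):
            x = chain.draws[:, result.names.index(name)]
            samples.append(x)
            ax_tr.plot(np.arange(x.size) + result.burn_in + 1, x, lw=0.4, label=f"chain {c+1}")
        ax_tr.set_title(f"history: {name}", fontsize=8)
        pooled = np.concatenate(samples)
        lo, hi = pooled.min(), pooled.max()
        if hi > lo:
            grid = np.linspace(lo, hi, 200)
            for x in samples:
                if np.std(x) > 0:
                    ax_de.plot(grid, stats.gaussian_kde(x)(grid), lw=0.8)
            ax_de.set_xlim(lo, hi)
        ax_de.set_title(f"density: {name}", fontsize=8)
        if multi:
            series = bgr_diagnostic(result, name)
            axes[2].plot(series["iteration"], series["bgr"])
            axes[2].axhline(1.0, color="grey", lw=0.5)
            axes[2].set_title(f"BGR: {name}", fontsize=8)
        fig.tight_layout()
        fname = "diag_" + re.sub(r"[^A-Za-z0-9_.-]+", "_", name) + ".png"
        path = outdir / fname
        fig.savefig(path, dpi=100)
        paths.append(str(path))
    return paths
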