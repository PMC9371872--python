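import numpy as np
import pytest
from scipy import stats

from frailsurv.baselines import BaselineSpec
from frailsurv.bayes import (
    AdaptiveRandomWalk,
    DICReport,
    McmcResult,
    PosteriorChain,
    PriorSpec,
    bgr_diagnostic,
    bgr_statistic,
    compute_dic,
    convergence_plots,
    frailty_conditional,
    gibbs_update_frailties,
    log_posterior,
    mc_error_ok,
    metropolis_step,
    run_mcmc,
    summarize_posterior,
)
from frailsurv.frailty import (
    FrailtyModelSpec,
    complete_data_loglik,
    frailty_log_density,
)
from frailsurv.simulate import ScenarioSpec, generate

from conftest import make_dataset, random_small_dataset

WEIBULL = BaselineSpec("weibull", {"lam": 1.0, "gamma": 2.0})


class TestLogPosterior:
    def test_component_sum_oracle(self):
        rng = np.random.default_rng(3)
        ds = random_small_dataset(rng, n=20)
        spec = FrailtyModelSpec(WEIBULL, np.array([0.4]), 0.7)
        z = rng.gamma(2.0, 0.5, ds.r)
        priors = PriorSpec()
        expected = (
            complete_data_loglik(spec, ds, z)
            + frailty_log_density(z, 0.7).sum()
            + stats.norm.logpdf(0.4, scale=np.sqrt(1e5))
            + stats.gamma.logpdf(1.0, 1.0, scale=1 / 0.001)
            + stats.gamma.logpdf(2.0, 1.0, scale=1 / 0.001)
            + stats.gamma.logpdf(1 / 0.7, 0.001, scale=1 / 0.001)
            - 2 * np.log(0.7)  # Jacobian of precision -> variance
        )
        assert log_posterior(spec, z, ds, priors) == pytest.approx(expected, abs=1e-10)

    def test_flat_prior_limit_differences_equal_loglik_differences(self):
        rng = np.random.default_rng(4)
        ds = random_small_dataset(rng, n=20)
        priors = PriorSpec(beta_variance=1e12)
        z = np.ones(ds.r)
        s1 = FrailtyModelSpec(WEIBULL, np.array([0.2]), 0.7)
        s2 = FrailtyModelSpec(WEIBULL, np.array([0.9]), 0.7)
        lhs = log_posterior(s1, z, ds, priors) - log_posterior(s2, z, ds, priors)
        rhs = complete_data_loglik(s1, ds, z) - complete_data_loglik(s2, ds, z)
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_invalid_states_are_minus_infinity(self):
        rng = np.random.default_rng(5)
        ds = random_small_dataset(rng, n=10)
        priors = PriorSpec()
        spec = FrailtyModelSpec(WEIBULL, np.array([0.0]), 0.0)
        assert log_posterior(spec, np.ones(ds.r), ds, priors) == -np.inf
        spec = FrailtyModelSpec(WEIBULL, np.array([0.0]), 1.0)
        z = np.ones(ds.r)
        z[0] = -1.0
        assert log_posterior(spec, z, ds, priors) == -np.inf


class TestGibbsFrailtyUpdate:
    def test_empty_cluster_reduces_to_prior(self):
        shape, rate = frailty_conditional(0.5, 0, 0)
        assert shape == pytest.approx(2.0)
        assert rate == pytest.approx(2.0)

    def test_long_run_mean_of_conditional(self):
        rng = np.random.default_rng(6)
        shape, rate = frailty_conditional(1.0, 2, 3.0)
        draws = rng.gamma(shape, 1 / rate, 100_000)
        mean = shape / rate  # (1+2)/(1+3)
        assert mean == pytest.approx(0.75)
        se = np.sqrt(shape) / rate / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_draws_match_analytic_conditional_distribution(self):
        """KS check of the sampled conditional against its analytic gamma form."""
        rng = np.random.default_rng(7)
        ds = make_dataset(
            [1.0, 2.0, 0.5, 1.5], [1, 0, 1, 1], clusters=["a", "a", "b", "b"]
        )
        spec = FrailtyModelSpec(
            BaselineSpec("exponential", {"lam": 0.5}), np.array([]), 0.8
        )
        draws = np.array(
            [gibbs_update_frailties(spec, ds, rng) for _ in range(20_000)]
        )
        H0 = 0.5 * ds.time
        for i, lab in enumerate(ds.cluster_labels):
            mask = ds.cluster_index == i
            d = ds.event[mask].sum()
            A = H0[mask].sum()
            res = stats.kstest(
                draws[:, i], stats.gamma(1 / 0.8 + d, scale=1 / (1 / 0.8 + A)).cdf
            )
            assert res.pvalue > 0.01


class TestMetropolis:
    def test_zero_scale_always_accepts_unchanged_state(self):
        rng = np.random.default_rng(8)
        block = AdaptiveRandomWalk(2, scale=1e-300)
        x = np.array([0.3, -0.2])
        new, _, accepted = metropolis_step(
            x, lambda v: float(-0.5 * v @ v), block, rng
        )
        assert accepted
        np.testing.assert_allclose(new, x, atol=1e-290)

    def test_chain_matches_analytic_normal_posterior(self):
        """On an exactly-normal 2-d target the chain reproduces mean and SD."""
        rng = np.random.default_rng(9)
        mean = np.array([1.0, -2.0])
        target = lambda v: float(-0.5 * np.sum((v - mean) ** 2))
        block = AdaptiveRandomWalk(2, scale=1.0)
        x = np.zeros(2)
        draws = []
        for it in range(30_000):
            x, _, _ = metropolis_step(x, target, block, rng, adapting=it < 5_000)
            if it >= 5_000:
                draws.append(x.copy())
        draws = np.array(draws)
        from frailsurv.bayes import _batch_means_se

        for j in range(2):
            se = _batch_means_se([draws[:, j]])
            assert abs(draws[:, j].mean() - mean[j]) < 3 * se
            assert draws[:, j].std() == pytest.approx(1.0, rel=0.1)
        rate = block.accepted / block.proposed
        assert 0.15 < rate < 0.5


class TestRunMcmc:
    def test_bitwise_reproducible(self, reduced_fixture):
        ds, fit = reduced_fixture["ds"], reduced_fixture["fit"]
        a = run_mcmc(ds, "weibull", n_iter=400, burn_in=100, n_chains=2, seed=11, init=fit.spec)
        b = run_mcmc(ds, "weibull", n_iter=400, burn_in=100, n_chains=2, seed=11, init=fit.spec)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.draws, cb.draws)

    def test_stored_draw_count_and_positivity(self, reduced_mcmc):
        res = reduced_mcmc["result"]
        assert res.n_stored == (res.n_iter - res.burn_in) // res.thin
        j = res.names.index("theta")
        assert all((c.draws[:, j] > 0).all() for c in res.chains)
        assert all((c.frailties > 0).all() for c in res.chains)

    def test_acceptance_rates_in_working_band(self, reduced_mcmc):
        for chain in reduced_mcmc["result"].chains:
            for rate in chain.acceptance.values():
                assert 0.15 < rate < 0.55

    def test_posterior_recovers_reduced_truth(self, reduced_fixture, reduced_mcmc):
        truth = reduced_fixture["report"].truth
        summary = reduced_mcmc["summary"]
        named = dict(truth["beta"], lam=truth["baseline"]["lam"],
                     gamma=truth["baseline"]["gamma"], theta=truth["theta"])
        for name, value in named.items():
            row = summary.loc[name]
            assert abs(row["mean"] - value) < 3.5 * row["sd"], name

    def test_constant_covariate_posterior_is_prior_dominated(self):
        """A never-varying covariate's coefficient stays at its prior: wide CI over 0."""
        import pandas as pd

        from frailsurv.dataset import CovariateCodebook, SurvivalDataset

        rng = np.random.default_rng(13)
        frame = pd.DataFrame(
            {
                "time": rng.exponential(1.0, 120),
                "event": np.ones(120, int),
                "cluster": rng.choice(["r1", "r2", "r3"], 120),
                "g": ["a"] * 120,  # 'b' never occurs -> design column all zero
            }
        )
        ds = SurvivalDataset(frame, CovariateCodebook({"g": ["a", "b"]}))
        init = FrailtyModelSpec(
            BaselineSpec("exponential", {"lam": 1.0}), np.array([0.0]), 0.3
        )
        res = run_mcmc(ds, "exponential", n_iter=3000, burn_in=800,
                       n_chains=1, seed=13, init=init)
        row = summarize_posterior(res).loc["g[b]"]
        assert row["q2.5"] < 0 < row["q97.5"]
        assert row["sd"] > 50  # prior sd is sqrt(1e5) ~ 316

    def test_niter_must_exceed_burnin(self, reduced_fixture):
        with pytest.raises(ValueError):
            run_mcmc(reduced_fixture["ds"], "weibull", n_iter=100, burn_in=100)

    def test_subject_order_permutation_changes_only_monte_carlo_noise(self, reduced_fixture):
        ds, fit = reduced_fixture["ds"], reduced_fixture["fit"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n)
        from frailsurv.dataset import SurvivalDataset

        ds_perm = SurvivalDataset(ds.frame.iloc[perm], ds.codebook)
        kw = dict(n_iter=3500, burn_in=500, n_chains=1, seed=5, init=fit.spec)
        s1 = summarize_posterior(run_mcmc(ds, "weibull", **kw))
        s2 = summarize_posterior(run_mcmc(ds_perm, "weibull", **kw))
        for name in s1.index:
            tol = 6 * np.hypot(s1.loc[name, "mc_error"], s2.loc[name, "mc_error"])
            assert abs(s1.loc[name, "mean"] - s2.loc[name, "mean"]) < max(tol, 1e-12), name


def _pseudo_result(chains_arrays, name="x"):
    chains = [
        PosteriorChain(
            draws=np.asarray(c, dtype=float).reshape(-1, 1),
            names=[name],
            log_post=np.zeros(len(c)),
            acceptance={},
        )
        for c in chains_arrays
    ]
    return McmcResult(chains=chains, family="weibull", with_frailty=False,
                      seed=0, n_iter=len(chains_arrays[0]), burn_in=0, thin=1)


class TestSummaries:
    def test_constant_chain_degenerate_summary(self):
        res = _pseudo_result([np.full(200, 2.5), np.full(200, 2.5)])
        row = summarize_posterior(res).loc["x"]
        assert row["sd"] == 0 and row["mc_error"] == 0
        assert row["q2.5"] == row["q97.5"] == 2.5

    def test_iid_normal_pseudo_chain(self):
        rng = np.random.default_rng(14)
        res = _pseudo_result([rng.standard_normal(21_000), rng.standard_normal(21_000)])
        row = summarize_posterior(res).loc["x"]
        n = 42_000
        assert abs(row["mean"]) < 3 / np.sqrt(n)
        assert row["mc_error"] == pytest.approx(row["sd"] / np.sqrt(n), rel=0.25)
        assert row["sample"] == n

    def test_significance_flag_follows_interval(self):
        rng = np.random.default_rng(15)
        res = _pseudo_result([rng.standard_normal(5000) + 5.0])
        assert bool(summarize_posterior(res).loc["x", "significant"])
        res = _pseudo_result([rng.standard_normal(5000) * 3.0])
        assert not bool(summarize_posterior(res).loc["x", "significant"])

    def test_mc_error_rule(self):
        rng = np.random.default_rng(16)
        res = _pseudo_result([rng.standard_normal(20_000)])
        assert bool(mc_error_ok(summarize_posterior(res)).loc["x"])


class TestBGR:
    def test_duplicated_chains_give_exactly_one(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(500)
        assert bgr_statistic(np.stack([x, x])) == 1.0

    def test_iid_chains_stay_below_105(self):
        rng = np.random.default_rng(18)
        chains = rng.standard_normal((2, 10_000))
        assert bgr_statistic(chains) < 1.05

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(19)
        chains = np.stack(
            [rng.standard_normal(2000), rng.standard_normal(2000) + 10.0]
        )
        assert bgr_statistic(chains) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            bgr_statistic(np.zeros((1, 100)))

    def test_windowed_series_ends_at_full_length(self):
        rng = np.random.default_rng(20)
        series = bgr_diagnostic(rng.standard_normal((2, 4000)))
        assert series["iteration"].iloc[-1] == 4000
        assert (series["bgr"] >= 1.0).all()

    def test_agrees_with_arviz_on_iid_chains(self):
        import arviz as az

        rng = np.random.default_rng(21)
        chains = rng.standard_normal((2, 5000))
        ours = bgr_statistic(chains)
        theirs = float(az.rhat(az.from_dict({"x": chains}))["x"].values)
        assert ours == pytest.approx(theirs, abs=0.01)


class TestDIC:
    def test_collapsed_chain_has_zero_pd(self):
        rng = np.random.default_rng(22)
        ds = random_small_dataset(rng, n=20)
        row = np.array([0.5, 1.5, 0.1, 0.6])  # lam, gamma, beta, theta
        res = McmcResult(
            chains=[
                PosteriorChain(
                    draws=np.tile(row, (100, 1)),
                    names=["lam", "gamma", "g[b]", "theta"],
                    log_post=np.zeros(100),
                    acceptance={},
                    frailties=np.ones((100, ds.r)),
                )
            ],
            family="weibull",
            with_frailty=True,
            seed=0,
            n_iter=100,
            burn_in=0,
            thin=1,
        )
        dic = compute_dic(res, ds)
        assert dic.p_d == pytest.approx(0.0, abs=1e-9)
        assert dic.dic == pytest.approx(dic.dhat, abs=1e-9)

    def test_identities_hold_exactly(self):
        rep = DICReport(dbar=45050.0, dhat=45027.8)
        assert rep.p_d == pytest.approx(45050.0 - 45027.8)
        assert rep.dic == pytest.approx(rep.dbar + rep.p_d)

    def test_conditional_focus_runs(self, reduced_fixture):
        ds, fit = reduced_fixture["ds"], reduced_fixture["fit"]
        res = run_mcmc(ds, "weibull", n_iter=600, burn_in=200, n_chains=1,
                       seed=23, init=fit.spec)
        marg = compute_dic(res, ds, focus="marginal")
        cond = compute_dic(res, ds, focus="conditional")
        assert np.isfinite(marg.dic) and np.isfinite(cond.dic)
        with pytest.raises(ValueError):
            compute_dic(res, ds, focus="nonsense")


class TestPlots:
    def test_files_exist_and_are_nonempty(self, reduced_fixture, tmp_path):
        ds, fit = reduced_fixture["ds"], reduced_fixture["fit"]
        res = run_mcmc(ds, "weibull", n_iter=400, burn_in=100, n_chains=2,
                       seed=24, init=fit.spec)
        paths = convergence_plots(res, tmp_path, params=["gamma", "theta"])
        assert len(paths) == 2
        for p in paths:
            assert (tmp_path / p.split("/")[-1]).stat().st_size > 0


class TestPosteriorConcentration:
    def test_coefficient_sds_shrink_with_sample_size(self):
        """Quadrupling n halves the coefficient posterior SDs (within 20%)."""
        sds = {}
        for n in (500, 2000):
            ds, _ = generate(ScenarioSpec.edhs_reduced(n=n, theta=0.5), seed=31)
            res = run_mcmc(ds, "weibull", n_iter=4000, burn_in=1000,
                           n_chains=1, seed=31)
            s = summarize_posterior(res)
            sds[n] = s.loc[[c for c in s.index if "[" in c], "sd"]
        ratio = (sds[500] / sds[2000]).mean()
        assert 2.0 * 0.8 < ratio < 2.0 * 1.2
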