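import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isomix import bayes_fit as bf
from isomix.bayes_fit import (
    ConvergenceWarning,
    FitResult,
    McmcSettings,
    PriorSpec,
    compute_dic,
    default_priors,
    fit_incorporation_bayes,
    fit_incorporation_nls,
    gelman_rubin,
    select_model,
)
from isomix.kinetics import CompartmentParams
from isomix.synthetic_data import ExperimentDesign, simulate_feeding_trial


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self, rng):
        chain = rng.standard_normal(500)
        chains = np.stack([chain, chain, chain])
        assert gelman_rubin(chains) == 1.0

    def test_disjoint_constant_chains_diverge(self):
        chains = np.stack([np.zeros(1000), np.full(1000, 10.0)])
        assert gelman_rubin(chains) == np.inf

    def test_separated_noisy_chains_large(self, rng):
        chains = np.stack(
            [rng.normal(0, 1, 2000), rng.normal(10, 1, 2000), rng.normal(-10, 1, 2000)]
        )
        assert gelman_rubin(chains) > 5.0

    def test_iid_normal_chains_near_one(self, rng):
        chains = rng.standard_normal((3, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100)))

    def test_dict_input(self, rng):
        chains = {"a": rng.standard_normal((3, 500))}
        out = gelman_rubin(chains)
        assert set(out) == {"a"} and out["a"] >= 1.0


class TestSettings:
    def test_burn_must_precede_end(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, n_burn=100)

    def test_psrf_needs_chains(self):
        with pytest.raises(ValueError):
            McmcSettings(n_chains=1)

    def test_retained_arithmetic(self):
        s = McmcSettings(n_chains=3, n_iter=10_000, n_burn=4_000, thin=4)
        assert s.n_keep_per_chain == 1500


class TestPriors:
    def test_default_priors_lookup(self):
        p = default_priors(1, "muscle", "c")
        assert p.dXinf == (-19.0, 10.0)
        assert p.dX0 == (-23.0, 10.0)
        assert p.lam == (0.1, 5.0)

    def test_unknown_combination_rejected(self):
        with pytest.raises(KeyError):
            default_priors(9, "muscle", "c")

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(dX0=(0.0, 0.0))


class TestBayesFit:
    def test_recovers_truth_on_clean_data(self, clean_g1_samples, small_settings):
        truth = {"dX0": -22.83, "dXinf": -19.23, "lambda": 0.20}
        fit = fit_incorporation_bayes(
            clean_g1_samples, "c", "one",
            priors=default_priors(1, "muscle", "c"), settings=small_settings,
        )
        for name, true_val in truth.items():
            post_sd = fit.draws[name].std(ddof=1)
            assert abs(fit.summary[name]["mean"] - true_val) < 2.0 * max(post_sd, 1e-3)

    def test_noisy_recovery_within_credibility(self, noisy_g1_samples, small_settings):
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one",
            priors=default_priors(1, "muscle", "c"), settings=small_settings,
        )
        assert fit.summary["dXinf"]["cr_low"] < -19.23 < fit.summary["dXinf"]["cr_high"]

    def test_single_day_rejected(self):
        df = pd.DataFrame({"day": [0, 0, 0], "d13c": [1.0, 1.1, 0.9], "d15n": [0, 0, 0]})
        with pytest.raises(ValueError, match="distinct days"):
            fit_incorporation_bayes(df, "c", "one")

    def test_mixed_groups_rejected(self, noisy_g1_samples):
        df = noisy_g1_samples.copy()
        df.loc[df.index[:3], "group"] = 2
        with pytest.raises(ValueError, match="group"):
            fit_incorporation_bayes(df, "c", "one")

    def test_draw_bookkeeping(self, noisy_g1_samples):
        settings = McmcSettings(n_chains=3, n_iter=3000, n_burn=1000, thin=4, seed=0)
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one",
            priors=default_priors(1, "muscle", "c"), settings=settings,
        )
        assert fit.draws["dXinf"].shape == (3, settings.n_keep_per_chain)

    def test_sigma_draws_positive(self, noisy_g1_samples, small_settings):
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one",
            priors=default_priors(1, "muscle", "c"), settings=small_settings,
        )
        assert np.all(fit.draws["sigma"] > 0)

    def test_credibility_brackets_mean(self, noisy_g1_samples, small_settings):
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one",
            priors=default_priors(1, "muscle", "c"), settings=small_settings,
        )
        for stats_ in fit.summary.values():
            assert stats_["cr_low"] <= stats_["mean"] <= stats_["cr_high"]

    def test_two_compartment_rate_ordering(self, noisy_g1_samples, small_settings):
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "two",
            priors=default_priors(1, "muscle", "c"), settings=small_settings,
        )
        assert np.all(fit.draws["lambda1"] >= fit.draws["lambda2"])
        assert np.all((fit.draws["p"] >= 0) & (fit.draws["p"] <= 1))

    def test_prior_robustness(self, noisy_g1_samples, small_settings):
        priors = default_priors(1, "muscle", "c")
        fit_a = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one", priors=priors, settings=small_settings
        )
        fit_b = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one",
            priors=priors.widened(100.0), settings=small_settings,
        )
        for name in ("dX0", "dXinf"):
            sd = fit_a.draws[name].std(ddof=1)
            assert abs(fit_a.summary[name]["mean"] - fit_b.summary[name]["mean"]) < sd

    def test_nonconvergence_flagged(self):
        # 2 iterations retained cannot mix: must warn, not silently pass
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"day": np.tile([0, 10, 20, 40, 80], 3),
             "d13c": rng.normal(-20, 2, 15), "d15n": np.zeros(15)}
        )
        settings = McmcSettings(n_chains=3, n_iter=60, n_burn=10, thin=1, seed=1)
        with pytest.warns(ConvergenceWarning):
            fit = fit_incorporation_bayes(df, "c", "one", settings=settings)
        assert not fit.converged


class TestDic:
    def test_degenerate_posterior_pd_zero(self):
        t = np.array([0.0, 10.0, 20.0])
        y = np.array([-22.0, -21.0, -20.0])
        draw = {"dX0": np.full((2, 5), -22.0), "dXinf": np.full((2, 5), -19.0),
                "lambda": np.full((2, 5), 0.1), "sigma": np.full((2, 5), 0.5)}
        fit = FitResult(
            model_kind="one", param_names=("dX0", "dXinf", "lambda", "sigma"),
            draws=draw, summary={}, psrf={}, dic=np.nan, converged=True,
            n_obs=3, t=t, y=y,
        )
        mu = -19.0 - (-19.0 + 22.0) * np.exp(-0.1 * t)
        d_hat = -2.0 * stats.norm.logpdf(y, mu, 0.5).sum()
        assert compute_dic(fit) == pytest.approx(d_hat, abs=1e-9)

    def test_hand_computed_deviance_two_draws(self):
        # brute-force log-likelihood oracle: 3 points, 2 distinct draws
        t = np.array([0.0, 5.0, 15.0])
        y = np.array([-22.5, -21.0, -19.5])
        draws_list = [(-22.8, -19.2, 0.15, 0.4), (-22.6, -19.4, 0.25, 0.6)]
        draw = {
            name: np.array([[draws_list[0][k], draws_list[1][k]]])
            for k, name in enumerate(("dX0", "dXinf", "lambda", "sigma"))
        }
        # single chain is fine for DIC arithmetic
        fit = FitResult(
            model_kind="one", param_names=("dX0", "dXinf", "lambda", "sigma"),
            draws=draw, summary={}, psrf={}, dic=np.nan, converged=True,
            n_obs=3, t=t, y=y,
        )
        devs = []
        for dX0, dXinf, lam, sigma in draws_list:
            mu = dXinf - (dXinf - dX0) * np.exp(-lam * t)
            devs.append(-2.0 * stats.norm.logpdf(y, mu, sigma).sum())
        d_bar = np.mean(devs)
        mean_params = np.mean(np.array(draws_list), axis=0)
        mu_bar = mean_params[1] - (mean_params[1] - mean_params[0]) * np.exp(
            -mean_params[2] * t
        )
        d_hat = -2.0 * stats.norm.logpdf(y, mu_bar, mean_params[3]).sum()
        expected = d_bar + (d_bar - d_hat)
        assert compute_dic(fit) == pytest.approx(expected, abs=1e-9)

    def test_empty_draws_rejected(self):
        fit = FitResult(
            model_kind="one", param_names=("dX0", "dXinf", "lambda", "sigma"),
            draws={n: np.empty((2, 0)) for n in ("dX0", "dXinf", "lambda", "sigma")},
            summary={}, psrf={}, dic=np.nan, converged=True,
            n_obs=3, t=np.arange(3.0), y=np.zeros(3),
        )
        with pytest.raises(ValueError):
            compute_dic(fit)


class TestNls:
    def test_zero_noise_exact_recovery(self, clean_g1_samples):
        res = fit_incorporation_nls(clean_g1_samples, "c", "one")
        assert res.params["dX0"] == pytest.approx(-22.83, abs=1e-6)
        assert res.params["dXinf"] == pytest.approx(-19.23, abs=1e-6)
        assert res.params["lambda"] == pytest.approx(0.20, abs=1e-6)

    def test_agrees_with_bayes_under_weak_priors(self, noisy_g1_samples, small_settings):
        nls = fit_incorporation_nls(noisy_g1_samples, "c", "one")
        fit = fit_incorporation_bayes(
            noisy_g1_samples, "c", "one", priors=PriorSpec(), settings=small_settings
        )
        for name in ("dX0", "dXinf", "lambda"):
            sd = fit.draws[name].std(ddof=1)
            assert abs(nls.params[name] - fit.summary[name]["mean"]) < 2.0 * sd

    def test_too_few_observations_rejected(self):
        # n = k + 1 with k = 4 (three curve params + sigma)
        df = pd.DataFrame(
            {"day": [0, 10, 20, 40, 80],
             "d13c": [-22.8, -21.5, -20.5, -19.7, -19.3],
             "d15n": np.zeros(5)}
        )
        with pytest.raises(ValueError, match="AICc"):
            fit_incorporation_nls(df, "c", "one")

    def test_aicc_formula(self, noisy_g1_samples):
        res = fit_incorporation_nls(noisy_g1_samples, "c", "one")
        n, k = res.n_obs, 4
        sigma2 = res.rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        expected = 2 * k - 2 * loglik + 2 * k * (k + 1) / (n - k - 1)
        assert res.aicc == pytest.approx(expected, rel=1e-12)


class TestSelectModel:
    def _fit_with_dic(self, kind, dic, t, y):
        names = bf._PARAM_NAMES[kind]
        draws = {n: np.ones((2, 3)) for n in names}
        return FitResult(
            model_kind=kind, param_names=names, draws=draws, summary={}, psrf={},
            dic=dic, converged=True, n_obs=len(t), t=t, y=y,
        )

    def test_clear_one_compartment_win(self):
        t, y = np.arange(5.0), np.zeros(5)
        one = self._fit_with_dic("one", 28.03, t, y)
        two = self._fit_with_dic("two", 28.46, t, y)
        assert select_model(one, two) == "one"

    def test_clear_two_compartment_win(self):
        t, y = np.arange(5.0), np.zeros(5)
        one = self._fit_with_dic("one", 25.72, t, y)
        two = self._fit_with_dic("two", 23.50, t, y)
        assert select_model(one, two) == "two"

    def test_tie_goes_to_one_compartment(self):
        t, y = np.arange(5.0), np.zeros(5)
        one = self._fit_with_dic("one", 30.0, t, y)
        two = self._fit_with_dic("two", 30.0, t, y)
        assert select_model(one, two) == "one"

    def test_mismatched_data_rejected(self):
        one = self._fit_with_dic("one", 10.0, np.arange(5.0), np.zeros(5))
        two = self._fit_with_dic("two", 12.0, np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="identical data"):
            select_model(one, two)

    def test_dic_prefers_one_compartment_under_null(self, small_settings):
        # data simulated from a one-compartment truth: DIC(one) <= DIC(two) + 2
        # in most repetitions
        params = {
            (1, "muscle", "c"): CompartmentParams(-22.8, -19.2, 0.15),
            (1, "muscle", "n"): CompartmentParams(8.7, 10.4, 0.05),
        }
        wins = 0
        n_rep = 8
        priors = default_priors(1, "muscle", "c")
        for seed in range(n_rep):
            design = ExperimentDesign(noise_sd_c=0.3, noise_sd_n=0.3, seed=seed)
            samples = simulate_feeding_trial(params, design)
            settings = small_settings.scaled(seed=seed)
            f1 = fit_incorporation_bayes(samples, "c", "one", priors, settings)
            f2 = fit_incorporation_bayes(samples, "c", "two", priors, settings)
            if f1.dic <= f2.dic + 2.0:
                wins += 1
        assert wins >= int(0.8 * n_rep)
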