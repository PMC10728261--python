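"""Gibbs samplers: conditional correctness, prior recovery, shrinkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import trialnoise as tn
from trialnoise.models import (
    McmcSettings,
    MultiTaskModel,
    MultiTaskPriors,
    OneTaskModel,
    OneTaskPriors,
    convergence_diagnostics,
    posterior_correlation_summary,
)
from trialnoise.trial_data import TrialTable

from conftest import make_table


def _single_task(table):
    return TrialTable(table.data[table.data["task"] == "task1"])


def _empty_table():
    return TrialTable(pd.DataFrame(columns=["person", "task", "condition", "rt"]))


@pytest.fixture(scope="module")
def tiny_instance():
    """3 persons, 4 trials per condition, known alpha/sigma."""
    rng = np.random.default_rng(11)
    I, L, sigma = 3, 4, 200.0
    theta = rng.normal(50, 25, I)
    alpha = rng.normal(800, 100, I)
    rows = []
    for i in range(I):
        for x, cond in ((0, "congruent"), (1, "incongruent")):
            for rt in alpha[i] + x * theta[i] + sigma * rng.standard_normal(L):
                rows.append((f"p{i}", "task1", cond, rt))
    return make_table(rows), alpha, sigma, L


class TestConditionalCorrectness:
    def test_sigma_theta_posterior_matches_grid_integration(self, tiny_instance):
        """With alpha and sigma^2 pinned, the Gibbs marginal of
        sigma_theta^2 must match a dense 2-D grid posterior with the
        per-person effects integrated out analytically."""
        table, alpha, sigma, L = tiny_instance
        model = OneTaskModel(iterations=60_000, burn_in=2000, chains=2, seed=3,
                             check_convergence=False)
        model.fit(table, fix_alpha=alpha, fix_sigma2=sigma**2)
        draws = np.sort(model.draws_.Sigma_theta[:, :, 0, 0].ravel())

        d = table.data
        mi = (
            d[d["condition"] == "incongruent"]
            .groupby("person", observed=True)["rt"].mean().to_numpy()
            - alpha
        )
        v_data = sigma**2 / L
        mu_grid = np.linspace(-400, 500, 1201)
        st2_grid = np.linspace(1e-3, 4e4, 4000)
        var = st2_grid[:, None] + v_data
        ll = (
            -0.5 * ((mi[None, None, :] - mu_grid[None, :, None]) ** 2).sum(-1) / var
            - len(mi) / 2 * np.log(var)
        )
        logp = (
            ll
            + stats.norm(50, 100).logpdf(mu_grid)[None, :]
            + stats.invgamma(a=2, scale=900).logpdf(st2_grid)[:, None]
        )
        p = np.exp(logp - logp.max())
        marg = np.trapezoid(p, mu_grid, axis=1)
        cdf = np.cumsum(marg)
        cdf /= cdf[-1]
        emp = np.searchsorted(draws, st2_grid) / len(draws)
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestPriorSampling:
    def test_one_task_effect_variance_prior_recovered(self):
        model = OneTaskModel(iterations=10_000, burn_in=0, chains=2, seed=6,
                             check_convergence=False).fit(_empty_table())
        st2 = model.draws_.Sigma_theta[:, :, 0, 0].ravel()
        ks = stats.kstest(st2, stats.invgamma(a=2, scale=900).cdf).statistic
        assert ks < 0.02
        mu_ks = stats.kstest(model.draws_.mu.ravel(),
                             stats.norm(50, 100).cdf).statistic
        assert mu_ks < 0.02

    def test_inverse_wishart_diagonal_marginal_matches_inverse_gamma(self):
        # df = J+3 with scale 1800 I implies each diagonal ~ IG(2, 900)
        model = MultiTaskModel(priors=MultiTaskPriors(J=2), iterations=10_000,
                               burn_in=0, chains=2, seed=5,
                               check_convergence=False).fit(_empty_table())
        for j in range(2):
            diag = model.draws_.Sigma_theta[:, :, j, j].ravel()
            ks = stats.kstest(diag, stats.invgamma(a=2, scale=900).cdf).statistic
            assert ks < 0.02

    def test_trial_variance_prior_recovered(self):
        model = MultiTaskModel(priors=MultiTaskPriors(J=2), iterations=10_000,
                               burn_in=0, chains=2, seed=5,
                               check_convergence=False).fit(_empty_table())
        ks = stats.kstest(model.draws_.sigma2.ravel(),
                          stats.invgamma(a=0.1, scale=0.1e6).cdf).statistic
        assert ks < 0.02


class TestOneTaskRecovery:
    @pytest.fixture(scope="class")
    def fitted(self):
        table, truth = tn.simulate_two_task(0.0, I=200, L=100, rng=42)
        model = OneTaskModel(iterations=3000, burn_in=500, chains=2, seed=9)
        model.fit(_single_task(table))
        return model, truth

    def test_parameters_recovered_within_three_posterior_sds(self, fitted):
        model, truth = fitted
        d = model.draws_
        for draws_arr, true_val in [
            (d.sigma_draws().ravel(), 200.0),
            (d.sigma_theta_draws().ravel(), 25.0),
            (d.mu.ravel(), 50.0),
        ]:
            assert abs(draws_arr.mean() - true_val) < 3 * draws_arr.std()

    def test_chains_converged(self, fitted):
        model, _ = fitted
        assert (model.diagnostics_["rhat"] < 1.05).all()

    def test_shrinkage_toward_group_mean(self, fitted):
        model, truth = fitted
        table, _ = tn.simulate_two_task(0.0, I=200, L=100, rng=42)
        piv = tn.person_task_effects(_single_task(table)).pivot()
        d = piv.loc[model.draws_.persons, "task1"].to_numpy()
        # every person's estimate is pulled toward the posterior grand
        # mean (1 ms slack for Monte-Carlo error in the posterior means)
        assert np.all(
            np.abs(model.theta_ - model.mu_theta_)
            <= np.abs(d - model.mu_theta_) + 1.0
        )
        # and on average the pull is strict
        assert np.mean(np.abs(model.theta_ - model.mu_theta_)) < np.mean(
            np.abs(d - model.mu_theta_)
        )

    def test_degenerate_noise_free_data(self):
        table, truth = tn.simulate_two_task(0.0, I=50, L=100, sigma=0.0, rng=3)
        model = OneTaskModel(iterations=1500, burn_in=300, chains=1, seed=2,
                             check_convergence=False).fit(_single_task(table))
        assert model.sigma_ < 6.0  # posterior mass collapses toward zero
        piv = tn.person_task_effects(_single_task(table)).pivot()
        d = piv.loc[model.draws_.persons, "task1"].to_numpy()
        np.testing.assert_allclose(model.theta_, d, atol=1.0)

    def test_shrinkage_decreases_with_more_trials(self):
        def median_shrink(L, seed):
            table, _ = tn.simulate_two_task(0.0, I=100, L=L, rng=seed)
            sub = _single_task(table)
            model = OneTaskModel(iterations=1500, burn_in=300, chains=1,
                                 seed=1, check_convergence=False).fit(sub)
            piv = tn.person_task_effects(sub).pivot()
            d = piv.loc[model.draws_.persons, "task1"].to_numpy()
            with np.errstate(invalid="ignore"):
                ratio = np.abs(model.theta_ - model.mu_theta_) / np.abs(
                    d - d.mean()
                )
            return np.nanmedian(ratio)

        assert median_shrink(400, 8) > median_shrink(10, 8)


class TestMultiTaskModel:
    @pytest.fixture(scope="class")
    def fitted_pair(self):
        table, truth = tn.simulate_two_task(0.8, I=200, L=100, rng=21)
        model = MultiTaskModel(iterations=2000, burn_in=500, chains=2, seed=4,
                               keep_person_draws=False,
                               check_convergence=False).fit(table)
        return model, table, truth

    def test_posterior_mean_disattenuates_sample_correlation(self, fitted_pair):
        model, table, truth = fitted_pair
        eff = tn.person_task_effects(table)
        r_sample = tn.sample_correlation(eff, "task1", "task2")
        rho_hat = model.correlation_[0, 1]
        # the model estimate must sit above the attenuated sample value,
        # closer to the generating .8
        assert rho_hat > r_sample + 0.1
        assert abs(rho_hat - 0.8) < abs(r_sample - 0.8)

    def test_correlation_draws_are_valid_matrices(self, fitted_pair):
        model, _, _ = fitted_pair
        corr = model.draws_.correlation_draws()
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)
        np.testing.assert_allclose(corr[..., 0, 0], 1.0)
        np.testing.assert_allclose(corr, np.swapaxes(corr, -1, -2))

    def test_sigma_recovered(self, fitted_pair):
        model, _, _ = fitted_pair
        assert model.sigma_ == pytest.approx(200.0, rel=0.02)

    def test_near_zero_variance_task_shrinks_to_grand_mean(self):
        # one task with essentially no true individual variation: its
        # person effects should collapse toward the task mean, and the
        # cross-task correlation should be left wide
        Sigma = np.array([[25.0**2, 0.0], [0.0, 0.5**2]])
        spec = tn.PopulationSpec(mu=[50.0, 50.0], Sigma_theta=Sigma)
        rng = np.random.default_rng(13)
        truth = tn.draw_true_effects(spec, 150, rng)
        table = tn.simulate_trials(truth, sigma=200.0, L=80, rng=rng)
        model = MultiTaskModel(iterations=2000, burn_in=500, chains=2, seed=8,
                               check_convergence=False).fit(table)
        eff = tn.person_task_effects(table).pivot()
        sd_sample = eff["task2"].std()
        sd_model = model.theta_[:, 1].std()
        assert sd_model < 0.25 * sd_sample
        summ = model.correlation_summary_.iloc[0]
        assert summ["hi"] - summ["lo"] > 0.5  # wide, honest uncertainty

    def test_missing_task_person_excluded_with_warning(self):
        table, _ = tn.simulate_two_task(0.5, I=10, L=5, rng=30)
        df = table.data
        drop = (df["person"] == 0) & (df["task"] == "task2")
        with pytest.warns(UserWarning, match="excluding"):
            MultiTaskModel(iterations=200, burn_in=50, chains=1, seed=1,
                           check_convergence=False).fit(TrialTable(df[~drop]))


class TestDiagnosticsAndSummaries:
    def test_identical_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        diag = convergence_diagnostics({"x": np.stack([x, x])})
        assert diag.loc[0, "rhat"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_have_large_rhat(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(1000)
        diag = convergence_diagnostics({"x": np.stack([a, a + 50.0])})
        assert diag.loc[0, "rhat"] > 1.5

    def test_constant_draws_summary(self):
        draws = tn.PosteriorDraws(
            mu=np.zeros((1, 100, 2)),
            sigma2=np.ones((1, 100)),
            Sigma_theta=np.tile(np.array([[4.0, 1.0], [1.0, 1.0]]),
                                (1, 100, 1, 1)),
            tasks=["A", "B"],
            persons=[],
        )
        summ = posterior_correlation_summary(draws)
        assert summ.loc[0, "mean"] == pytest.approx(0.5)
        assert summ.loc[0, "lo"] == pytest.approx(0.5)
        assert summ.loc[0, "hi"] == pytest.approx(0.5)

    def test_symmetric_draws_give_symmetric_interval(self):
        rng = np.random.default_rng(1)
        r = np.tanh(rng.standard_normal(20_000) * 0.3)
        C = np.empty((1, r.size, 2, 2))
        C[..., 0, 0] = C[..., 1, 1] = 1.0
        C[0, :, 0, 1] = C[0, :, 1, 0] = r
        draws = tn.PosteriorDraws(
            mu=np.zeros((1, r.size, 2)), sigma2=np.ones((1, r.size)),
            Sigma_theta=C, tasks=["A", "B"], persons=[],
        )
        summ = posterior_correlation_summary(draws)
        assert summ.loc[0, "lo"] == pytest.approx(-summ.loc[0, "hi"], abs=0.03)


class TestEstimatorApi:
    def test_get_set_params_round_trip(self):
        model = MultiTaskModel(iterations=123, seed=7)
        params = model.get_params()
        assert params["iterations"] == 123
        cloned = clone(model)
        assert cloned.get_params()["seed"] == 7

    def test_functional_wrappers_return_draws(self):
        table, _ = tn.simulate_two_task(0.5, I=8, L=4, rng=2)
        draws = tn.fit_multi_task(
            table, mcmc=McmcSettings(iterations=200, burn_in=50, chains=1, seed=1)
        )
        assert draws.n_draws == 150
        one = tn.fit_one_task(
            _single_task(table),
            mcmc=McmcSettings(iterations=200, burn_in=50, chains=1, seed=1),
        )
        assert one.J == 1

    def test_one_task_model_rejects_multi_task_data(self):
        table, _ = tn.simulate_two_task(0.5, I=5, L=3, rng=2)
        with pytest.raises(ValueError, match="single task"):
            OneTaskModel(iterations=100, burn_in=10).fit(table)

    def test_mcmc_settings_validated(self):
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(chains=0)

    def test_priors_validated(self):
        with pytest.raises(ValueError):
            OneTaskPriors(sigma2_shape=-1)
        with pytest.raises(ValueError):
            MultiTaskPriors(J=2, iw_df=0.5)
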