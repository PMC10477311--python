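"""Hierarchical model: standardization, likelihood, gradients, sampler, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from reefmsy import model as M
from reefmsy.design import StandardizationSpec, build_design, fit_standardization
from reefmsy.hmc import HMCConfig, sample_chain
from reefmsy.params import ModelParams
from reefmsy.simulate import DatasetDesign, simulate_dataset
from reefmsy.surplus import SurplusModel

FOX = SurplusModel.fox()


class TestStandardization:
    def test_two_sd_formula(self, desk_table):
        spec = fit_standardization(desk_table)
        x = desk_table["sst"].to_numpy()
        np.testing.assert_allclose(
            spec.transform("sst", x), (x - x.mean()) / (2 * x.std()), rtol=1e-12
        )

    def test_gravity_passes_through_untransformed(self, desk_table):
        dm = build_design(desk_table)
        np.testing.assert_array_equal(dm.gravity, desk_table["gravity"].to_numpy())

    def test_atoll_is_untransformed_dummy(self, desk_table):
        dm = build_design(desk_table)
        assert set(np.unique(dm.env[:, 2])) <= {0.0, 1.0}

    def test_missing_coral_imputed_at_mean(self, desk_table):
        dm = build_design(desk_table)
        miss = desk_table["coral_cover"].isna().to_numpy()
        assert miss.any()
        np.testing.assert_allclose(dm.env[miss, 3], 0.0, atol=1e-12)

    def test_zero_variance_column_raises_with_name(self, desk_table):
        bad = desk_table.copy()
        bad["sst"] = 27.0
        with pytest.raises(ValueError, match="sst"):
            fit_standardization(bad)

    def test_unknown_habitat_level_raises(self, desk_table):
        bad = desk_table.copy()
        bad.loc[0, "habitat"] = "pinnacle"
        with pytest.raises(ValueError, match="pinnacle"):
            build_design(bad)

    def test_spec_round_trips_through_dict(self, desk_table):
        spec = fit_standardization(desk_table)
        spec2 = StandardizationSpec.from_dict(spec.to_dict())
        assert spec2.mean == spec.mean and spec2.sd == spec.sd


class TestLogLikelihood:
    def test_empty_dataset_is_zero(self):
        assert M.log_likelihood(ModelParams(), M.ModelData.empty()) == 0.0

    def test_single_reserve_reduces_to_standard_normal_density(self):
        """One reserve site with zero covariates: the log-likelihood is the normal
        density of log B_obs around the recovery trajectory mean."""
        data = M.ModelData.empty()
        t, B0, Bmin, r = 7.0, 120.0, 10.0, 0.135
        mu = np.log(B0) + np.log(Bmin / B0) * np.exp(-r * t)
        y = mu + 0.37
        data.y_i, data.t_i = np.array([y]), np.array([t])
        data.env_i, data.samp_i = np.zeros((1, 4)), np.zeros((1, 7))
        data.size_i, data.grav_i = np.zeros(1), np.zeros(1)
        params = ModelParams(B0=B0, r=r, Bmin=Bmin, sigma_i=1.0)
        expected = -0.5 * 0.37**2 - 0.5 * np.log(2 * np.pi)
        assert M.log_likelihood(params, data) == pytest.approx(expected, rel=1e-12)

    def test_generator_round_trip_zero_residuals(self, tiny_design):
        """With noise off, the likelihood's mean equals the observed log biomass."""
        params = ModelParams(sigma_i=1e-9, sigma_j=1e-9, sigma_z=1e-9)
        table, truth = simulate_dataset(params, tiny_design, seed=5)
        data = M.prepare_data(table)
        theta = M.pack_params(truth.params, data.jurisdictions)
        mu_i, mu_j, mu_z, *_ = M._mu_blocks(theta, data, FOX)
        np.testing.assert_allclose(np.concatenate([mu_i, mu_j, mu_z]),
                                   np.concatenate([data.y_i, data.y_j, data.y_z]), rtol=1e-6)

    def test_pack_unpack_round_trip(self, desk_data):
        p = ModelParams(u={c: 0.1 for c in desk_data.jurisdictions})
        p2 = M.unpack_params(M.pack_params(p, desk_data.jurisdictions), desk_data.jurisdictions)
        assert p2.B0 == pytest.approx(p.B0)
        assert p2.beta_gravity == pytest.approx(p.beta_gravity)
        assert p2.u == pytest.approx(p.u)


@pytest.mark.parametrize("model", [FOX, SurplusModel.schaefer(), SurplusModel.pella_tomlinson(3.0)])
def test_analytic_gradient_matches_finite_differences(desk_data, model):
    rng = np.random.default_rng(0)
    theta = M.pack_params(ModelParams(), desk_data.jurisdictions)
    theta = theta + 0.05 * rng.standard_normal(theta.size)
    _, g = M.log_posterior_and_grad(theta, desk_data, model)
    eps = 1e-6
    for k in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        num = (M.log_posterior_and_grad(tp, desk_data, model)[0]
               - M.log_posterior_and_grad(tm, desk_data, model)[0]) / (2 * eps)
        assert g[k] == pytest.approx(num, rel=1e-5, abs=1e-5)


class TestSamplerOnKnownTarget:
    def test_recovers_correlated_gaussian(self):
        """HMC on an exactly known 4-d correlated Gaussian: moments recovered."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        cov = A @ A.T + 0.5 * np.eye(4)
        prec = np.linalg.inv(cov)
        mean = np.array([1.0, -2.0, 0.5, 3.0])

        def logp(x):
            d = x - mean
            return -0.5 * d @ prec @ d, -prec @ d

        cfg = HMCConfig(n_warmup=600, n_samples=1500)
        draws = np.vstack([sample_chain(logp, np.zeros(4), cfg, seed=s)[0] for s in (0, 1)])
        mc_se = np.sqrt(np.diag(cov) / len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 30 * mc_se)
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.35, atol=0.3)

    def test_same_seed_same_draws(self):
        def logp(x):
            return -0.5 * x @ x, -x

        cfg = HMCConfig(n_warmup=100, n_samples=100)
        d1, _ = sample_chain(logp, np.zeros(3), cfg, seed=5)
        d2, _ = sample_chain(logp, np.zeros(3), cfg, seed=5)
        np.testing.assert_array_equal(d1, d2)


class TestFit:
    def test_fit_is_reproducible(self, desk_data):
        a = M.fit(desk_data, n_chains=2, n_warmup=150, n_samples=100, seed=9)
        b = M.fit(desk_data, n_chains=2, n_warmup=150, n_samples=100, seed=9)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_prior_only_recovers_prior(self):
        """With no data the posterior is the prior: B0 median ~ 120, contraction ~ 0."""
        post = M.fit(M.ModelData.empty(), n_chains=2, n_warmup=400, n_samples=400, seed=0)
        med = float(np.median(post.get("B0")))
        # prior median of exp(N(log 120, 1)) is 120; MC error on 800 draws is wide
        assert 95.0 < med < 150.0
        rep = M.diagnostics(post)
        assert abs(rep["contraction"].mean()) < 0.15

    def test_parameter_recovery_within_three_posterior_sd(self, desk_fit, desk_truth, desk_data):
        flat = desk_fit.flat()
        truth_theta = M.pack_params(desk_truth.params, desk_data.jurisdictions)
        names = desk_fit.names
        for k, name in enumerate(names):
            if name.startswith("u["):
                continue
            post_med, post_sd = np.median(flat[:, k]), np.std(flat[:, k])
            assert abs(post_med - truth_theta[k]) < 3.5 * post_sd, name

    def test_gravity_monotonicity_contract(self, desk_fit, desk_data):
        """beta_gravity < 0 draws imply higher gravity lowers expected biomass."""
        bgrav = desk_fit.get("beta_gravity")
        # generator truth is negative; posterior should concentrate below zero
        assert np.mean(bgrav < 0) > 0.9

    def test_doubling_data_shrinks_posterior(self, desk_fit):
        """Posterior contraction on B0 increases with sample size."""
        big = DatasetDesign(n_reserve=60, n_remote=40, n_fished=200, n_jurisdictions=8)
        table, _ = simulate_dataset(design=big, seed=1)
        post_big = M.fit(M.prepare_data(table), n_chains=2, n_warmup=400, n_samples=400, seed=2)
        sd_small = np.std(np.log(desk_fit.get("B0")))
        sd_big = np.std(np.log(post_big.get("B0")))
        assert sd_big < sd_small

    def test_single_chain_rejected(self, desk_data):
        with pytest.raises(ValueError):
            M.fit(desk_data, n_chains=1, n_warmup=10, n_samples=10, seed=0)


class TestDiagnostics:
    @pytest.mark.parametrize("shrink, expected", [(1.0, 0.0), (0.5, 0.75)])
    def test_contraction_identities(self, shrink, expected):
        """Posterior identical to prior -> contraction 0; posterior SD half the
        prior SD -> contraction 0.75 (per parameter, on the sampling scale)."""
        rng = np.random.default_rng(0)
        names = M.param_names([])
        theta = np.empty((2, 4000, len(names)))
        for k, name in enumerate(names):
            theta[:, :, k] = rng.normal(0.0, shrink * np.sqrt(M.prior_variance(name)), (2, 4000))
        draws = M.PosteriorDraws(theta, [], FOX, StandardizationSpec())
        rep = M.diagnostics(draws)
        assert rep["contraction"].mean() == pytest.approx(expected, abs=0.05)

    def test_prior_variance_table(self):
        assert M.prior_variance("log_B0") == 1.0
        assert M.prior_variance("beta_sst") == 4.0
        assert M.prior_variance("gamma") == 25.0
        assert M.prior_variance("log_sigma_i") == pytest.approx(np.pi**2 / 4)
        assert np.isnan(M.prior_variance("u[J01]"))

    def test_synthetic_fit_meets_stated_thresholds(self, desk_diagnostics):
        """The fit to desk-scale synthetic data satisfies the convergence bar:
        split R-hat below 1.01 and bulk ESS above 400 for every parameter."""
        assert desk_diagnostics["rhat"].max() <= 1.01
        assert desk_diagnostics["ess_bulk"].min() >= 400
        assert desk_diagnostics["contraction"].mean(skipna=True) >= 0.5

    def test_single_chain_diagnostics_rejected(self, desk_fit):
        one = M.PosteriorDraws(desk_fit.theta[:1], desk_fit.jurisdictions, FOX, desk_fit.spec)
        with pytest.raises(ValueError):
            M.diagnostics(one)


class TestCrossCheckWithEmcee:
    def test_posterior_means_agree_with_ensemble_sampler(self, tiny_design):
        """Independent route: emcee's affine-invariant ensemble sampler on the same
        log posterior should give the same posterior means (loose MC tolerance)."""
        emcee = pytest.importorskip("emcee")
        table, _ = simulate_dataset(design=tiny_design, seed=3)
        data = M.prepare_data(table)
        dim = len(M.param_names(data.jurisdictions))

        def logp(th):
            return M.log_posterior_and_grad(th, data, FOX)[0]

        post = M.fit(data, n_chains=2, n_warmup=400, n_samples=600, seed=4)
        hmc_mean = post.flat().mean(axis=0)
        hmc_sd = post.flat().std(axis=0)

        nw = max(2 * dim + 2, 64)
        rng = np.random.default_rng(0)
        p0 = hmc_mean + 0.5 * hmc_sd * rng.standard_normal((nw, dim))
        sampler = emcee.EnsembleSampler(nw, dim, logp)
        state = sampler.run_mcmc(p0, 1500, progress=False)
        chain = sampler.get_chain(discard=700, flat=True)
        em_mean = chain.mean(axis=0)
        # agree within a third of a posterior SD on every coordinate
        assert np.all(np.abs(em_mean - hmc_mean) < 0.35 * hmc_sd + 0.02)


class TestModelCompare:
    def test_self_comparison_is_zero(self, desk_fit):
        cmp = M.model_compare({"a": desk_fit, "b": desk_fit})
        assert cmp["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-6)

    def test_generative_family_preferred(self):
        """Data generated under the Gompertz-Fox trajectory: LOO should prefer the
        fox fit over Schaefer in a majority of replicates."""
        design = DatasetDesign(n_reserve=60, n_remote=30, n_fished=60, n_jurisdictions=4)
        wins = 0
        reps = 3
        for rep in range(reps):
            table, _ = simulate_dataset(design=design, seed=100 + rep, model=FOX)
            data = M.prepare_data(table)
            fits = {
                "fox": M.fit(data, FOX, n_chains=2, n_warmup=300, n_samples=300, seed=rep),
                "schaefer": M.fit(data, SurplusModel.schaefer(), n_chains=2, n_warmup=300,
                                  n_samples=300, seed=rep),
            }
            cmp = M.model_compare(fits)
            if cmp.index[0] == "fox":
                wins += 1
        assert wins >= 2

    def test_mismatched_observations_rejected(self, desk_fit, tiny_design):
        table, _ = simulate_dataset(design=tiny_design, seed=3)
        other = M.fit(M.prepare_data(table), n_chains=2, n_warmup=100, n_samples=100, seed=0)
        with pytest.raises(ValueError):
            M.model_compare({"a": desk_fit, "b": other})

    def test_corrupted_likelihood_ranked_last(self, desk_fit):
        bad = M.PosteriorDraws(desk_fit.theta, desk_fit.jurisdictions, desk_fit.model,
                               desk_fit.spec, log_lik=desk_fit.log_lik.copy())
        bad.log_lik[:, :, 0] = -1e30
        cmp = M.model_compare({"good": desk_fit, "bad": bad})
        assert cmp.index[-1] == "bad"


class TestSelectReserveYear:
    def test_one_row_per_reserve(self, desk_table):
        doubled = pd.concat([desk_table, desk_table[desk_table["category"] == "reserve"]],
                            ignore_index=True)
        out = M.select_reserve_year(doubled, seed=0)
        res = out[out["category"] == "reserve"]
        assert res["site_id"].is_unique
        # non-reserve rows untouched
        assert (out["category"] != "reserve").sum() == (desk_table["category"] != "reserve").sum()

    def test_seeded_choice_is_reproducible(self, desk_table):
        doubled = pd.concat([desk_table, desk_table[desk_table["category"] == "reserve"]],
                            ignore_index=True)
        a = M.select_reserve_year(doubled, seed=3)
        b = M.select_reserve_year(doubled, seed=3)
        pd.testing.assert_frame_equal(a, b)
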