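"""Likelihood, priors, diagnostics, sampler correctness and model ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from gannetpop import _pack as pk
from gannetpop import inference as inf
from gannetpop.modelspec import ModelSpec, NULL_MODEL, enumerate_models
from gannetpop.params import DemographicParams


def tiny_data(census_rows, fec_rows, years=(2000, 2003), n_colonies=1,
              K=10_000.0, seed=0):
    """FitData on a miniature window with externally supplied observations."""
    from gannetpop.synthetic import generate_climate
    from gannetpop.covariates import standardize

    clim = standardize(generate_climate(n_colonies=n_colonies, seed=seed),
                       window=(1900, 2016))
    colonies = clim.colonies()
    census = pd.DataFrame(census_rows, columns=["colony_id", "year", "aos_count"])
    fec = pd.DataFrame(fec_rows, columns=["colony_id", "year", "nests", "chicks"])
    return inf.prepare_data(census, fec, clim, colonies,
                            range(years[0], years[1] + 1),
                            np.full(n_colonies, K))


class TestLogLikelihood:
    def test_no_observations_gives_zero(self):
        data = tiny_data([], [])
        params = DemographicParams(K=data.K_expert)
        layout = pk.build_layout(1, data.n_steps, NULL_MODEL)
        theta = pk.pack_theta(params, NULL_MODEL, layout,
                              eps=np.zeros(data.n_steps), logP0=np.log([500.0]))
        assert inf.log_likelihood(theta, data, NULL_MODEL, params) == 0.0

    def test_single_exact_census_point_is_standard_normal_density(self):
        """A census equal to the latent size with sigma_obs = 1 contributes
        the Normal(0, 1) log-density at zero."""
        data = tiny_data([("colony_0", 2000, 500)], [])
        params = DemographicParams(K=data.K_expert, sigma_obs=1.0)
        layout = pk.build_layout(1, data.n_steps, NULL_MODEL)
        theta = pk.pack_theta(params, NULL_MODEL, layout,
                              eps=np.zeros(data.n_steps), logP0=np.log([500.0]))
        ll = inf.log_likelihood(theta, data, NULL_MODEL, params)
        assert ll == pytest.approx(stats.norm.logpdf(0.0), abs=1e-12)

    def test_three_point_toy_matches_scalar_density_oracle(self):
        """Hand-summed scipy densities reproduce the engine to 1e-9."""
        data = tiny_data([("colony_0", 2000, 450), ("colony_0", 2001, 520)],
                         [("colony_0", 2001, 100, 72)])
        params = DemographicParams(K=data.K_expert, sigma_obs=0.2, alpha0=0.9)
        layout = pk.build_layout(1, data.n_steps, NULL_MODEL)
        eps = np.array([0.1, -0.2, 0.05])
        theta = pk.pack_theta(params, NULL_MODEL, layout, eps=eps,
                              logP0=np.log([480.0]))
        ll = inf.log_likelihood(theta, data, NULL_MODEL, params)

        P, _, bmat, _ = pk.simulate_trajectory(params, NULL_MODEL, data.X, eps,
                                               np.array([480.0]))
        expected = (stats.norm.logpdf(np.log(450), np.log(P[0, 0]), 0.2)
                    + stats.norm.logpdf(np.log(520), np.log(P[1, 0]), 0.2)
                    + stats.binom.logpmf(72, 100, bmat[1, 0]))
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_zero_count_handled_via_half(self):
        data = tiny_data([("colony_0", 2000, 0)], [])
        assert data.cobs_logy[0] == pytest.approx(np.log(0.5))


class TestLogPrior:
    def _theta(self, data, params, spec, **kw):
        layout = pk.build_layout(1, data.n_steps, spec)
        return layout, pk.pack_theta(params, spec, layout,
                                     eps=np.zeros(data.n_steps),
                                     logP0=np.log([500.0]), **kw)

    def test_standard_normal_contribution_of_linear_coefficients(self):
        spec = ModelSpec(id="m1.10", fecundity_terms=(("SST", 1),))
        data = tiny_data([], [])
        base = DemographicParams(K=data.K_expert, alpha_lin={"SST": 0.0})
        moved = base.with_(alpha_lin={"SST": 1.3})
        _, th0 = self._theta(data, base, spec)
        _, th1 = self._theta(data, moved, spec)
        diff = (inf.log_prior(th1, data, spec, moved)
                - inf.log_prior(th0, data, spec, base))
        assert diff == pytest.approx(stats.norm.logpdf(1.3) - stats.norm.logpdf(0.0),
                                     abs=1e-10)

    def test_gamma_prior_on_parabola_magnitudes(self):
        """Gamma(1, 1) = Exponential(1): log-density at 0.848 is -0.848."""
        spec = ModelSpec(id="q", fecundity_terms=(("nsAT", 1), ("nsAT", 2)))
        data = tiny_data([], [])
        a = DemographicParams(K=data.K_expert, alpha_lin={"nsAT": 1.0},
                              alpha_quad={"nsAT": 0.848})
        b = a.with_(alpha_quad={"nsAT": 0.0})
        _, tha = self._theta(data, a, spec)
        _, thb = self._theta(data, b, spec)
        diff = inf.log_prior(tha, data, spec, a) - inf.log_prior(thb, data, spec, b)
        assert diff == pytest.approx(-0.848, abs=1e-10)

    def test_negative_parabola_magnitude_has_no_support(self):
        spec = ModelSpec(id="q", fecundity_terms=(("nsAT", 1), ("nsAT", 2)))
        data = tiny_data([], [])
        p = DemographicParams(K=data.K_expert, alpha_lin={"nsAT": 1.0})
        layout, th = self._theta(data, p, spec)
        import gannetpop._engine as eng
        th[layout[eng.L_OFF_FQUAD]] = -0.1
        assert inf.log_prior(th, data, spec, p) == -np.inf

    def test_nonpositive_noise_scales_have_no_support(self):
        import gannetpop._engine as eng
        data = tiny_data([], [])
        p = DemographicParams(K=data.K_expert)
        layout, th = self._theta(data, p, NULL_MODEL)
        th[layout[eng.L_OFF_SIGB]] = -0.5
        assert inf.log_prior(th, data, NULL_MODEL, p) == -np.inf


class TestGelmanRubin:
    def test_identical_chains_give_unity(self):
        x = np.random.default_rng(0).normal(size=(1, 200, 2))
        chains = np.repeat(x, 4, axis=0)
        r = inf.gelman_rubin(chains)
        assert np.all(r <= 1.0 + 1e-6)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 300), rng.normal(10, 1, 300)])
        assert inf.gelman_rubin(chains)[0] > 3.0

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 100))
        m, n = chains.shape
        means = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert inf.gelman_rubin(chains)[0] == pytest.approx(expected, rel=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            inf.gelman_rubin(np.zeros((1, 50)))


@pytest.fixture(scope="module")
def conjugate_fit():
    """Forty replicate censuses of one colony-year: the initial log size
    has an (approximately) conjugate normal posterior."""
    rng = np.random.default_rng(4)
    sigma, mu = 0.1, np.log(800.0)
    counts = np.exp(rng.normal(mu, sigma, size=40)).round().astype(int)
    rows = [("colony_0", 2000, int(c)) for c in counts]
    data = tiny_data(rows, [], years=(2000, 2002))
    params = DemographicParams(K=data.K_expert)
    settings = inf.MCMCSettings(chains=4, iters=1200, burnin=500, thin=2, seed=3)
    res = inf.run_mcmc(data, NULL_MODEL, params, settings)
    return res, np.log(counts.astype(float))


class TestSampler:
    def test_conjugate_posterior_recovered(self, conjugate_fit):
        res, logy = conjugate_fit
        summ = inf.summarize(res)
        post = summ.params.set_index("name").loc["logP0_colony_0"]
        se_ref = logy.std(ddof=1) / np.sqrt(logy.size)
        assert post["median"] == pytest.approx(logy.mean(), abs=3 * se_ref)
        # posterior spread of the mean parameter is near sigma/sqrt(k)
        width = (post["hi95"] - post["lo95"]) / (2 * 1.96)
        assert 0.5 * se_ref < width < 2.0 * se_ref

    def test_wellmixed_target_passes_rhat(self, conjugate_fit):
        res, _ = conjugate_fit
        summ = inf.summarize(res)
        assert summ.params.set_index("name").loc["logP0_colony_0", "rhat"] < 1.05

    def test_same_seed_reproduces_draws(self):
        data = tiny_data([("colony_0", 2000, 300)], [("colony_0", 2001, 50, 30)])
        params = DemographicParams(K=data.K_expert)
        settings = inf.MCMCSettings(chains=2, iters=400, burnin=200, thin=2, seed=9)
        a = inf.run_mcmc(data, NULL_MODEL, params, settings)
        b = inf.run_mcmc(data, NULL_MODEL, params, settings)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_interval_ordering_in_summary(self, small_fit):
        summ = inf.summarize(small_fit)
        p = summ.params
        assert (p.lo95 <= p["median"] + 1e-12).all()
        assert (p["median"] <= p.hi95 + 1e-12).all()

    def test_latent_medians_track_truth(self, small_fit, small_study):
        """Latent colony-size posteriors cover the generating trajectory."""
        summ = inf.summarize(small_fit)
        truth = small_study.latent.set_index(["colony", "year"]).P
        obs = set(zip(small_study.census.colony_id, small_study.census.year))
        lat = summ.latent.set_index(["colony", "year"])
        hits, total = 0, 0
        for (colony, year) in obs:
            row = lat.loc[(colony, year)]
            total += 1
            if abs(row["median"] - truth.loc[(colony, year)]) <= 2 * max(row["sd"], 1e-9):
                hits += 1
        assert hits / total >= 0.9


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self, small_fit):
        import copy
        res = copy.copy(small_fit)
        one = small_fit.draws[0, -1]
        res.draws = np.tile(one, (2, 40, 1))
        ll = inf.log_likelihood(one, res.data, res.spec, res.template)
        res.loglik = np.full((2, 40), ll)
        d, dbar, pd_ = inf.dic(res)
        assert pd_ == pytest.approx(0.0, abs=1e-8)
        assert d == pytest.approx(-2 * ll, abs=1e-8)

    def test_too_few_draws_rejected(self, small_fit):
        import copy
        res = copy.copy(small_fit)
        res.draws = small_fit.draws[:, :10]
        res.loglik = small_fit.loglik[:, :10]
        with pytest.raises(ValueError, match="30 retained draws"):
            inf.dic(res)

    def test_effective_parameters_near_free_mean_count(self, conjugate_fit):
        """Normal toy: pD is close to the number of weakly- and strongly-
        identified quantities actually informed by the data (~2 here:
        the initial log size and the observation SD)."""
        res, _ = conjugate_fit
        _, _, pd_ = inf.dic(res)
        assert 0.5 < pd_ < 5.0


class TestEnumerateAndSelect:
    def test_suite_counts_and_ids(self):
        models = enumerate_models()
        assert len(models) == 47
        ids = [m.id for m in models]
        assert len(set(ids)) == 47
        assert "m0.00" in ids and "m2.31" in ids and "m3.3^251" in ids

    def test_best_published_structure_terms(self):
        m = {m.id: m for m in enumerate_models()}["m3.3^251"]
        assert m.covariates("fecundity") == [("nsAT", True), ("prec", False)]
        assert m.covariates("recruitment") == [("SST", False)]

    def test_null_model_is_interceptonly(self):
        m = {m.id: m for m in enumerate_models()}["m0.00"]
        assert m.fecundity_terms == () and m.recruitment_terms == ()

    def test_quadratic_requires_linear_term(self):
        with pytest.raises(ValueError, match="lack their linear term"):
            ModelSpec(id="bad", fecundity_terms=(("nsAT", 2),))

    def test_selection_table_null_delta_zero_and_order_invariant(self, small_study):
        data = inf.prepare_data(small_study.census, small_study.fecundity,
                                small_study.climate, small_study.colonies,
                                small_study.years, small_study.params_true.K)
        specs = [NULL_MODEL, small_study.spec_true]
        settings = inf.MCMCSettings(chains=2, iters=600, burnin=300, thin=3, seed=2)
        tab = inf.select_model(data, specs, small_study.params_true, settings)
        assert tab.loc[tab.model == "m0.00", "dDIC"].iloc[0] == 0.0
        assert set(tab.columns) >= {"model", "DIC", "dDIC", "converged"}
        tab2 = inf.select_model(data, specs[::-1], small_study.params_true, settings)
        a = tab.set_index("model").DIC
        b = tab2.set_index("model").DIC
        np.testing.assert_allclose(a.loc[a.index.sort_values()],
                                   b.loc[b.index.sort_values()], rtol=1e-12)

    def test_selection_requires_null(self, small_study):
        data = inf.prepare_data(small_study.census, small_study.fecundity,
                                small_study.climate, small_study.colonies,
                                small_study.years, small_study.params_true.K)
        with pytest.raises(ValueError, match="null"):
            inf.select_model(data, [small_study.spec_true], small_study.params_true)


class TestValidation:
    def test_chicks_exceeding_nests_rejected(self, small_study):
        bad = small_study.fecundity.copy()
        bad.loc[bad.index[0], "chicks"] = bad.loc[bad.index[0], "nests"] + 1
        with pytest.raises(ValueError, match="chicks > nests"):
            inf.prepare_data(small_study.census, bad, small_study.climate,
                             small_study.colonies, small_study.years,
                             small_study.params_true.K)

    def test_unknown_colony_rejected(self, small_study):
        bad = small_study.census.copy()
        bad.loc[bad.index[0], "colony_id"] = "atlantis"
        with pytest.raises(ValueError, match="unknown colony"):
            inf.prepare_data(bad, small_study.fecundity, small_study.climate,
                             small_study.colonies, small_study.years,
                             small_study.params_true.K)

    def test_noncontiguous_window_rejected(self, small_study):
        with pytest.raises(ValueError, match="contiguous"):
            inf.prepare_data(small_study.census, small_study.fecundity,
                             small_study.climate, small_study.colonies,
                             [2000, 2002, 2004], small_study.params_true.K)
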