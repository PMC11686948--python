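"""Closed-form demographic rates and the one-step metapopulation update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from gannetpop.demography import (capacity_dominance, fecundity_rate,
                                  hpai_survival, marine_carrying_capacity,
                                  marine_dd, movement_weights, recruitment_rate,
                                  step_metapopulation, terrestrial_dd)
from gannetpop.modelspec import ModelSpec
from gannetpop.params import (COVARIATES, ColonyState, DemographicParams,
                              equilibrium_prebreeders)

NULL = ModelSpec(id="m0.00")


def zero_climate(n=1):
    return {c: np.zeros(n) for c in COVARIATES}


class TestFecundity:
    def test_peak_at_parabola_vertex_matches_published_value(self, best_model_params,
                                                             best_model_spec):
        """At the nsAT optimum with mean precipitation, fecundity peaks at 0.84."""
        x_star = 1.546 / (2 * 0.848)
        x = {"nsAT": x_star, "prec": 0.0}
        b = fecundity_rate(x, best_model_params, best_model_spec, eps_t=0.0)
        assert round(float(b), 2) == 0.84

    def test_intercept_only_evaluation(self, best_model_params, best_model_spec):
        b = fecundity_rate({"nsAT": 0.0, "prec": 0.0}, best_model_params,
                           best_model_spec)
        assert b == pytest.approx(expit(0.969), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(d=st.floats(0.01, 3.0))
    def test_parabola_symmetry_around_vertex(self, d, best_model_params,
                                             best_model_spec):
        x_star = 1.546 / (2 * 0.848)
        p, s = best_model_params, best_model_spec
        lo = fecundity_rate({"nsAT": x_star - d, "prec": 0.0}, p, s)
        hi = fecundity_rate({"nsAT": x_star + d, "prec": 0.0}, p, s)
        assert lo == pytest.approx(hi, rel=1e-9)

    def test_unknown_covariate_in_spec_is_configuration_error(self, best_model_params):
        bad = ModelSpec(id="x", fecundity_terms=(("SLM", 1),))
        with pytest.raises(KeyError):
            fecundity_rate({"nsAT": 0.0}, best_model_params, bad)

    def test_annual_noise_shifts_logit(self, best_model_params, best_model_spec):
        x = {"nsAT": 0.0, "prec": 0.0}
        b0 = fecundity_rate(x, best_model_params, best_model_spec, eps_t=0.0)
        b1 = fecundity_rate(x, best_model_params, best_model_spec, eps_t=0.5)
        assert logit(b1) - logit(b0) == pytest.approx(0.5, abs=1e-9)


class TestMarineDD:
    def test_intercept_only_evaluation(self, best_model_params, best_model_spec):
        eta = marine_dd({"SST": 0.0}, best_model_params, best_model_spec)
        assert eta == pytest.approx(expit(-6.619), rel=1e-12)
        assert eta == pytest.approx(1.33e-3, rel=0.01)

    def test_monotone_increasing_in_sst(self, best_model_params, best_model_spec):
        z = np.linspace(-3, 3, 25)
        eta = np.array([marine_dd({"SST": v}, best_model_params, best_model_spec)
                        for v in z])
        assert np.all(np.diff(eta) > 0)

    def test_vanishes_in_cold_limit(self, best_model_params, best_model_spec):
        eta = marine_dd({"SST": -60.0}, best_model_params, best_model_spec)
        assert 0 < eta < 1e-20


class TestTerrestrialDD:
    def test_half_re_cancels_log_term(self):
        p = DemographicParams(re=0.5, alpha_const=100.0, K=np.array([10_000.0]))
        assert terrestrial_dd(10_000.0, p) == pytest.approx(0.01, abs=1e-15)

    def test_scalar_evaluation_oracle(self):
        p = DemographicParams(re=0.3, alpha_const=100.0, K=np.array([1_000.0]))
        expected = (100 - np.log(0.3 / 0.7)) / 1_000
        assert terrestrial_dd(1_000.0, p) == pytest.approx(expected, rel=1e-12)

    def test_inverse_proportionality_in_K(self):
        p = DemographicParams(re=0.3)
        assert terrestrial_dd(2_000.0, p) == pytest.approx(
            terrestrial_dd(1_000.0, p) / 2, rel=1e-12)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            terrestrial_dd(0.0, DemographicParams())


class TestRecruitment:
    def test_saturates_at_one_for_empty_colony(self):
        p = DemographicParams(alpha_const=100.0)
        r = recruitment_rate(0.0, 0.01, 0.001, p)
        assert abs(r - 1.0) <= 1e-12

    def test_equals_re_at_binding_capacity(self):
        """Algebraic identity: r(P = C) = re when the marine term binds."""
        p = DemographicParams(re=0.3, alpha_const=100.0)
        eta = 1.5e-3
        C = marine_carrying_capacity(eta, p)
        r = recruitment_rate(C, 1e-6, eta, p)
        assert r == pytest.approx(0.3, abs=1e-9)

    def test_midpoint_evaluation_oracle(self):
        p = DemographicParams(alpha_const=100.0)
        r = recruitment_rate(10_000.0, 0.01, 0.001, p)
        assert r == pytest.approx(0.5, abs=1e-12)

    def test_strictly_decreasing_in_colony_size(self):
        # range chosen so the logistic is not saturated to 0/1 in floats
        p = DemographicParams()
        P = np.linspace(14_000, 26_000, 40)
        r = recruitment_rate(P, 0.005, 0.001, p)
        assert np.all(np.diff(r) < 0)
        full = recruitment_rate(np.linspace(0, 3e4, 50), 0.005, 0.001, p)
        assert np.all(np.diff(full) <= 0)

    def test_negative_P_rejected(self):
        with pytest.raises(ValueError):
            recruitment_rate(-1.0, 0.01, 0.001, DemographicParams())


class TestMarineCapacity:
    def test_round_trip_with_terrestrial_dd(self):
        p = DemographicParams(re=0.3)
        for K in np.geomspace(10, 1e6, 13):
            eta = terrestrial_dd(K, p)
            assert marine_carrying_capacity(eta, p) == pytest.approx(K, rel=1e-9)

    def test_scalar_evaluation_oracle(self):
        p = DemographicParams(re=0.5, alpha_const=100.0)
        C = marine_carrying_capacity(1.33e-3, p)
        assert C == pytest.approx(100.0 / 1.33e-3, rel=1e-12)
        assert C == pytest.approx(7.5e4, rel=0.01)

    def test_inverse_proportionality_in_eta(self):
        p = DemographicParams()
        assert marine_carrying_capacity(2e-3, p) == pytest.approx(
            marine_carrying_capacity(1e-3, p) / 2, rel=1e-12)

    def test_nonpositive_eta_rejected(self):
        with pytest.raises(ValueError):
            marine_carrying_capacity(0.0, DemographicParams())

    def test_capacity_decreases_with_sst(self, best_model_params, best_model_spec):
        """Warming SST raises eta, hence shrinks the marine capacity."""
        z = np.linspace(-2, 2, 21)
        C = np.array([marine_carrying_capacity(
            marine_dd({"SST": v}, best_model_params, best_model_spec),
            best_model_params) for v in z])
        assert np.all(np.diff(C) < 0)


class TestCapacityDominance:
    @pytest.mark.parametrize("C,K,diff,label", [
        (30_000.0, 30_000.0, 0.0, "terrestrial"),   # tie rule
        (50_000.0, 30_000.0, 20_000.0, "terrestrial"),
        (10_000.0, 30_000.0, -20_000.0, "marine"),
    ])
    def test_sign_and_label(self, C, K, diff, label):
        d, lab = capacity_dominance(C, K)
        assert d == diff and lab == label


class TestHpaiSurvival:
    def test_affected_colonies_get_measured_survival(self):
        assert hpai_survival("affected", DemographicParams()) == 0.455

    def test_unaffected_keep_regular_survival(self):
        p = DemographicParams(phi_ad=0.94)
        assert hpai_survival("unaffected", p) == 0.94

    def test_unknown_status_draws_in_prior_range(self):
        rng = np.random.default_rng(0)
        p = DemographicParams()
        draws = [hpai_survival("unknown", p, rng) for _ in range(200)]
        assert all(0.455 <= d <= 0.94 for d in draws)

    def test_unknown_status_string_rejected(self):
        with pytest.raises(ValueError):
            hpai_survival("maybe", DemographicParams())

    def test_unknown_without_rng_rejected(self):
        with pytest.raises(ValueError):
            hpai_survival("unknown", DemographicParams())


class TestStep:
    def _state(self, n=3):
        P = np.array([1000.0, 5000.0, 20_000.0][:n])
        J = np.full((n, 5), 200.0)
        return ColonyState(P, J, 2000)

    def test_no_survival_empties_the_metapopulation(self):
        p = DemographicParams(phi_ad=0.0, phi_juv=0.0, K=np.full(3, 1e4))
        nxt = step_metapopulation(self._state(), zero_climate(3), p, NULL)
        assert np.all(nxt.P == 0) and np.all(nxt.J == 0)

    def test_pure_adult_survival_when_b_and_r_zero(self):
        """With fecundity ~0 and recruitment ~0, P just decays by phi_ad."""
        # b -> 0 via a huge negative intercept; r -> 0 via eta ~ 1 with a
        # tiny steepness constant, so alpha - eta*P is hugely negative
        p = DemographicParams(alpha0=-500.0, beta0=30.0, alpha_const=1e-6,
                              phi_ad=0.9, K=np.full(3, 1e12))
        s = self._state()
        nxt = step_metapopulation(s, zero_climate(3), p, NULL)
        assert nxt.P == pytest.approx(0.9 * s.P, rel=1e-12)

    def test_movement_conserves_prebreeders(self):
        p = DemographicParams(K=np.full(3, 1e4), rho=3.0)
        P = self._state().P
        W = movement_weights(P, p.rho)
        Q = p.phi_juv * self._state().J[:, -1]
        arrivals = Q @ W
        assert arrivals.sum() == pytest.approx(Q.sum(), rel=1e-12)

    def test_year_advances_and_dimensions_fixed(self):
        p = DemographicParams(K=np.full(3, 1e4))
        s = self._state()
        nxt = step_metapopulation(s, zero_climate(3), p, NULL)
        assert nxt.year == 2001 and nxt.P.shape == s.P.shape and nxt.J.shape == s.J.shape

    def test_mismatched_climate_rejected(self):
        p = DemographicParams(K=np.full(3, 1e4))
        with pytest.raises(ValueError):
            step_metapopulation(self._state(), zero_climate(2), p, NULL)

    def test_hpai_shock_applies_only_in_2022(self):
        p = DemographicParams(alpha0=-500.0, beta0=30.0, alpha_const=1e-6,
                              K=np.full(2, 1e12), phi_ad=0.94)
        P = np.array([1000.0, 1000.0])
        s = ColonyState(P, np.zeros((2, 5)), 2022)
        nxt = step_metapopulation(s, zero_climate(2), p, NULL,
                                  hpai_status=["affected", "unaffected"])
        assert nxt.P == pytest.approx([455.0, 940.0], rel=1e-12)
        s2 = ColonyState(P, np.zeros((2, 5)), 2021)
        nxt2 = step_metapopulation(s2, zero_climate(2), p, NULL,
                                   hpai_status=["affected", "unaffected"])
        assert nxt2.P == pytest.approx([940.0, 940.0], rel=1e-12)

    def test_philopatry_keeps_recruits_home_when_rho_large(self):
        W = movement_weights(np.array([1000.0, 1000.0]), rho=1e9)
        assert W[0, 0] > 0.999 and W[1, 1] > 0.999


class TestStationarity:
    def test_moderate_steepness_converges_below_binding_capacity(self):
        """Constant climate, no noise, gentle recruitment decline: the
        5-colony system converges to a stationary point under min(C, K)."""
        from gannetpop._pack import simulate_trajectory

        n, T = 5, 600
        params = DemographicParams(
            alpha0=0.969, alpha_lin={"nsAT": 1.546, "prec": 0.139},
            alpha_quad={"nsAT": 0.848}, beta0=-6.0, beta_lin={"SST": 0.881},
            sigma_b=0.0, alpha_const=20.0, K=np.geomspace(5e3, 3e5, n))
        spec = ModelSpec(id="m3.3^251",
                         fecundity_terms=(("nsAT", 1), ("nsAT", 2), ("prec", 1)),
                         recruitment_terms=(("SST", 1),))
        X = np.zeros((T, n, 5))
        P, _, _, _ = simulate_trajectory(params, spec, X, np.zeros(T),
                                         P0=0.05 * params.K)
        eta = marine_dd({"SST": 0.0}, params, spec)
        C = marine_carrying_capacity(eta, params)
        cap = np.minimum(params.K, C)
        # stationary: per-capita gains and losses balance year to year
        assert np.max(np.abs(P[-1] / P[-2] - 1)) < 1e-8
        # equilibrium sits at/below capacity up to the recruitment tail:
        # immigration from conspecific attraction can push a receiving
        # colony slightly into the tail of the recruitment logistic
        assert np.all(P[-1] <= cap * 1.03)

    def test_steep_default_threshold_cycles_tightly_around_capacity(self):
        """At the default steepness (alpha = 100) the delayed recruitment
        pipeline overcompensates: the attractor is a bounded cycle around
        min(C, K) rather than a point, and excursions above capacity stay
        within the recruitment-tail tolerance."""
        from gannetpop._pack import simulate_trajectory

        n, T = 5, 600
        params = DemographicParams(
            alpha0=0.969, beta0=-6.0, sigma_b=0.0, K=np.geomspace(5e3, 3e5, n))
        X = np.zeros((T, n, 5))
        P, _, _, _ = simulate_trajectory(params, NULL, X, np.zeros(T),
                                         P0=0.05 * params.K)
        eta = marine_dd({}, params, NULL)
        C = marine_carrying_capacity(eta, params)
        cap = np.minimum(params.K, C)
        tail = P[-100:]
        assert np.all(tail.max(axis=0) <= 1.25 * cap)
        np.testing.assert_allclose(tail.mean(axis=0), cap, rtol=0.10)

    def test_fixed_inputs_are_bit_reproducible(self):
        from gannetpop._pack import simulate_trajectory

        rng = np.random.default_rng(5)
        params = DemographicParams(K=np.array([1e4, 2e4]))
        X = rng.normal(size=(20, 2, 5))
        eps = rng.normal(0, 0.3, 20)
        P1, _, _, _ = simulate_trajectory(params, NULL, X, eps, np.array([500.0, 800.0]))
        P2, _, _, _ = simulate_trajectory(params, NULL, X, eps, np.array([500.0, 800.0]))
        assert np.array_equal(P1, P2)


class TestEngineParity:
    def test_python_step_matches_numba_trajectory(self, best_model_params,
                                                  best_model_spec):
        """The readable stepper and the fast kernel are the same process."""
        from gannetpop._pack import simulate_trajectory

        rng = np.random.default_rng(3)
        n, T = 4, 30
        params = best_model_params.with_(K=np.geomspace(8e3, 2e5, n))
        X = rng.normal(size=(T, n, 5))
        eps = rng.normal(0, 0.3, T)
        P0 = np.geomspace(500, 8000, n)
        P, Jf, _, _ = simulate_trajectory(params, best_model_spec, X, eps, P0)

        b0 = fecundity_rate({c: X[0, :, i] for i, c in enumerate(COVARIATES)},
                            params, best_model_spec, eps[0])
        state = ColonyState(P0, equilibrium_prebreeders(P0, b0, params), 0)
        for t in range(T):
            clim = {c: X[t, :, i] for i, c in enumerate(COVARIATES)}
            state = step_metapopulation(state, clim, params, best_model_spec,
                                        eps_t=eps[t])
        np.testing.assert_allclose(state.P, P[-1], rtol=1e-12)
        np.testing.assert_allclose(state.J, Jf, rtol=1e-9, atol=1e-9)
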