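"""Leslie projection, stationary age distribution, predicted observables."""

import numpy as np
import pytest

from harpseal_ipm.environment import EnvironmentSeries
from harpseal_ipm.hazards import (age_log_hazard, annual_survival,
                                  density_env_log_hazard, fecundity,
                                  ice_hazard)
from harpseal_ipm.params import ModelParams, YearEffects
from harpseal_ipm.projection import (advance, build_matrix, partition_deaths,
                                     q_schedules, run_process_model,
                                     stationary_age_distribution,
                                     struck_loss_q)


def _flat_env(n_years: int, start: int = 1951, nlci=0.0, ic=0.0):
    years = np.arange(start, start + n_years)
    return EnvironmentSeries(
        years=years,
        ic=np.full((3, n_years), float(ic)),
        nlci=np.full(n_years, float(nlci)),
        p=np.full((3, n_years), 1 / 3))


class TestBuildMatrix:
    def test_pure_age_advance_conserves_total(self, rng):
        n = rng.uniform(0, 100, 8)
        m = build_matrix(np.ones(8), np.zeros(8), 1.0)
        out = m @ n
        assert out.sum() == pytest.approx(n.sum())
        assert out[0] == 0.0
        assert out[-1] == pytest.approx(n[-2] + n[-1])

    def test_uniform_survival_contracts_total(self, rng):
        n = rng.uniform(0, 100, 8)
        m = build_matrix(np.full(8, 0.8), np.zeros(8), 1.0)
        assert (m @ n).sum() == pytest.approx(0.8 * n.sum())

    def test_matrix_multiply_matches_bookkeeping_loop(self, rng):
        for _ in range(10):
            a = 12
            sa = rng.uniform(0.3, 1.0, a)
            f = rng.uniform(0.0, 1.0, a)
            s0 = rng.uniform(0.2, 1.0)
            n = rng.uniform(0, 1e5, a)
            m = build_matrix(sa, f, s0)
            # independent age-by-age bookkeeping
            expected = np.zeros(a)
            expected[0] = 0.5 * s0 * np.dot(f, n)
            for i in range(1, a):
                expected[i] = sa[i - 1] * n[i - 1]
            expected[-1] += sa[-1] * n[-1]
            assert np.allclose(m @ n, expected)
            assert np.allclose(advance(n, sa, f, s0), expected)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(np.array([1.2, 0.5]), np.zeros(2), 0.9)


class TestStationaryAgeDistribution:
    def test_matches_eigen_decomposition(self, rng):
        sa = rng.uniform(0.5, 0.95, 3)
        m = build_matrix(sa, np.array([0.0, 0.6, 0.9]), 0.7)
        sad = stationary_age_distribution(m)
        vals, vecs = np.linalg.eig(m)
        lead = np.argmax(vals.real)
        expected = np.abs(vecs[:, lead].real)
        expected /= expected.sum()
        assert np.allclose(sad, expected, atol=1e-8)

    def test_nonnegative_unit_sum(self, rng):
        m = build_matrix(rng.uniform(0.3, 1.0, 6),
                         rng.uniform(0, 1, 6), 0.5)
        sad = stationary_age_distribution(m)
        assert np.all(sad >= 0)
        assert sad.sum() == pytest.approx(1.0)

    def test_scaled_identity_returns_start_distribution(self):
        # every vector is stationary; iteration stops at the uniform start
        sad = stationary_age_distribution(0.9 * np.eye(3))
        assert np.allclose(sad, 1 / 3)


class TestProcessModel:
    def test_initial_vector_sums_to_n0(self):
        params = ModelParams(n0=1e6)
        state = run_process_model(params, _flat_env(1), n_ages=12)
        assert state.total[0] == pytest.approx(1e6)
        assert np.allclose(state.n[:, 0] / 1e6, state.sad)

    def test_constant_schedule_converges_to_dominant_eigenvalue(self):
        # density independence and a flat environment give a constant matrix
        params = ModelParams(phi_s=0.0, phi_f=0.0, delta=0.0)
        state = run_process_model(params, _flat_env(60), n_ages=12)
        m = build_matrix(state.rates.sa[:, 0], state.rates.f[:, 0],
                         state.rates.s0[0])
        lam = np.max(np.linalg.eigvals(m).real)
        observed = state.total[-1] / state.total[-2]
        assert observed == pytest.approx(lam, abs=1e-6)

    def test_linearity_in_n0_without_density_dependence(self):
        base = dict(phi_s=0.0, phi_f=0.0)
        s1 = run_process_model(ModelParams(n0=1e6, **base), _flat_env(20),
                               n_ages=12)
        s2 = run_process_model(ModelParams(n0=2e6, **base), _flat_env(20),
                               n_ages=12)
        assert np.allclose(s2.n, 2 * s1.n, rtol=1e-10)

    def test_trajectory_bit_reproducible(self):
        params = ModelParams()
        env = _flat_env(30)
        a = run_process_model(params, env)
        b = run_process_model(params, env)
        assert np.array_equal(a.n, b.n)

    def test_inlined_rates_match_hazard_module_operations(self):
        # the projection loop inlines the hazard math for speed; verify a
        # mid-trajectory year against the module-level operations
        params = ModelParams(sigma_s=0.2, sigma_f=0.1,
                             sigma_h=np.full(4, 0.3))
        rng = np.random.default_rng(5)
        env = _flat_env(10)
        env.nlci = rng.normal(0, 1, 10)
        env.ic = rng.normal(0, 1, (3, 10))
        effects = YearEffects.draw(10, params, rng)
        state = run_process_model(params, env, effects, n_ages=12)
        t = 6
        n_sc = state.total[t] * params.density_scale
        gd0, gda = density_env_log_hazard(
            params.phi_s, params.delta, params.zeta, n_sc, env.nlci[t],
            effects.eps_s[t])
        gamma_a, gamma_0 = age_log_hazard(params.alpha1, params.alpha2,
                                          params.alpha3, params.upsilon, 12)
        h0 = np.exp(gamma_0 + gd0)
        ha = np.exp(gamma_a + gda)
        hic = ice_hazard(params.psi0, params.psi, env.ic[:, t], env.p[:, t])
        s0, sa = annual_survival(h0, hic, np.exp(effects.gamma_h0[:, t]),
                                 ha, np.exp(effects.gamma_ha[:, t]))
        f = fecundity(params, state.total[t - 1] * params.density_scale,
                      env.nlci[t - 1], effects.eps_f[t], 12)
        assert state.hazards.h0[t] == pytest.approx(h0, rel=1e-12)
        assert np.allclose(state.hazards.ha[:, t], ha, rtol=1e-12)
        assert state.hazards.hic[t] == pytest.approx(hic, rel=1e-12)
        assert state.rates.s0[t] == pytest.approx(s0, rel=1e-12)
        assert np.allclose(state.rates.sa[:, t], sa, rtol=1e-12)
        assert np.allclose(state.rates.f[:, t], f, rtol=1e-12)


class TestPredictedObservables:
    def test_newborn_survival_limits(self):
        env = _flat_env(5)
        births_adjusted = {}
        for pi in (1e-9, 0.999999999):
            state = run_process_model(ModelParams(pi=pi), env, n_ages=12)
            births_adjusted[pi] = state.yoy_prd[2] / state.births[2]
        assert births_adjusted[1e-9] == pytest.approx(1.0, abs=1e-6)
        state = run_process_model(ModelParams(pi=0.999999999), env, n_ages=12)
        assert births_adjusted[0.999999999] == pytest.approx(
            state.rates.s0[2], rel=1e-6)

    def test_uniform_adults_give_uniform_agedist(self):
        state = run_process_model(ModelParams(), _flat_env(3), n_ages=12)
        state.n[:, :] = 7.0
        adist = state.agedist_prd(m=5)
        assert adist.shape == (8, 3)
        assert np.allclose(adist, 1 / 8)

    def test_empty_adult_pool_rejected(self):
        state = run_process_model(ModelParams(), _flat_env(3), n_ages=12)
        state.n[4:, 1] = 0.0
        with pytest.raises(ValueError, match="undefined"):
            state.agedist_prd(m=5)


class TestDeathPartition:
    def _state(self, n_years=6):
        params = ModelParams(sigma_h=np.full(4, 0.2))
        rng = np.random.default_rng(8)
        env = _flat_env(n_years, ic=-0.5)
        effects = YearEffects.draw(n_years, params, rng)
        state = run_process_model(params, env, effects, n_ages=12)
        return state

    def test_equal_hazards_split_evenly(self):
        state = self._state()
        h = 0.1
        state.hazards.h0[:] = h
        state.hazards.hic[:] = h
        state.hazards.hh0[:, :] = h
        part = partition_deaths(state, np.ones((4, 6)), np.ones((4, 6)))
        assert np.allclose(part.f_h0, 1 / 6)
        assert np.allclose(part.f_ice, 1 / 6)
        assert np.allclose(part.f_nat0, 1 / 6)

    def test_cause_fractions_sum_to_one(self):
        state = self._state()
        q0, qa = q_schedules(state.years)
        part = partition_deaths(state, q0, qa)
        total = part.f_h0.sum(axis=0) + part.f_ice + part.f_nat0
        assert np.allclose(total, 1.0, atol=1e-12)
        adult_total = part.f_ha.sum(axis=0) \
            + state.hazards.ha / (state.hazards.ha
                                  + state.hazards.hha.sum(axis=0))
        assert np.allclose(adult_total, 1.0, atol=1e-12)

    def test_death_accounting_closes(self):
        state = self._state()
        q0, qa = q_schedules(state.years)
        part = partition_deaths(state, q0, qa)
        births = state.births
        expected = births * (1 - state.rates.s0)
        assert np.allclose(part.yoy_deaths, expected, rtol=1e-9)
        # reported removals never exceed the deaths they derive from
        assert np.all(part.hv0_prd.sum(axis=0) <= part.yoy_deaths + 1e-9)
        assert np.all(part.hva_prd.sum(axis=0)
                      <= part.adult_deaths.sum(axis=0) + 1e-9)


class TestStruckLoss:
    @pytest.mark.parametrize("source,age,year,q", [
        ("canadian", "yoy", 1975, 0.99),
        ("canadian", "yoy", 1983, 0.95),
        ("canadian", "yoy", 2010, 0.95),
        ("greenland", "yoy", 1990, 0.50),
        ("arctic", "yoy", 1960, 0.50),
        ("canadian", "adult", 1990, 0.50),
        ("greenland", "adult", 1955, 0.50),
        ("bycatch", "yoy", 2000, 1.0),
        ("bycatch", "adult", 2000, 1.0),
    ])
    def test_reporting_fractions(self, source, age, year, q):
        assert struck_loss_q(source, age, year) == q

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown removal source"):
            struck_loss_q("norway", "yoy", 1990)
        with pytest.raises(ValueError):
            struck_loss_q("canadian", "pup", 1990)
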