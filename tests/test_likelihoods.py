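"""Observation-model kernels, moments, limits, and joint decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from harpseal_ipm.likelihoods import (JointLikelihood, ObservationSet,
                                      betabinom_logpmf,
                                      dirichlet_multinomial_logpmf,
                                      gamma_logpdf, loglik_agedist,
                                      loglik_pregnancy,
                                      loglik_removal_agesplit,
                                      loglik_removals, loglik_yoy_survey,
                                      nb_size_from_cv, nbinom_logpmf)
from harpseal_ipm.projection import partition_deaths, q_schedules, \
    run_process_model
from harpseal_ipm.synthetic import fixture_small


class TestKernelsAgainstScipy:
    """Every fast gammaln-based kernel must agree with the reference
    scipy.stats implementation."""

    def test_gamma(self, rng):
        x = rng.gamma(5.0, 2.0, 20)
        mean, sd = 12.0, 3.0
        a, b = mean ** 2 / sd ** 2, mean / sd ** 2
        assert np.allclose(gamma_logpdf(x, mean, sd),
                           stats.gamma.logpdf(x, a, scale=1 / b))

    def test_betabinom(self, rng):
        n = 30
        k = rng.integers(0, n + 1, 20)
        a, b = 3.5, 7.2
        assert np.allclose(betabinom_logpmf(k, n, a, b),
                           stats.betabinom.logpmf(k, n, a, b))

    def test_dirichlet_multinomial(self, rng):
        alpha = np.array([2.0, 5.0, 1.5, 8.0])
        counts = rng.multinomial(40, [0.2, 0.3, 0.1, 0.4])
        assert dirichlet_multinomial_logpmf(counts, alpha) == pytest.approx(
            float(stats.dirichlet_multinomial.logpmf(counts, alpha, 40)))

    def test_nbinom(self, rng):
        mu, size = 50.0, 8.0
        k = rng.integers(0, 200, 20)
        p = size / (size + mu)
        assert np.allclose(nbinom_logpmf(k, mu, size),
                           stats.nbinom.logpmf(k, size, p))


class TestSurveyLikelihood:
    def test_implied_gamma_moments(self):
        prd, se = 400_000.0, 40_000.0
        a, b = prd ** 2 / se ** 2, prd / se ** 2
        assert a == pytest.approx(100.0)
        assert b == pytest.approx(2.5e-4)
        assert a / b == pytest.approx(prd)
        assert a / b ** 2 == pytest.approx(se ** 2)

    def test_density_maximized_at_gamma_mode(self):
        prd, se = 400_000.0, 40_000.0
        a, b = prd ** 2 / se ** 2, prd / se ** 2
        grid = np.linspace(0.5 * prd, 1.5 * prd, 20_001)
        ll = loglik_yoy_survey(grid, prd, se)
        mode = (a - 1) / b
        assert grid[np.argmax(ll)] == pytest.approx(mode, rel=1e-3)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            loglik_yoy_survey(-5.0, 100.0, 10.0)
        with pytest.raises(ValueError):
            loglik_yoy_survey(5.0, -100.0, 10.0)


class TestPregnancyLikelihood:
    def test_mean_is_predicted_fecundity(self):
        nf, f, eta = 50, 0.7, 10.0
        k = np.arange(nf + 1)
        pmf = np.exp(loglik_pregnancy(k, nf, f, eta))
        assert pmf.sum() == pytest.approx(1.0)
        assert (k * pmf).sum() / nf == pytest.approx(f)

    def test_overdispersion_factor(self):
        nf, f, eta = 50, 0.7, 10.0
        k = np.arange(nf + 1)
        pmf = np.exp(loglik_pregnancy(k, nf, f, eta))
        var = (k ** 2 * pmf).sum() - ((k * pmf).sum()) ** 2
        binom_var = nf * f * (1 - f)
        assert var / binom_var == pytest.approx((nf + eta) / (1 + eta),
                                                rel=1e-6)

    def test_large_precision_recovers_binomial(self):
        k, nf, f = 31, 50, 0.7
        ll = loglik_pregnancy(k, nf, f, 1e8)
        assert abs(ll - stats.binom.logpmf(k, nf, f)) < 1e-6

    def test_rejects_count_above_sample(self):
        with pytest.raises(ValueError):
            loglik_pregnancy(11, 10, 0.5, 5.0)


class TestAgeCompositionLikelihood:
    def test_large_precision_recovers_multinomial(self):
        counts = np.array([12, 5, 3])
        probs = np.array([0.6, 0.25, 0.15])
        ll = loglik_agedist(counts, probs, 1e8)
        assert abs(ll - stats.multinomial.logpmf(counts, 20, probs)) < 1e-6

    def test_two_class_toy_matches_beta_binomial(self):
        # 2-class Dirichlet-multinomial is exactly a beta-binomial
        counts = np.array([3, 1])
        ll = loglik_agedist(counts, np.array([0.5, 0.5]), 2.0)
        expected = stats.betabinom.logpmf(3, 4, 1.0, 1.0)
        assert ll == pytest.approx(float(expected))

    def test_mean_proportions_unaffected_by_precision(self, rng):
        probs = np.array([0.5, 0.3, 0.2])
        n = 200_000
        for tau in (2.0, 50.0):
            p = rng.dirichlet(tau * probs, size=500)
            counts = np.array([rng.multinomial(40, pi) for pi in p])
            assert np.allclose(counts.mean(axis=0) / 40, probs, atol=0.02)

    def test_empty_counts_warn_and_contribute_zero(self):
        with pytest.warns(RuntimeWarning):
            assert loglik_agedist(np.zeros(3), np.full(3, 1 / 3), 5.0) == 0.0


class TestRemovalsLikelihood:
    def test_size_parameter_arithmetic(self):
        assert nb_size_from_cv(1000.0, 0.1) == pytest.approx(1e6 / 9000)
        assert nb_size_from_cv(1000.0, 0.1) == pytest.approx(111.11, rel=1e-3)

    def test_variance_identity(self):
        mu, cv = 1000.0, 0.1
        size = nb_size_from_cv(mu, cv)
        assert mu + mu ** 2 / size == pytest.approx((cv * mu) ** 2)

    def test_monte_carlo_moments(self):
        mu, cv = 1000.0, 0.1
        size = nb_size_from_cv(mu, cv)
        rng = np.random.default_rng(12)
        draws = rng.negative_binomial(size, size / (size + mu), 1_000_000)
        assert draws.mean() == pytest.approx(mu, rel=0.001)
        assert draws.var() == pytest.approx((cv * mu) ** 2, rel=0.01)

    def test_poisson_fallback_when_underdispersed(self):
        with pytest.warns(RuntimeWarning, match="Poisson"):
            ll = loglik_removals(4.0, 5.0, 0.1)  # (cv*mu)^2 = 0.25 < mu
        assert ll == pytest.approx(float(stats.poisson.logpmf(4, 5.0)))

    def test_negative_count_off_support(self):
        assert loglik_removals(np.array([-3.0]), 100.0, 0.3)[0] == -np.inf


class TestAgeSplitLikelihood:
    def test_pmf_normalizes_over_support(self):
        n, r, kappa = 20, 0.3, 5.0
        k = np.arange(n + 1)
        pmf = np.exp(loglik_removal_agesplit(k, n, r, kappa))
        assert pmf.sum() == pytest.approx(1.0)
        assert (k * pmf).sum() / n == pytest.approx(r)

    def test_large_precision_recovers_binomial(self):
        ll = loglik_removal_agesplit(6, 20, 0.3, 1e8)
        assert abs(ll - stats.binom.logpmf(6, 20, 0.3)) < 1e-6

    def test_rejects_yoy_above_total(self):
        with pytest.raises(ValueError):
            loglik_removal_agesplit(25, 20, 0.3, 5.0)


@pytest.fixture(scope="module")
def bundle():
    scenario, env, effects, state, obs = fixture_small()
    part = partition_deaths(state, *q_schedules(scenario.years))
    lik = JointLikelihood(obs, env.years, n_ages=scenario.n_ages)
    return scenario, state, part, lik, obs, env


class TestJointLikelihood:

    def test_total_decomposes_over_datasets(self, bundle):
        scenario, state, part, lik, obs, env = bundle
        eta, tau = scenario.params.eta, scenario.params.tau
        terms = lik.terms(state, part, eta, tau)
        assert set(terms) == {"surveys", "pregnancy", "ages", "removals",
                              "agesplit"}
        total = lik.total(state, part, eta, tau)
        assert total == pytest.approx(sum(v.sum() for v in terms.values()))
        assert np.isfinite(total)

    def test_leave_one_out_changes_only_own_term(self, bundle):
        scenario, state, part, lik, obs, env = bundle
        eta, tau = scenario.params.eta, scenario.params.tau
        base = lik.terms(state, part, eta, tau)
        obs2 = ObservationSet(
            surveys=obs.surveys.iloc[1:].reset_index(drop=True),
            pregnancy=obs.pregnancy, ages=obs.ages, removals=obs.removals,
            min_age=obs.min_age)
        lik2 = JointLikelihood(obs2, env.years, n_ages=scenario.n_ages)
        dropped = lik2.terms(state, part, eta, tau)
        assert np.allclose(dropped["surveys"], base["surveys"][1:])
        for name in ("pregnancy", "ages", "removals", "agesplit"):
            assert np.allclose(dropped[name], base[name])

    def test_pointwise_labels_cover_every_observation(self, bundle):
        scenario, state, part, lik, obs, env = bundle
        labels, values = lik.pointwise(state, part, scenario.params.eta,
                                       scenario.params.tau)
        assert len(labels) == len(values)
        n_expected = (len(obs.surveys) + len(obs.pregnancy)
                      + obs.ages["year"].nunique() + len(obs.removals)
                      + obs.removals["reported_yoy"].notna().sum())
        assert len(values) == n_expected
        assert np.all(np.isfinite(values))


class TestObservationSetValidation:
    def test_schema_violations_rejected(self):
        good = fixture_small()[4]
        bad_surveys = good.surveys.copy()
        bad_surveys.loc[0, "se"] = 0.0
        with pytest.raises(ValueError, match="SEs"):
            ObservationSet(surveys=bad_surveys, pregnancy=good.pregnancy,
                           ages=good.ages, removals=good.removals)
        bad_rm = good.removals.copy()
        bad_rm.loc[0, "reported_yoy"] = bad_rm.loc[0, "reported_total"] + 1
        with pytest.raises(ValueError, match="exceed"):
            ObservationSet(surveys=good.surveys, pregnancy=good.pregnancy,
                           ages=good.ages, removals=bad_rm)

    def test_csv_round_trip(self, tmp_path):
        good = fixture_small()[4]
        good.to_csv_dir(tmp_path)
        back = ObservationSet.from_csv_dir(tmp_path, min_age=good.min_age)
        pd.testing.assert_frame_equal(good.surveys, back.surveys)
        pd.testing.assert_frame_equal(good.removals, back.removals)

    def test_missing_table_named_in_error(self, tmp_path):
        good = fixture_small()[4]
        good.to_csv_dir(tmp_path)
        (tmp_path / "surveys.csv").unlink()
        with pytest.raises(FileNotFoundError, match="surveys"):
            ObservationSet.from_csv_dir(tmp_path)
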