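"""Synthetic study-input generator.

Produces complete model inputs (environmental series, latent truth, and the
four observed tables) with exactly the statistical structure the analysis
assumes: gamma survey error, beta-binomial pregnancy sampling,
Dirichlet-multinomial age sampling, negative-binomial removals with a
beta-binomial young-of-the-year split, and AR(1) standardized environmental
anomalies. The default scenario is tuned so the synthetic population passes
through the qualitative historical phases (harvest-driven decline, recovery
after harvest reduction, renewed decline under density and ice effects);
its parameter values are scenario settings, not estimates of the real
population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import EnvironmentSeries, simulate_ar1
from .likelihoods import ObservationSet, nb_size_from_cv
from .params import SOURCES, ModelParams, YearEffects
from .projection import (ProcessState, partition_deaths, q_schedules,
                         run_process_model)


@dataclass
class SyntheticScenario:
    """Everything needed to simulate one synthetic study."""

    params: ModelParams = field(default_factory=ModelParams)
    start_year: int = 1951
    end_year: int = 2019
    n_ages: int = 36
    min_age: int = 5
    ar_coef: float = 0.5              # AR(1) coefficient, NLCI and ice
    theta: np.ndarray = field(default_factory=lambda: np.array([5., 3., 12.]))
    ic_trend_start: int | None = 2000  # onset of declining-ice trend
    ic_trend: float = -0.08            # anomaly units per year after onset
    survey_years: list[int] | None = None   # default: every 4th year
    survey_cv: float = 0.1
    sample_start_year: int | None = None    # pregnancy/age sampling onset
    preg_ages: tuple[int, int] = (3, 16)
    preg_n: int = 20                   # females sampled per age and year
    ages_n: int = 400                  # aged animals per year
    removal_cv: dict = field(default_factory=lambda: dict(
        canadian=0.1, arctic=0.3, greenland=0.3, bycatch=0.3))
    removal_kappa: dict = field(default_factory=lambda: dict(
        canadian=100.0, arctic=10.0, greenland=10.0, bycatch=10.0))
    # truth-only era offsets added to harvest hyper-means: source ->
    # list of (from_year, yoy_offset, adult_offset) steps
    harvest_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.end_year - self.start_year + 1 < 10:
            raise ValueError("span must cover at least 10 years")
        if self.survey_years is None:
            self.survey_years = list(
                range(self.start_year, self.end_year + 1, 4))
        if self.sample_start_year is None:
            self.sample_start_year = self.start_year
        if not set(self.survey_years) <= set(self.years):
            raise ValueError("survey years outside the scenario span")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["theta"] = self.theta.tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticScenario":
        d = json.loads(Path(path).read_text())
        d["params"] = ModelParams.from_dict(d["params"])
        d["theta"] = np.asarray(d["theta"])
        d["survey_years"] = list(d["survey_years"])
        return cls(**d)


def default_scenario() -> SyntheticScenario:
    """Full-span scenario with stochastic year effects and harvest eras."""
    params = ModelParams(sigma_s=0.1, sigma_f=0.1,
                         sigma_h=np.full(4, 0.15))
    offsets = {
        "canadian": [(1983, -2.2, -2.0), (1996, 0.0, -2.0),
                     (2009, -1.4, -2.0)],
        "greenland": [(1996, 0.0, 0.9)],
    }
    return SyntheticScenario(params=params, harvest_offsets=offsets,
                             sample_start_year=1979, ic_trend=-0.15,
                             survey_years=list(range(1952, 2018, 5)))


def small_scenario(n_years: int = 30, n_ages: int = 12,
                   min_age: int = 3) -> SyntheticScenario:
    """Reduced-scale scenario for fast end-to-end fitting.

    Deterministic year effects (all sigmas zero), no harvest eras, annual
    surveys and sampling, and a growth-to-saturation trajectory (moderate
    harvest, strong density dependence) so that density and climate effects
    are identifiable from the span.
    """
    params = ModelParams(
        n0=1.5e6, alpha3=0.01, phi_s=0.3, phi_f=0.5,
        gbar_h0=np.array([-2.5, -5.5, -4.2, -4.6]),
        gbar_ha=np.array([-4.0, -5.8, -4.2, -6.2]))
    return SyntheticScenario(
        params=params, start_year=1951, end_year=1951 + n_years - 1,
        n_ages=n_ages, min_age=min_age, ic_trend_start=None,
        survey_years=list(range(1951, 1951 + n_years)),
        preg_ages=(3, min(10, n_ages)), preg_n=30, ages_n=300)


def generate_environment(scenario: SyntheticScenario,
                         rng: np.random.Generator) -> EnvironmentSeries:
    years = scenario.years
    T = len(years)
    nlci = simulate_ar1(T, scenario.ar_coef, rng)
    ic = np.stack([simulate_ar1(T, scenario.ar_coef, rng) for _ in range(3)])
    if scenario.ic_trend_start is not None:
        onset = years >= scenario.ic_trend_start
        ic[:, onset] += scenario.ic_trend * (years[onset]
                                             - scenario.ic_trend_start)
    p = rng.dirichlet(scenario.theta, size=T).T
    observed = np.isin(years, scenario.survey_years)
    return EnvironmentSeries(years=years, ic=ic, nlci=nlci, p=p,
                             theta=scenario.theta.copy(),
                             observed_p=observed)


def _era_offsets(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    years = scenario.years
    off0 = np.zeros((len(SOURCES), len(years)))
    offa = np.zeros_like(off0)
    for j, src in enumerate(SOURCES):
        for from_year, d0, da in scenario.harvest_offsets.get(src, []):
            sel = years >= from_year
            off0[j, sel] = d0
            offa[j, sel] = da
    return off0, offa


def generate_truth(scenario: SyntheticScenario, rng: np.random.Generator
                   ) -> tuple[EnvironmentSeries, YearEffects, ProcessState]:
    """Simulate the environment, year effects and latent trajectory."""
    env = generate_environment(scenario, rng)
    effects = YearEffects.draw(env.n_years, scenario.params, rng)
    off0, offa = _era_offsets(scenario)
    effects.gamma_h0 = effects.gamma_h0 + off0
    effects.gamma_ha = effects.gamma_ha + offa
    state = run_process_model(scenario.params, env, effects,
                              n_ages=scenario.n_ages)
    if not np.all(np.isfinite(state.n)) or np.any(state.n < 0):
        raise ValueError("scenario produced a non-finite trajectory")
    return env, effects, state


def _sample_betabinom(rng, n, a, b):
    p = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
    return rng.binomial(np.asarray(n, dtype=int), p)


def generate_observations(scenario: SyntheticScenario, state: ProcessState,
                          rng: np.random.Generator) -> ObservationSet:
    """Draw the four observed tables from the model's own data model."""
    years = scenario.years
    params = scenario.params
    q0, qa = q_schedules(years)
    part = partition_deaths(state, q0, qa)
    tpos = {int(y): t for t, y in enumerate(years)}

    # pup-production surveys: gamma error with design CV
    rows = []
    for y in scenario.survey_years:
        mu = state.yoy_prd[tpos[y]]
        se = scenario.survey_cv * mu
        a, b = mu ** 2 / se ** 2, mu / se ** 2
        rows.append((y, rng.gamma(a, 1.0 / b), se))
    surveys = pd.DataFrame(rows, columns=["year", "yoy_est", "se"])

    # pregnancy status of sampled females: beta-binomial
    lo, hi = scenario.preg_ages
    rows = []
    for y in years[years >= scenario.sample_start_year]:
        t = tpos[int(y)]
        for age in range(lo, hi + 1):
            f = state.rates.f[age - 1, t]
            if f <= 0:
                k = 0
            else:
                k = _sample_betabinom(rng, scenario.preg_n,
                                      params.eta * f, params.eta * (1 - f))
            rows.append((int(y), age, scenario.preg_n, int(k)))
    pregnancy = pd.DataFrame(
        rows, columns=["year", "age", "n_sampled", "n_pregnant"])

    # age composition: Dirichlet-multinomial
    adist = state.agedist_prd(scenario.min_age)
    rows = []
    for y in years[years >= scenario.sample_start_year]:
        t = tpos[int(y)]
        p = rng.dirichlet(params.tau * adist[:, t])
        counts = rng.multinomial(scenario.ages_n, p)
        for k, age in enumerate(range(scenario.min_age,
                                      scenario.n_ages + 1)):
            rows.append((int(y), age, int(counts[k])))
    ages = pd.DataFrame(rows, columns=["year", "age", "count"])

    # reported removals: negative binomial total + beta-binomial YOY split
    rows = []
    for j, src in enumerate(SOURCES):
        cv = scenario.removal_cv[src]
        kappa = scenario.removal_kappa[src]
        for y in years:
            t = tpos[int(y)]
            mu = part.hv_prd[j, t]
            size = nb_size_from_cv(mu, cv)
            if np.isinf(size):
                tot = rng.poisson(mu)
            else:
                tot = rng.negative_binomial(size, size / (size + mu))
            ratio = part.hv0_prd[j, t] / mu
            yoy = _sample_betabinom(rng, tot, kappa * ratio,
                                    kappa * (1 - ratio)) if tot > 0 else 0
            rows.append((int(y), src, int(tot), int(yoy), cv, kappa))
    removals = pd.DataFrame(rows, columns=["year", "source", "reported_total",
                                           "reported_yoy", "cv", "kappa"])

    return ObservationSet(surveys=surveys, pregnancy=pregnancy, ages=ages,
                          removals=removals, min_age=scenario.min_age)


def simulate_study(scenario: SyntheticScenario, seed: int
                   ) -> tuple[EnvironmentSeries, YearEffects, ProcessState,
                              ObservationSet]:
    """Truth plus observations from a single seed (bit-reproducible)."""
    rng = np.random.default_rng(seed)
    env, effects, state = generate_truth(scenario, rng)
    obs = generate_observations(scenario, state, rng)
    return env, effects, state, obs


_FIXTURE_SEED = 20210  # frozen: the miniature dataset is deterministic


def fixture_small() -> tuple[SyntheticScenario, EnvironmentSeries,
                             YearEffects, ProcessState, ObservationSet]:
    """Deterministic 15-year, 12-age-class miniature with all data tables."""
    scenario = SyntheticScenario(
        params=ModelParams(n0=1.5e6, alpha3=0.01),
        start_year=1951, end_year=1965, n_ages=12, min_age=3,
        ic_trend_start=None, survey_years=list(range(1951, 1966, 2)),
        preg_ages=(3, 10), preg_n=15, ages_n=150)
    return (scenario, *simulate_study(scenario, _FIXTURE_SEED))
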