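"""Age-structured projection and model-predicted observables.

The population is a 36-class (configurable) Leslie system with time-varying
survival and fecundity. Year 0 of the model corresponds to the first survey
year; the initial vector is the starting abundance times the stationary age
distribution of the first year's demographic schedule. Predicted observables
(pup production available to the survey, adult age composition, reported
removals by cause) are derived from the latent trajectory, with reported
removals partitioned across causes by hazard ratios and thinned by the
struck-and-loss reporting fraction Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .environment import EnvironmentSeries
from .hazards import HazardSet, VitalRates, age_log_hazard, ice_hazard
from .params import SOURCES, ModelParams, YearEffects


def build_matrix(s_a: np.ndarray, f: np.ndarray, s0: float) -> np.ndarray:
    """Leslie projection matrix for one year.

    First row holds reproductive contributions ``R(i) = 0.5 * F(i) * S0``
    (female offspring surviving to age 1); the subdiagonal advances ages; the
    terminal class also retains its own survivors.
    """
    s_a = np.asarray(s_a, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((s_a < 0) | (s_a > 1)) or np.any((f < 0) | (f > 1)) \
            or not 0 <= s0 <= 1:
        raise ValueError("vital rates must lie in [0, 1]")
    a = len(s_a)
    m = np.zeros((a, a))
    m[0, :] = 0.5 * f * s0
    m[np.arange(1, a), np.arange(a - 1)] = s_a[:-1]
    m[a - 1, a - 1] += s_a[-1]
    return m


def advance(n: np.ndarray, s_a: np.ndarray, f: np.ndarray,
            s0: float) -> np.ndarray:
    """One projection step without materializing the matrix (fast path;
    identical to ``build_matrix(...) @ n``)."""
    out = np.empty_like(n)
    out[0] = 0.5 * s0 * (f * n).sum()
    out[1:] = s_a[:-1] * n[:-1]
    out[-1] += s_a[-1] * n[-1]
    return out


def stationary_age_distribution(m: np.ndarray, tol: float = 1e-10,
                                max_iter: int = 10_000) -> np.ndarray:
    """Stationary (stable) age distribution by repeated projection.

    Projects a uniform start vector, renormalizing to unit sum, until the
    L1 change between iterates drops below ``tol``. Warns and returns the
    last iterate if the cap is reached.
    """
    a = m.shape[0]
    w = np.full(a, 1.0 / a)
    for _ in range(max_iter):
        w_new = m @ w
        total = w_new.sum()
        if total <= 0:
            raise ValueError("projection matrix annihilated the population")
        w_new /= total
        if np.abs(w_new - w).sum() < tol:
            return w_new
        w = w_new
    warnings.warn("stationary age distribution did not converge; "
                  "returning last iterate", RuntimeWarning)
    return w


@dataclass
class ProcessState:
    """Latent trajectory plus every hazard, rate and predicted observable."""

    years: np.ndarray
    n: np.ndarray             # (A, T) abundance by age class
    hazards: HazardSet
    rates: VitalRates
    yoy_prd: np.ndarray       # (T,) pups available to the survey
    sad: np.ndarray           # initial stationary age distribution

    @property
    def total(self) -> np.ndarray:
        """N(t): sum of the adult age classes."""
        return self.n.sum(axis=0)

    @property
    def births(self) -> np.ndarray:
        """Total pups born each year, 0.5 * sum n(i) F(i)."""
        return 0.5 * (self.n * self.rates.f).sum(axis=0)

    def agedist_prd(self, m: int = 5) -> np.ndarray:
        """Predicted age frequency distribution over ages m..A, per year."""
        block = self.n[m - 1:, :]
        totals = block.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("age distribution undefined: no adults >= m")
        return block / totals


def run_process_model(params: ModelParams, env: EnvironmentSeries,
                      effects: YearEffects | None = None,
                      n_ages: int = 36) -> ProcessState:
    """Simulate the deterministic process model over the environment span.

    Year effects default to their hierarchical means. Density dependence uses
    the current year's adult abundance; fecundity uses the previous year's
    abundance and climate index (year 0 falls back to the initial values).
    """
    params.validate()
    T = env.n_years
    if effects is None:
        effects = YearEffects.zeros(T, params)

    gamma_a, gamma_0 = age_log_hazard(params.alpha1, params.alpha2,
                                      params.alpha3, params.upsilon, n_ages)
    hh0 = np.exp(effects.gamma_h0)
    hha = np.exp(effects.gamma_ha)
    sum_hh0 = hh0.sum(axis=0)
    sum_hha = hha.sum(axis=0)
    hic = np.atleast_1d(
        np.asarray(ice_hazard(params.psi0, params.psi, env.ic, env.p)))

    scale = params.density_scale

    # the per-year recursion runs in a compiled kernel (the MCMC hot path);
    # its math is checked against the hazard-module operations in the tests.
    # Initialization: N0 times the SAD of the first year's schedule, with
    # density evaluated at N0 (the schedule is fixed during SAD iteration).
    from ._kernel import project_kernel
    ages = np.arange(1, n_ages + 1)
    f_static = params.beta1 + params.beta2 * np.where(
        ages <= 8, (8.0 - ages) ** 2, 0.0)
    n, h0, ha, s0, sa, f, sad, sad_ok = project_kernel(
        np.exp(gamma_a), gamma_0, f_static, 2,
        np.asarray(env.nlci, dtype=float),
        np.asarray(effects.eps_s, dtype=float),
        np.asarray(effects.eps_f, dtype=float),
        hic, sum_hh0, sum_hha,
        params.zeta, params.delta, params.phi_s * scale,
        params.phi_f * scale, params.n0, 1e-10, 10_000)
    if not sad_ok:
        warnings.warn("stationary age distribution did not converge at "
                      "initialization", RuntimeWarning)

    s_nb = s0 ** params.pi
    yoy_prd = 0.5 * (n * f).sum(axis=0) * s_nb
    hazards = HazardSet(h0=h0, ha=ha, hic=hic, hh0=hh0, hha=hha)
    rates = VitalRates(s0=s0, sa=sa, f=f, s_nb=s_nb)
    return ProcessState(years=env.years.copy(), n=n, hazards=hazards,
                        rates=rates, yoy_prd=yoy_prd, sad=sad)


def struck_loss_q(source: str, age_class: str, year: int) -> float:
    """Reporting fraction Q = 1 - struck-and-loss rate.

    Canadian-hunt YOY losses were 1% before 1983 and 5% after; Arctic and
    Greenland YOY losses 50%; adult losses 50% for all hunts; bycatch is
    fully reported.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown removal source: {source!r}")
    if age_class not in ("yoy", "adult"):
        raise ValueError(f"age_class must be 'yoy' or 'adult'")
    if source == "bycatch":
        return 1.0
    if age_class == "adult":
        return 0.5
    if source == "canadian":
        return 0.99 if year < 1983 else 0.95
    return 0.5  # arctic, greenland YOY


def q_schedules(years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(4, T) reporting fractions for YOY and adults across the year axis."""
    q0 = np.array([[struck_loss_q(s, "yoy", int(y)) for y in years]
                   for s in SOURCES])
    qa = np.array([[struck_loss_q(s, "adult", int(y)) for y in years]
                   for s in SOURCES])
    return q0, qa


@dataclass
class DeathPartition:
    """Cause-partitioned deaths and predicted reported removals."""

    f_h0: np.ndarray       # (4, T) YOY death fraction by removal source
    f_ice: np.ndarray      # (T,) YOY death fraction from ice
    f_nat0: np.ndarray     # (T,) YOY death fraction from natural hazards
    f_ha: np.ndarray       # (4, A, T) adult death fraction by source and age
    yoy_deaths: np.ndarray  # (T,) total YOY deaths
    adult_deaths: np.ndarray  # (A, T) deaths by adult age class
    hv0_prd: np.ndarray    # (4, T) predicted reported YOY removals
    hva_prd: np.ndarray    # (4, T) predicted reported adult removals

    @property
    def hv_prd(self) -> np.ndarray:
        return self.hv0_prd + self.hva_prd


def partition_deaths(state: ProcessState, q0: np.ndarray,
                     qa: np.ndarray) -> DeathPartition:
    """Partition deaths across causes by hazard ratios and apply reporting.

    YOY cause fractions are ``hH0_j / (h0 + hIC + sum_j hH0_j)``; adult
    fractions are age-specific, ``hHA_j / (hA(i) + sum_j hHA_j)``. Expected
    reported removals are total deaths x fraction x Q.
    """
    hz, rates = state.hazards, state.rates
    denom0 = hz.h0 + hz.hic + hz.hh0.sum(axis=0)
    if np.any(denom0 <= 0):
        raise ValueError("cause partition undefined: zero total YOY hazard")
    f_h0 = hz.hh0 / denom0
    f_ice = hz.hic / denom0
    f_nat0 = hz.h0 / denom0

    denom_a = hz.ha + hz.hha.sum(axis=0)  # (A, T)
    f_ha = hz.hha[:, None, :] / denom_a[None, :, :]

    yoy_deaths = 0.5 * (state.n * rates.f).sum(axis=0) * (1.0 - rates.s0)
    adult_deaths = state.n * (1.0 - rates.sa)

    hv0_prd = yoy_deaths * f_h0 * q0
    hva_prd = (adult_deaths[None, :, :] * f_ha).sum(axis=1) * qa
    return DeathPartition(f_h0=f_h0, f_ice=f_ice, f_nat0=f_nat0, f_ha=f_ha,
                          yoy_deaths=yoy_deaths, adult_deaths=adult_deaths,
                          hv0_prd=hv0_prd, hva_prd=hva_prd)
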