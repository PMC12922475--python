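"""Environmental inputs: ice anomaly index, climate index, whelping proportions.

The ice index standardizes raw first-year ice cover for each whelping area
(two Gulf of St. Lawrence patches and the Front off southern Labrador) over a
fixed 1969-2000 reference window and averages the whelping-period and
post-weaning-fast anomalies. Proportions of pups born in each area follow a
Dirichlet distribution fit by maximum likelihood to survey-year observations;
non-survey years receive Dirichlet draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma

AREAS = ("gulf_s", "gulf_n", "front")
PERIODS = (1, 2)  # whelping, post-weaning fast
REFERENCE_YEARS = (1969, 2000)
ICE_YEARS = (1969, 2019)


class DegenerateReferenceError(ValueError):
    """Raised when a reference ice series has zero spread."""


@dataclass
class EnvironmentSeries:
    """Environmental driver series aligned to the model year axis.

    ``ic`` is the standardized ice anomaly (3 areas x T, zero-filled where
    anomalies are unobservable), ``nlci`` the climate index, ``p`` the
    simplex-valued proportions of pups born in each area, ``theta`` the
    Dirichlet concentrations behind ``p``, and ``observed_p`` flags years
    where ``p`` comes from survey data rather than a Dirichlet draw.
    """

    years: np.ndarray
    ic: np.ndarray
    nlci: np.ndarray
    p: np.ndarray
    theta: np.ndarray = field(default_factory=lambda: np.ones(3))
    observed_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        T = len(self.years)
        self.ic = np.asarray(self.ic, dtype=float)
        self.nlci = np.asarray(self.nlci, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.ic.shape != (3, T) or self.p.shape != (3, T):
            raise ValueError("ic and p must have shape (3, n_years)")
        if self.nlci.shape != (T,):
            raise ValueError("nlci must have shape (n_years,)")
        if not np.allclose(self.p.sum(axis=0), 1.0, atol=1e-12):
            raise ValueError("whelping proportions must sum to 1 per year")
        if np.any(self.theta <= 0):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def n_years(self) -> int:
        return len(self.years)


def compute_ice_index(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardized ice anomaly per area and year.

    ``raw`` has columns ``area`` (in :data:`AREAS`), ``period`` (1 or 2),
    ``year`` and ``ice_cover``. For each (area, period) the mean and SD are
    taken over reference years 1969-2000, and the index is the two-period
    average of ``(ICE - mean) / SD``. Missing periods propagate as NaN.

    Returns a DataFrame indexed by year with one column per area.
    """
    raw = raw.copy()
    required = {"area", "period", "year", "ice_cover"}
    if missing := required - set(raw.columns):
        raise ValueError(f"ice table missing columns: {sorted(missing)}")
    years = raw["year"].to_numpy()
    if years.min() < ICE_YEARS[0] or years.max() > ICE_YEARS[1]:
        raise ValueError(
            f"ice years must lie within {ICE_YEARS[0]}-{ICE_YEARS[1]}")
    if not set(raw["area"]) <= set(AREAS):
        raise ValueError(f"unknown ice areas: {set(raw['area']) - set(AREAS)}")

    all_years = np.arange(years.min(), years.max() + 1)
    areas = [a for a in AREAS if a in set(raw["area"])]
    out = pd.DataFrame(index=pd.Index(all_years, name="year"),
                       columns=areas, dtype=float)
    for area in areas:
        z_by_period = []
        for p in PERIODS:
            s = (raw[(raw["area"] == area) & (raw["period"] == p)]
                 .set_index("year")["ice_cover"]
                 .reindex(all_years))
            ref = s.loc[REFERENCE_YEARS[0]:REFERENCE_YEARS[1]].dropna()
            if len(ref) < 2:
                raise ValueError(
                    f"area {area} period {p}: need >= 2 reference-period years")
            sd = ref.std(ddof=1)
            if sd == 0:
                raise DegenerateReferenceError(
                    f"area {area} period {p}: zero spread in reference years")
            z_by_period.append((s - ref.mean()) / sd)
        out[area] = sum(z_by_period) / len(PERIODS)
    return out


def _inverse_digamma(y: np.ndarray) -> np.ndarray:
    # Minka's initialization followed by Newton steps.
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - digamma(1.0)))
    for _ in range(8):
        x = x - (digamma(x) - y) / polygamma(1, x)
    return x


def dirichlet_loglik(theta: np.ndarray, p_rows: np.ndarray) -> float:
    """Total Dirichlet log-density of simplex rows ``p_rows`` (n x k)."""
    n = p_rows.shape[0]
    return float(
        n * (gammaln(theta.sum()) - gammaln(theta).sum())
        + ((theta - 1.0) * np.log(p_rows).sum(axis=0)).sum()
    )


def fit_whelping_dirichlet(p_obs: np.ndarray, tol: float = 1e-8,
                           max_iter: int = 2000,
                           zero_floor: float = 1e-4) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood Dirichlet concentrations for observed proportions.

    Uses Minka's fixed-point iteration with convergence declared when the
    log-likelihood changes by less than ``tol``. Rows containing zeros are
    floored at ``zero_floor`` and renormalized (the Dirichlet has no mass on
    the simplex boundary). Returns ``(theta, converged)``.
    """
    p = np.atleast_2d(np.asarray(p_obs, dtype=float))
    if p.shape[0] < 2:
        raise ValueError("need at least 2 observed proportion rows to fit")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must be nonnegative and sum to 1")
    p = np.maximum(p, zero_floor)
    p = p / p.sum(axis=1, keepdims=True)

    mean_log_p = np.log(p).mean(axis=0)
    # moment-matched start
    m = p.mean(axis=0)
    v = p.var(axis=0).mean()
    s0 = max((m[0] * (1 - m[0])) / max(v, 1e-12) - 1.0, 1.0)
    theta = m * s0

    ll = dirichlet_loglik(theta, p)
    converged = False
    for _ in range(max_iter):
        theta = _inverse_digamma(digamma(theta.sum()) + mean_log_p)
        ll_new = dirichlet_loglik(theta, p)
        if abs(ll_new - ll) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return theta, converged


def sample_whelping_proportions(theta: np.ndarray, years: np.ndarray,
                                observed: dict[int, np.ndarray],
                                rng: np.random.Generator) -> np.ndarray:
    """Whelping-area proportions per year: observed rows pass through
    unchanged, other years are Dirichlet(theta) draws. Returns (3, T)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    years = np.asarray(years, dtype=int)
    p = np.empty((len(theta), len(years)))
    for t, year in enumerate(years):
        if year in observed:
            row = np.asarray(observed[year], dtype=float)
            if not np.isclose(row.sum(), 1.0, atol=1e-8):
                raise ValueError(f"observed proportions for {year} off simplex")
            p[:, t] = row
        else:
            p[:, t] = rng.dirichlet(theta)
    return p


def simulate_ar1(n: int, coef: float, rng: np.random.Generator,
                 marginal_sd: float = 1.0) -> np.ndarray:
    """Stationary AR(1) series with the given marginal SD (anomaly scale)."""
    innov_sd = marginal_sd * np.sqrt(1.0 - coef ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + rng.normal(0.0, innov_sd)
    return x
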