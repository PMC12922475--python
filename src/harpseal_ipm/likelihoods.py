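"""Observation likelihoods linking process-model predictions to data.

Four data model components: gamma-distributed pup-production survey
estimates with design-based SEs; beta-binomial pregnancy counts; a
Dirichlet-multinomial over adult age compositions; negative-binomial
reported removals (variance pinned to an assigned CV) with a beta-binomial
split of removals into young of the year versus adults.

Kernels are written against ``scipy.special`` so a single vectorized call
covers each dataset inside the sampler; every kernel is cross-checked
against the corresponding ``scipy.stats`` distribution in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .params import SOURCES
from .projection import DeathPartition, ProcessState

_F_EPS = 1e-12


def gamma_logpdf(x, mean, sd):
    """Gamma log-density parameterized by mean and SD (shape = mean^2/sd^2,
    rate = mean/sd^2), matching the survey error model."""
    x, mean, sd = np.broadcast_arrays(x, mean, sd)
    if np.any(np.asarray(x) <= 0):
        raise ValueError("gamma observations must be positive")
    a = mean ** 2 / sd ** 2
    b = mean / sd ** 2
    return a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(x) - b * x


def betabinom_logpmf(k, n, a, b):
    """Beta-binomial log-pmf; -inf off support."""
    k, n, a, b = np.broadcast_arrays(
        np.asarray(k, float), np.asarray(n, float), a, b)
    with np.errstate(all="ignore"):
        out = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
               + betaln(k + a, n - k + b) - betaln(a, b))
    bad = (k < 0) | (k > n)
    if bad.any():
        out = np.where(bad, -np.inf, out)
    return out


def dirichlet_multinomial_logpmf(counts, alpha):
    """Dirichlet-multinomial log-pmf of one count vector."""
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n = counts.sum()
    a0 = alpha.sum()
    return float(gammaln(n + 1) - gammaln(counts + 1).sum()
                 + gammaln(a0) - gammaln(n + a0)
                 + (gammaln(counts + alpha) - gammaln(alpha)).sum())


def nbinom_logpmf(k, mu, size):
    """Negative-binomial log-pmf with mean ``mu`` and size ``size``
    (gamma-function form, valid for non-integer size)."""
    k, mu, size = np.broadcast_arrays(np.asarray(k, float), mu, size)
    with np.errstate(all="ignore"):
        out = (gammaln(k + size) - gammaln(size) - gammaln(k + 1)
               + size * np.log(size / (size + mu))
               + k * np.log(mu / (size + mu)))
    bad = k < 0
    if bad.any():
        out = np.where(bad, -np.inf, out)
    return out


def nb_size_from_cv(mu, cv):
    """Size parameter making the NB variance equal (CV * mu)^2.

    Where (CV*mu)^2 <= mu the NB cannot be that underdispersed; those
    entries return inf (the Poisson limit) and the caller falls back to a
    Poisson term.
    """
    mu, cv = np.broadcast_arrays(np.asarray(mu, float), np.asarray(cv, float))
    var = (cv * mu) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        size = np.where(var > mu, mu ** 2 / (var - mu), np.inf)
    return size


def loglik_yoy_survey(yoy_obs, yoy_prd, se_sv):
    """Gamma log-density of observed pup-production estimates."""
    if np.any(np.asarray(yoy_prd) <= 0) or np.any(np.asarray(se_sv) <= 0):
        raise ValueError("predictions and SEs must be positive")
    return gamma_logpdf(yoy_obs, yoy_prd, se_sv)


def loglik_pregnancy(npr_obs, nf, f_prd, eta):
    """Beta-binomial log-pmf of pregnant counts among sampled females."""
    if np.any(np.asarray(npr_obs) > np.asarray(nf)):
        raise ValueError("pregnant count exceeds sample size")
    if eta <= 0:
        raise ValueError("eta must be positive")
    f = np.clip(np.asarray(f_prd, float), _F_EPS, 1.0 - _F_EPS)
    return betabinom_logpmf(npr_obs, nf, eta * f, eta * (1.0 - f))


def loglik_agedist(nc, agedist_prd, tau):
    """Dirichlet-multinomial log-pmf of an observed age-count vector."""
    nc = np.asarray(nc, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if nc.sum() == 0:
        warnings.warn("empty age-count vector contributes 0", RuntimeWarning)
        return 0.0
    q = np.clip(np.asarray(agedist_prd, float), _F_EPS, None)
    q = q / q.sum()
    return dirichlet_multinomial_logpmf(nc, tau * q)


def loglik_removals(hv_obs, hv_prd, cv):
    """Negative-binomial log-pmf of reported removals.

    The size parameter pins the variance to (CV * predicted)^2; where that
    would be at or below the mean, a Poisson term is used instead (variance
    floor) with a warning.
    """
    hv_obs = np.asarray(hv_obs, dtype=float)
    mu = np.asarray(hv_prd, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("predicted removals must be positive")
    size = nb_size_from_cv(mu, cv)
    out = np.where(np.isinf(size),
                   hv_obs * np.log(mu) - mu - gammaln(hv_obs + 1),
                   nbinom_logpmf(hv_obs, mu, np.where(np.isinf(size),
                                                      1.0, size)))
    if np.any(np.isinf(size)):
        warnings.warn("CV^2 * mu <= 1 for some removals; Poisson fallback",
                      RuntimeWarning)
    return out


def loglik_removal_agesplit(hv0_obs, hv_obs, ratio, kappa):
    """Beta-binomial log-pmf of the YOY count among reported removals."""
    if np.any(np.asarray(hv0_obs) > np.asarray(hv_obs)):
        raise ValueError("YOY removals exceed total removals")
    r = np.clip(np.asarray(ratio, float), _F_EPS, 1.0 - _F_EPS)
    kappa = np.asarray(kappa, float)
    return betabinom_logpmf(hv0_obs, hv_obs, kappa * r, kappa * (1.0 - r))


# ---------------------------------------------------------------------------

DATASETS = ("surveys", "pregnancy", "ages", "removals", "agesplit")


@dataclass
class ObservationSet:
    """The four observed tables plus error metadata.

    ``surveys``: year, yoy_est, se. ``pregnancy``: year, age, n_sampled,
    n_pregnant. ``ages``: year, age, count. ``removals``: year, source,
    reported_total, reported_yoy, cv, kappa. ``min_age`` is the youngest age
    class compared against age-composition data.
    """

    surveys: pd.DataFrame
    pregnancy: pd.DataFrame
    ages: pd.DataFrame
    removals: pd.DataFrame
    min_age: int = 5

    def __post_init__(self) -> None:
        schemas = {
            "surveys": ("year", "yoy_est", "se"),
            "pregnancy": ("year", "age", "n_sampled", "n_pregnant"),
            "ages": ("year", "age", "count"),
            "removals": ("year", "source", "reported_total", "reported_yoy",
                         "cv", "kappa"),
        }
        for name, cols in schemas.items():
            df = getattr(self, name)
            if missing := set(cols) - set(df.columns):
                raise ValueError(
                    f"{name} table missing columns: {sorted(missing)}")
        if np.any(self.surveys["se"] <= 0):
            raise ValueError("survey SEs must be positive")
        if np.any(self.pregnancy["n_pregnant"] > self.pregnancy["n_sampled"]):
            raise ValueError("pregnant count exceeds sample size")
        if np.any(self.removals["cv"] <= 0):
            raise ValueError("removal CVs must be positive")
        yoy = self.removals["reported_yoy"]
        bad = yoy.notna() & (yoy > self.removals["reported_total"])
        if bad.any():
            raise ValueError("YOY removals exceed total removals")
        if not set(self.removals["source"]) <= set(SOURCES):
            raise ValueError("unknown removal source in removals table")

    def to_csv_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("surveys", "pregnancy", "ages", "removals"):
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_csv_dir(cls, path: str | Path, min_age: int = 5
                     ) -> "ObservationSet":
        path = Path(path)
        frames = {}
        for name in ("surveys", "pregnancy", "ages", "removals"):
            fp = path / f"{name}.csv"
            if not fp.exists():
                raise FileNotFoundError(f"missing observation table: {fp}")
            frames[name] = pd.read_csv(fp)
        return cls(min_age=min_age, **frames)


@dataclass
class JointLikelihood:
    """Aligns an :class:`ObservationSet` to a model year axis and evaluates
    the joint log-likelihood of a process state (fast path for MCMC).

    Pointwise terms are exposed per observation unit (one per survey point,
    pregnancy row, age-composition year, removal total and removal
    age-split) for PSIS-LOO.
    """

    obs: ObservationSet
    years: np.ndarray
    n_ages: int = 36
    _idx: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        year_pos = {int(y): t for t, y in enumerate(self.years)}
        o = self.obs
        idx: dict = {}

        sv = o.surveys[o.surveys["year"].isin(year_pos)]
        idx["sv_t"] = sv["year"].map(year_pos).to_numpy(dtype=int)
        idx["sv_obs"] = sv["yoy_est"].to_numpy(float)
        idx["sv_se"] = sv["se"].to_numpy(float)

        pr = o.pregnancy[o.pregnancy["year"].isin(year_pos)
                         & (o.pregnancy["age"] <= self.n_ages)]
        idx["pr_t"] = pr["year"].map(year_pos).to_numpy(dtype=int)
        idx["pr_i"] = pr["age"].to_numpy(int) - 1
        idx["pr_n"] = pr["n_sampled"].to_numpy(float)
        idx["pr_k"] = pr["n_pregnant"].to_numpy(float)

        ag = o.ages[o.ages["year"].isin(year_pos)
                    & (o.ages["age"] >= o.min_age)
                    & (o.ages["age"] <= self.n_ages)]
        pivot = (ag.pivot_table(index="age", columns="year", values="count",
                                aggfunc="sum", fill_value=0)
                 .reindex(np.arange(o.min_age, self.n_ages + 1), fill_value=0))
        idx["ag_years_t"] = np.array([year_pos[int(y)] for y in pivot.columns], dtype=int)
        idx["ag_counts"] = pivot.to_numpy(float)  # (ages m..A, n_obs_years)

        rm = o.removals[o.removals["year"].isin(year_pos)]
        src_pos = {s: j for j, s in enumerate(SOURCES)}
        idx["rm_t"] = rm["year"].map(year_pos).to_numpy(dtype=int)
        idx["rm_j"] = rm["source"].map(src_pos).to_numpy(dtype=int)
        idx["rm_tot"] = rm["reported_total"].to_numpy(float)
        idx["rm_cv"] = rm["cv"].to_numpy(float)
        split = rm["reported_yoy"].notna().to_numpy()
        idx["sp_mask"] = split
        idx["sp_yoy"] = rm["reported_yoy"].to_numpy(float)[split]
        idx["sp_kappa"] = rm["kappa"].to_numpy(float)[split]
        self._idx = idx

    @property
    def n_obs(self) -> int:
        x = self._idx
        return (len(x["sv_t"]) + len(x["pr_t"]) + len(x["ag_years_t"])
                + len(x["rm_t"]) + int(x["sp_mask"].sum()))

    # -- per-dataset terms ------------------------------------------------
    def terms(self, state: ProcessState, part: DeathPartition,
              eta: float, tau: float) -> dict[str, np.ndarray]:
        """Pointwise log-likelihood arrays keyed by dataset name."""
        x = self._idx
        out: dict[str, np.ndarray] = {}

        out["surveys"] = loglik_yoy_survey(
            x["sv_obs"], state.yoy_prd[x["sv_t"]], x["sv_se"])

        f_prd = state.rates.f[x["pr_i"], x["pr_t"]]
        out["pregnancy"] = loglik_pregnancy(x["pr_k"], x["pr_n"], f_prd, eta)

        adist = state.agedist_prd(self.obs.min_age)
        counts = x["ag_counts"]
        alpha = tau * np.clip(adist[:, x["ag_years_t"]], _F_EPS, None)
        n_tot = counts.sum(axis=0)
        a0 = alpha.sum(axis=0)
        out["ages"] = (gammaln(n_tot + 1) - gammaln(counts + 1).sum(axis=0)
                       + gammaln(a0) - gammaln(n_tot + a0)
                       + (gammaln(counts + alpha)
                          - gammaln(alpha)).sum(axis=0))

        hv_prd = part.hv_prd[x["rm_j"], x["rm_t"]]
        out["removals"] = loglik_removals(x["rm_tot"], hv_prd, x["rm_cv"])

        m = x["sp_mask"]
        ratio = part.hv0_prd[x["rm_j"][m], x["rm_t"][m]] / hv_prd[m]
        out["agesplit"] = loglik_removal_agesplit(
            x["sp_yoy"], x["rm_tot"][m], ratio, x["sp_kappa"])
        return out

    def total(self, state: ProcessState, part: DeathPartition,
              eta: float, tau: float) -> float:
        return float(sum(v.sum() for v in
                         self.terms(state, part, eta, tau).values()))

    def pointwise(self, state: ProcessState, part: DeathPartition,
                  eta: float, tau: float) -> tuple[list[str], np.ndarray]:
        terms = self.terms(state, part, eta, tau)
        labels = [f"{name}[{i}]" for name in DATASETS
                  for i in range(len(np.atleast_1d(terms[name])))]
        values = np.concatenate([np.atleast_1d(terms[n]) for n in DATASETS])
        return labels, values

    # -- posterior-predictive support ------------------------------------
    def moments(self, state: ProcessState, part: DeathPartition,
                eta: float, tau: float
                ) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """(mean, variance, observed) per dataset under the data model,
        flattened to one entry per observation cell (age-composition years
        expand to cells). Used for Pearson-residual discrepancy statistics."""
        x = self._idx
        out = {}
        out["surveys"] = (state.yoy_prd[x["sv_t"]], x["sv_se"] ** 2,
                          x["sv_obs"])

        f = np.clip(state.rates.f[x["pr_i"], x["pr_t"]], _F_EPS, 1 - _F_EPS)
        n = x["pr_n"]
        mean = n * f
        var = n * f * (1 - f) * (n + eta) / (1 + eta)
        out["pregnancy"] = (mean, var, x["pr_k"])

        adist = state.agedist_prd(self.obs.min_age)
        q = np.clip(adist[:, x["ag_years_t"]], _F_EPS, None)
        q = q / q.sum(axis=0)
        n_tot = x["ag_counts"].sum(axis=0)
        mean = n_tot * q
        var = n_tot * q * (1 - q) * (n_tot + tau) / (1 + tau)
        out["ages"] = (mean.ravel(), var.ravel(), x["ag_counts"].ravel())

        mu = part.hv_prd[x["rm_j"], x["rm_t"]]
        var = np.maximum((x["rm_cv"] * mu) ** 2, mu)  # Poisson floor
        out["removals"] = (mu, var, x["rm_tot"])

        m = x["sp_mask"]
        r = np.clip(part.hv0_prd[x["rm_j"][m], x["rm_t"][m]] / mu[m],
                    _F_EPS, 1 - _F_EPS)
        n = x["rm_tot"][m]
        kap = x["sp_kappa"]
        mean = n * r
        var = np.maximum(n * r * (1 - r) * (n + kap) / (1 + kap), _F_EPS)
        out["agesplit"] = (mean, var, x["sp_yoy"])
        return out

    def simulate(self, state: ProcessState, part: DeathPartition,
                 eta: float, tau: float, rng: np.random.Generator
                 ) -> dict[str, np.ndarray]:
        """Replicate observations from the data model at the given state,
        on the same design (years, sample sizes) as the observed tables."""
        x = self._idx
        rep = {}
        mu = state.yoy_prd[x["sv_t"]]
        a = mu ** 2 / x["sv_se"] ** 2
        rep["surveys"] = rng.gamma(a, mu / a)

        f = np.clip(state.rates.f[x["pr_i"], x["pr_t"]], _F_EPS, 1 - _F_EPS)
        p = rng.beta(eta * f, eta * (1 - f))
        rep["pregnancy"] = rng.binomial(x["pr_n"].astype(int), p)

        adist = state.agedist_prd(self.obs.min_age)
        cols = []
        for c, t in enumerate(x["ag_years_t"]):
            q = np.clip(adist[:, t], _F_EPS, None)
            p = rng.dirichlet(tau * q / q.sum())
            cols.append(rng.multinomial(int(x["ag_counts"][:, c].sum()), p))
        rep["ages"] = np.array(cols).T.ravel()

        mu = part.hv_prd[x["rm_j"], x["rm_t"]]
        size = nb_size_from_cv(mu, x["rm_cv"])
        tot = np.where(np.isinf(size), rng.poisson(mu),
                       rng.negative_binomial(np.where(np.isinf(size), 1, size),
                                             np.where(np.isinf(size), 0.5,
                                                      size / (size + mu))))
        rep["removals"] = tot

        # age split replicated conditional on the observed totals, matching
        # the moments used for the discrepancy statistic
        m = x["sp_mask"]
        r = np.clip(part.hv0_prd[x["rm_j"][m], x["rm_t"][m]] / mu[m],
                    _F_EPS, 1 - _F_EPS)
        p = rng.beta(x["sp_kappa"] * r, x["sp_kappa"] * (1 - r))
        rep["agesplit"] = rng.binomial(x["rm_tot"][m].astype(int), p)
        return rep
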