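"""Instantaneous hazards and vital rates under the competing-hazards model.

All mortality causes act as additive instantaneous hazards, so annual
survival is ``exp(-sum of hazards)`` and cause-of-death shares are hazard
ratios. Natural hazards combine a Siler-type age quadratic (on the log-hazard
scale) with a density/environment modifier; ice hazards are a saturating
logistic in the ice anomaly, weighted across whelping areas; human-removal
hazards are hierarchical by source. Fecundity is the complement of the hazard
of not becoming pregnant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .params import ModelParams


@dataclass
class HazardSet:
    """Per-year instantaneous hazards (unitless, per year).

    ``h0``: YOY natural; ``ha``: (A, T) adult natural by age; ``hic``:
    population-level ice; ``hh0``/``hha``: (4, T) removal hazards by source.
    """

    h0: np.ndarray
    ha: np.ndarray
    hic: np.ndarray
    hh0: np.ndarray
    hha: np.ndarray


@dataclass
class VitalRates:
    """Annual survival and fecundity derived from a :class:`HazardSet`."""

    s0: np.ndarray          # (T,) YOY survival
    sa: np.ndarray          # (A, T) adult survival
    f: np.ndarray           # (A, T) fecundity (birth probability)
    s_nb: np.ndarray        # (T,) newborn survival to the pup survey


def age_log_hazard(alpha1: float, alpha2: float, alpha3: float,
                   upsilon: float, n_ages: int = 36
                   ) -> tuple[np.ndarray, float]:
    """Siler-type age log hazards.

    Returns ``(gamma_a, gamma_0)`` where ``gamma_a[i-1] = alpha1 -
    alpha2*(i-1) + alpha3*(i-1)**2`` for ages ``i = 1..n_ages`` and the YOY
    log hazard adds ``upsilon`` to the 1-year-old value.
    """
    if n_ages < 1:
        raise ValueError("n_ages must be >= 1")
    i = np.arange(1, n_ages + 1)
    gamma_a = alpha1 - alpha2 * (i - 1) + alpha3 * (i - 1) ** 2
    return gamma_a, float(gamma_a[0] + upsilon)


def density_env_log_hazard(phi_s: float, delta: float, zeta: float,
                           n_scaled: float, nlci: float, eps_s: float
                           ) -> tuple[float, float]:
    """Density/environment log-hazard modifiers for YOY and adults.

    ``gamma_d0 = phi_s * N * exp(delta*NLCI + eps_s)`` with ``N`` on the
    configured (scaled) abundance axis; the adult modifier attenuates the
    YOY effect on the hazard scale: ``exp(gamma_da) = (exp(gamma_d0)-1)*zeta
    + 1``, so ``zeta = 1`` gives identical per-capita effects and ``zeta = 0``
    removes them for adults.
    """
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    if n_scaled < 0:
        raise ValueError("abundance must be nonnegative")
    gamma_d0 = phi_s * n_scaled * np.exp(delta * nlci + eps_s)
    gamma_da = np.log((np.exp(gamma_d0) - 1.0) * zeta + 1.0)
    return float(gamma_d0), float(gamma_da)


def ice_hazard(psi0: float, psi: np.ndarray, ic: np.ndarray,
               p: np.ndarray) -> float | np.ndarray:
    """Population-level YOY ice hazard.

    Each area's hazard is ``expit(-psi0 - psi_a * IC_a)``: a saturating
    logistic that vanishes for strongly positive (icy) anomalies and rises
    toward its maximum as the anomaly becomes strongly negative. The
    population hazard is the whelping-proportion-weighted sum across areas.
    ``ic`` and ``p`` have the area axis first; extra axes broadcast.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0):
        raise ValueError("psi magnitudes must be nonnegative")
    ic = np.asarray(ic, dtype=float)
    p = np.asarray(p, dtype=float)
    scalar = ic.ndim == 1
    if scalar:
        ic = ic[:, None]
        p = p[:, None]
    area_hazard = expit(-psi0 - psi[:, None] * ic)
    out = (p * area_hazard).sum(axis=0)
    return float(out[0]) if scalar else out


def harvest_hazards(gbar: np.ndarray, sigma: np.ndarray, n_years: int,
                    rng: np.random.Generator | None = None,
                    gamma: np.ndarray | None = None) -> np.ndarray:
    """Source x year removal hazards from hierarchical log-hazards.

    If realized year effects ``gamma`` (4, T) are given (the inference case)
    they are exponentiated directly; otherwise year log-hazards are drawn
    ``Normal(gbar_j, sigma_j)``.
    """
    if gamma is None:
        if rng is None:
            raise ValueError("need rng when year effects are not supplied")
        gamma = rng.normal(np.asarray(gbar)[:, None],
                           np.asarray(sigma)[:, None],
                           (len(gbar), n_years))
    return np.exp(gamma)


def fecundity(params: ModelParams, n_prev_scaled: float, nlci_prev: float,
              eps_f: float, n_ages: int = 36) -> np.ndarray:
    """Age-specific birth probability for one year.

    Fecundity is ``exp(-hazard of not becoming pregnant)``: zero below age 3,
    penalized by ``beta2*(8-i)^2`` through age 8, asymptotic above. Density
    and climate act through an exponentiated modifier of the density term,
    with a one-year lag on abundance and the climate index.
    """
    i = np.arange(1, n_ages + 1)
    grad = np.exp(params.delta * nlci_prev + eps_f)
    log_haz = params.beta1 + params.phi_f * n_prev_scaled * grad \
        + params.beta2 * np.where(i <= 8, (8 - i) ** 2, 0.0)
    f = np.exp(-np.exp(log_haz))
    f[i < 3] = 0.0
    return f


def annual_survival(h0: float, hic: float, hh0: np.ndarray,
                    ha: np.ndarray, hha: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Annual YOY and adult survival from competing hazards.

    ``S0 = exp(-(h0 + hIC + sum_j hH0_j))`` and ``SA(i) = exp(-(hA(i) +
    sum_j hHA_j))``.
    """
    hh0 = np.asarray(hh0, dtype=float)
    hha = np.asarray(hha, dtype=float)
    ha = np.asarray(ha, dtype=float)
    if h0 < 0 or hic < 0 or np.any(hh0 < 0) or np.any(ha < 0) \
            or np.any(hha < 0):
        raise ValueError("hazards must be nonnegative")
    s0 = float(np.exp(-(h0 + hic + hh0.sum())))
    sa = np.exp(-(ha + hha.sum()))
    return s0, sa
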