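"""Parameter containers for the harp seal integrated population model.

``ModelParams`` holds every estimable scalar/hyperparameter of the process
model; ``YearEffects`` holds the year-indexed latent deviations (survival and
fecundity random effects, source-specific harvest log-hazards). Both
round-trip through flat JSON documents keyed by symbol name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Human-removal sources, in canonical order.
SOURCES = ("canadian", "arctic", "greenland", "bycatch")
N_SOURCES = len(SOURCES)


@dataclass
class ModelParams:
    """Structural parameters of the process model.

    Log-hazard parameters follow the competing-hazards formulation: natural
    hazards are exponentials of an age quadratic (``alpha1..alpha3``) plus a
    young-of-the-year increment (``upsilon``) and a density/environment
    modifier; harvest hazards are hierarchical with per-source hyper-means
    (``gbar_h0``, ``gbar_ha``, on the log-hazard scale) and between-year SDs
    ``sigma_h``. Abundance enters density terms multiplied by
    ``density_scale`` (individuals -> millions by default) so that ``phi_s``
    and ``phi_f`` are O(0.1-1).
    """

    n0: float = 2.4e6            # initial abundance, individuals, both sexes
    alpha1: float = -2.5         # log hazard of a 1-year-old
    alpha2: float = 0.25         # early-life decline in log hazard with age
    alpha3: float = 0.006        # late-life increase in log hazard with age
    upsilon: float = 0.35        # added YOY log hazard
    phi_s: float = 0.12          # density effect on YOY survival (per million)
    phi_f: float = 0.4           # density effect on fecundity (per million)
    delta: float = 0.25          # climate (NLCI) effect, shared S and F
    zeta: float = 0.2            # adult attenuation of density/env effects
    sigma_s: float = 0.0         # SD of survival random effect eps_S
    sigma_f: float = 0.0         # SD of fecundity random effect eps_F
    psi0: float = 3.0            # ice-hazard threshold
    psi: np.ndarray = field(default_factory=lambda: np.array([1.5, 1.5, 3.5]))
    beta1: float = -2.42         # fecundity baseline (log hazard of not conceiving)
    beta2: float = 0.05          # young-adult age effect on fecundity
    gbar_h0: np.ndarray = field(
        default_factory=lambda: np.array([-0.55, -5.5, -4.2, -4.6]))
    gbar_ha: np.ndarray = field(
        default_factory=lambda: np.array([-2.4, -5.8, -4.2, -6.2]))
    sigma_h: np.ndarray = field(default_factory=lambda: np.zeros(4))
    pi: float = 0.1              # fraction of YOY mortality before pup survey
    eta: float = 30.0            # pregnancy beta-binomial inverse scale
    tau: float = 50.0            # age-composition Dirichlet-multinomial precision
    density_scale: float = 1e-6  # multiplies N in density terms

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.gbar_h0 = np.asarray(self.gbar_h0, dtype=float)
        self.gbar_ha = np.asarray(self.gbar_ha, dtype=float)
        self.sigma_h = np.asarray(self.sigma_h, dtype=float)

    def validate(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        for name in ("sigma_s", "sigma_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if np.any(self.sigma_h < 0):
            raise ValueError("sigma_h must be nonnegative")
        if np.any(self.psi < 0):
            raise ValueError("psi must be nonnegative")
        scalars = [self.alpha1, self.alpha2, self.alpha3, self.upsilon,
                   self.phi_s, self.phi_f, self.delta, self.beta1, self.beta2,
                   self.psi0, self.eta, self.tau]
        if not np.all(np.isfinite(scalars)):
            raise ValueError("hazard-scale parameters must be finite")

    def copy(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    # -- flat JSON serialization keyed by symbol name ------------------
    def to_dict(self) -> dict:
        d = {}
        for k in ("n0", "alpha1", "alpha2", "alpha3", "upsilon", "phi_s",
                  "phi_f", "delta", "zeta", "sigma_s", "sigma_f", "psi0",
                  "beta1", "beta2", "pi", "eta", "tau", "density_scale"):
            d[k] = float(getattr(self, k))
        for a in range(3):
            d[f"psi_{a + 1}"] = float(self.psi[a])
        for j, src in enumerate(SOURCES):
            d[f"gbar_h0_{src}"] = float(self.gbar_h0[j])
            d[f"gbar_ha_{src}"] = float(self.gbar_ha[j])
            d[f"sigma_h_{src}"] = float(self.sigma_h[j])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kwargs = {k: d[k] for k in d
                  if not (k.startswith("psi_") or k.startswith("gbar_")
                          or k.startswith("sigma_h_"))}
        kwargs["psi"] = np.array([d[f"psi_{a + 1}"] for a in range(3)])
        kwargs["gbar_h0"] = np.array([d[f"gbar_h0_{s}"] for s in SOURCES])
        kwargs["gbar_ha"] = np.array([d[f"gbar_ha_{s}"] for s in SOURCES])
        kwargs["sigma_h"] = np.array([d[f"sigma_h_{s}"] for s in SOURCES])
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class YearEffects:
    """Year-indexed latent deviations.

    ``eps_s``, ``eps_f`` are Normal(0, sigma) random-effect series; ``gamma_h0``
    and ``gamma_ha`` are the realized source x year harvest log-hazards
    (shape ``(4, T)``).
    """

    eps_s: np.ndarray
    eps_f: np.ndarray
    gamma_h0: np.ndarray
    gamma_ha: np.ndarray

    @classmethod
    def zeros(cls, n_years: int, params: ModelParams) -> "YearEffects":
        """Year effects at their hierarchical means (no stochasticity)."""
        return cls(
            eps_s=np.zeros(n_years),
            eps_f=np.zeros(n_years),
            gamma_h0=np.tile(params.gbar_h0[:, None], (1, n_years)),
            gamma_ha=np.tile(params.gbar_ha[:, None], (1, n_years)),
        )

    @classmethod
    def draw(cls, n_years: int, params: ModelParams,
             rng: np.random.Generator) -> "YearEffects":
        """Draw year effects from their hierarchical sampling distributions."""
        return cls(
            eps_s=rng.normal(0.0, params.sigma_s, n_years),
            eps_f=rng.normal(0.0, params.sigma_f, n_years),
            gamma_h0=rng.normal(params.gbar_h0[:, None],
                                params.sigma_h[:, None], (N_SOURCES, n_years)),
            gamma_ha=rng.normal(params.gbar_ha[:, None],
                                params.sigma_h[:, None], (N_SOURCES, n_years)),
        )

    @property
    def n_years(self) -> int:
        return len(self.eps_s)
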