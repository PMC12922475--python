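"""CSV/JSON plumbing: environmental tables, trajectories, fit artifacts.

All tabular interchange is plain CSV with headers; run artifacts embed a
config hash and seed so outputs are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import AREAS, EnvironmentSeries
from .likelihoods import ObservationSet
from .params import SOURCES, ModelParams
from .projection import DeathPartition, ProcessState

_P_COLUMNS = [f"p_{a}" for a in AREAS]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    if missing := set(cols) - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def write_env_series(env: EnvironmentSeries, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"year": env.years, "nlci": env.nlci})
    for k, a in enumerate(AREAS):
        df[f"ic_{a}"] = env.ic[k]
    for k, c in enumerate(_P_COLUMNS):
        df[c] = env.p[k]
    df["observed"] = (env.observed_p.astype(int)
                      if env.observed_p is not None else 0)
    df.to_csv(path, index=False)
    meta = {"theta": env.theta.tolist()}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_env_series(path: str | Path) -> EnvironmentSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["year", "nlci", *(f"ic_{a}" for a in AREAS),
                          *_P_COLUMNS, "observed"], path)
    theta = np.ones(3)
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        theta = np.asarray(json.loads(meta_path.read_text())["theta"])
    return EnvironmentSeries(
        years=df["year"].to_numpy(int),
        ic=df[[f"ic_{a}" for a in AREAS]].to_numpy(float).T,
        nlci=df["nlci"].to_numpy(float),
        p=df[_P_COLUMNS].to_numpy(float).T,
        theta=theta,
        observed_p=df["observed"].to_numpy(bool))


def write_trajectory(state: ProcessState, part: DeathPartition | None,
                     out_dir: str | Path) -> None:
    """Tidy per-age trajectory plus an annual summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    A, T = state.n.shape
    tidy = pd.DataFrame({
        "year": np.repeat(state.years, A),
        "age": np.tile(np.arange(1, A + 1), T),
        "n": state.n.T.ravel(),
    })
    tidy.to_csv(out_dir / "trajectory.csv", index=False)
    summary = pd.DataFrame({"year": state.years, "N": state.total,
                            "yoy_prd": state.yoy_prd,
                            "s0": state.rates.s0})
    if part is not None:
        for j, src in enumerate(SOURCES):
            summary[f"removals_prd_{src}"] = part.hv_prd[j]
    summary.to_csv(out_dir / "summary.csv", index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_metadata(config: dict, seed: int | None = None) -> dict:
    try:
        ver = version("harpseal-ipm")
    except PackageNotFoundError:  # running from a source tree
        ver = "unknown"
    return {"config": config, "config_hash": config_hash(config),
            "seed": seed, "package_version": ver}


# -- fit persistence --------------------------------------------------------

def save_fit(draws, out_dir: str | Path) -> None:
    """Persist posterior draws plus everything needed to rebuild the model
    (free parameter list, base parameters, age count, data span)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(out_dir / "draws.csv", index=False)
    draws.summary().to_csv(out_dir / "summary.csv")
    cfg = {
        "free": list(draws.names),
        "base_params": draws.model.base_params.to_dict(),
        "n_ages": draws.model.n_ages,
        "min_age": draws.model.obs.min_age,
        "metadata": draws.metadata,
    }
    (out_dir / "fit_config.json").write_text(
        json.dumps(cfg, indent=1, default=str))


def load_fit(fit_dir: str | Path, obs: ObservationSet,
             env: EnvironmentSeries):
    """Rebuild a :class:`PosteriorDraws` from a saved fit directory."""
    from .inference import IPMModel, PosteriorDraws
    fit_dir = Path(fit_dir)
    cfg = json.loads((fit_dir / "fit_config.json").read_text())
    base = ModelParams.from_dict(cfg["base_params"])
    model = IPMModel(obs, env, base_params=base, free=tuple(cfg["free"]),
                     n_ages=cfg["n_ages"])
    df = pd.read_csv(fit_dir / "draws.csv")
    chains = sorted(df["chain"].unique())
    draws = np.stack([df[df["chain"] == c][cfg["free"]].to_numpy()
                      for c in chains])
    return PosteriorDraws(names=list(cfg["free"]), draws=draws, model=model,
                          metadata=cfg.get("metadata", {}))
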