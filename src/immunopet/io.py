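"""Configuration files, CSV/JSON writers and synthetic PK fixtures.

Configuration is a flat YAML mapping whose keys follow the parameter-table
abbreviations (``pvf``, ``ivf``, ``k_ev``, ``T0``, ``KD``, ``k_syn``,
``k_deg``, ``k_int``, ``ID_l_mg``, ``ID_u_mg``, ``MW``, ``k1``, ``k2``,
``k_cl``, ``V_p``, ``V_t``, ``BW``) plus run options (``scenario``,
``t_end``, ``n_points``, ``output_dir``, ``seed``).  Missing keys take the
published defaults; unknown keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import FLAT_KEYS, ModelParams, Trajectory, params_from_flat, params_to_flat
from .plasma import BiexpParams, PKSample

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "dump_config",
    "params_hash",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_dose_response_csv",
    "write_summary_json",
    "write_pk_csv",
    "read_pk_csv",
    "pk_params_fragment",
    "generate_pk_fixture",
]

logger = logging.getLogger("immunopet")

TRAJECTORY_COLUMNS = [
    "time_h", "Xp_l", "Xp_u", "XRoB_l", "XRoB_u", "Xi_l", "Xi_u",
    "T_nM", "Xr", "f_u", "C_t_nM", "SUV_tumor", "SUV_plasma",
]

RUN_KEYS = ("scenario", "t_end", "n_points", "output_dir", "seed")


class ConfigError(ValueError):
    """A configuration file is malformed or contains unknown keys."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: model parameters plus run options."""

    params: ModelParams = field(default_factory=ModelParams)
    scenario: str | None = None
    t_end: float = 120.0
    n_points: int = 241
    output_dir: str = "."
    seed: int | None = None
    user_keys: tuple[str, ...] = ()  #: keys explicitly set in the file


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a flat YAML config; missing keys fall back to the defaults.

    ``path=None`` or an empty file yields the fully-defaulted configuration.
    Every parameter is logged with its provenance (user-set vs default).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    unknown = set(raw) - set(FLAT_KEYS) - set(RUN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    flat = {k: raw[k] for k in FLAT_KEYS if k in raw}
    defaults = params_to_flat(ModelParams())
    merged = {**defaults, **flat}
    params = params_from_flat(merged)

    for key in FLAT_KEYS:
        provenance = "user" if key in flat else "default"
        logger.debug("config %s=%s (%s)", key, merged[key], provenance)

    cfg = RunConfig(
        params=params,
        scenario=raw.get("scenario"),
        t_end=float(raw.get("t_end", 120.0)),
        n_points=int(raw.get("n_points", 241)),
        output_dir=str(raw.get("output_dir", ".")),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
        user_keys=tuple(sorted(raw)),
    )
    if cfg.t_end <= 0:
        raise ConfigError("t_end must be positive")
    if cfg.n_points < 2:
        raise ConfigError("n_points must be at least 2")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the full effective configuration (round-trips via load_config)."""
    flat = params_to_flat(cfg.params)
    out = {k: v for k, v in flat.items() if v is not None}
    out.update({"scenario": cfg.scenario, "t_end": cfg.t_end,
                "n_points": cfg.n_points, "output_dir": cfg.output_dir,
                "seed": cfg.seed})
    out = {k: v for k, v in out.items() if v is not None}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def params_hash(params: ModelParams) -> str:
    """Short stable hash of a parameter set, for result provenance."""
    flat = params_to_flat(params)
    payload = json.dumps({k: None if v is None else repr(float(v))
                          for k, v in flat.items()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# CSV / JSON writers
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Export a trajectory; floats are written with 17 significant digits so
    reading the file back reproduces the values bit-for-bit."""
    df = traj.to_frame()[TRAJECTORY_COLUMNS]
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory CSV missing column(s): {sorted(missing)}")
    return df


def write_dose_response_csv(points, path: str | Path) -> None:
    from .scenarios import dose_response_frame

    dose_response_frame(points).to_csv(path, index=False)


def write_summary_json(name: str, params: ModelParams, readouts: dict,
                       path: str | Path) -> None:
    """Scenario summary: name, parameter hash and scalar readouts."""
    payload = {"scenario": name, "params_hash": params_hash(params),
               "params": {k: v for k, v in params_to_flat(params).items()},
               "readouts": readouts}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_pk_csv(samples: Sequence[PKSample], path: str | Path) -> None:
    pd.DataFrame(samples, columns=["time_h", "concentration"]).to_csv(
        path, index=False, float_format="%.17g")


def read_pk_csv(path: str | Path) -> list[PKSample]:
    """Read plasma samples from a two-column CSV (time_h, concentration)."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns[:2])
    return [PKSample(float(t), float(c)) for t, c in zip(df[cols[0]], df[cols[1]])]


def pk_params_fragment(pk, path: str | Path) -> None:
    """Write fitted micro rate constants as a config fragment directly
    consumable by load_config."""
    Path(path).write_text(yaml.safe_dump(
        {"k1": float(pk.k1), "k2": float(pk.k2), "k_cl": float(pk.k_cl)}))


# ---------------------------------------------------------------------------
# Synthetic plasma PK fixtures
# ---------------------------------------------------------------------------

def generate_pk_fixture(biexp: BiexpParams, n_samples: int = 20,
                        noise_cv: float = 0.0, seed: int | None = None,
                        t_span: tuple[float, float] = (1.0, 240.0)) -> list[PKSample]:
    """Synthetic plasma concentration samples from a known biexponential.

    Stands in for digitized literature plasma curves when exercising the
    calibration path.  Sample times are log-spaced over ``t_span``; noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``.
    Deterministic for a fixed ``seed``.
    """
    if n_samples < 5:
        raise ConfigError("n_samples must be at least 5")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be non-negative")
    times = np.geomspace(t_span[0], t_span[1], n_samples)
    conc = np.asarray(biexp(times), dtype=float)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        conc = conc * rng.lognormal(mean=0.0, sigma=sigma, size=n_samples)
    return [PKSample(float(t), float(c)) for t, c in zip(times, conc)]
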