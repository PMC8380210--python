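"""Scenario analyses: time-courses, target-concentration dose--response,
IHC classification and inverse estimation of the extravasation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (DEFAULT_EVAL_TIME_H, DomainError, ModelParams, Trajectory,
                    replace_flat, simulate)

__all__ = [
    "IHCBoundaries",
    "DoseResponsePoint",
    "InversionError",
    "time_course",
    "default_t0_grid",
    "dose_response",
    "dose_response_frame",
    "ihc_classify",
    "suv_floor",
    "invert_kev",
]

logger = logging.getLogger("immunopet")


@dataclass(frozen=True)
class IHCBoundaries:
    """Concentration bands (nM) mapping target expression to IHC score.

    Intervals are left-closed / right-open so every concentration has
    exactly one class: IHC0 = [0, b01), IHC1 = [b01, b12), IHC2 = [b12, b23),
    IHC3 = [b23, inf).
    """

    b01: float = 30.0
    b12: float = 120.0
    b23: float = 590.0

    def __post_init__(self) -> None:
        if not (0 < self.b01 < self.b12 < self.b23):
            raise DomainError("IHC boundaries must be strictly increasing and positive")


DEFAULT_IHC = IHCBoundaries()


class InversionError(RuntimeError):
    """The requested SUV cannot be matched by any extravasation rate."""


@dataclass(frozen=True)
class DoseResponsePoint:
    """One point of the uptake vs target-concentration curve."""

    T0: float
    suv_at_eval: float
    f_u_at_eval: float
    ihc_class: int


def time_course(params: ModelParams, T0: float | None = None,
                t_end: float = DEFAULT_EVAL_TIME_H, n_points: int = 241,
                **sim_kwargs) -> Trajectory:
    """Simulate the uptake time-course, optionally overriding the target
    concentration (the synthesis rate stays slaved to ``k_deg * T0`` unless
    it was set explicitly)."""
    if T0 is not None:
        params = replace_flat(params, T0=T0)
    return simulate(params, t_end=t_end, n_points=n_points, **sim_kwargs)


def default_t0_grid() -> np.ndarray:
    """Log-spaced 60-point grid over [0.1, 1000] nM plus the target-free
    point, resolving both the rising limb and the saturation plateau."""
    return np.concatenate([[0.0], np.geomspace(0.1, 1000.0, 60)])


def ihc_classify(T0: float, boundaries: IHCBoundaries = DEFAULT_IHC) -> int:
    """IHC score (0-3) for a target concentration in nM."""
    if T0 < 0:
        raise DomainError("T0 must be non-negative")
    if T0 < boundaries.b01:
        return 0
    if T0 < boundaries.b12:
        return 1
    if T0 < boundaries.b23:
        return 2
    return 3


def dose_response(params: ModelParams, T0_grid: Sequence[float] | None = None,
                  t_eval: float = DEFAULT_EVAL_TIME_H,
                  boundaries: IHCBoundaries = DEFAULT_IHC,
                  **sim_kwargs) -> list[DoseResponsePoint]:
    """Tumor SUV at ``t_eval`` as a function of the target concentration.

    Runs one simulation per grid point; the result is sorted by T0.
    """
    grid = default_t0_grid() if T0_grid is None else np.asarray(T0_grid, dtype=float)
    if np.any(grid < 0):
        raise DomainError("T0 grid values must be non-negative")
    points = []
    for T0 in np.sort(grid):
        traj = time_course(params, T0=float(T0), t_end=t_eval, n_points=2,
                           **sim_kwargs)
        points.append(DoseResponsePoint(
            T0=float(T0),
            suv_at_eval=float(traj.suv_tumor[-1]),
            f_u_at_eval=float(traj.f_u[-1]),
            ihc_class=ihc_classify(float(T0), boundaries),
        ))
    logger.debug("dose_response n=%d t_eval=%g", len(points), t_eval)
    return points


def dose_response_frame(points: Sequence[DoseResponsePoint]) -> pd.DataFrame:
    """Tabular view with the standard export column names."""
    return pd.DataFrame({
        "T0_nM": [p.T0 for p in points],
        "SUV": [p.suv_at_eval for p in points],
        "f_u": [p.f_u_at_eval for p in points],
        "IHC_class": [p.ihc_class for p in points],
    })


def suv_floor(params: ModelParams, t_eval: float = DEFAULT_EVAL_TIME_H) -> float:
    """Vascular-only tumor SUV at ``t_eval`` (no extravasation): the lower
    bound any observed SUV must exceed for the inverse problem."""
    traj = simulate(replace_flat(params, k_ev=0.0), t_end=t_eval, n_points=2)
    return float(traj.suv_tumor[-1])


def invert_kev(observed_suv: float, params: ModelParams,
               t_eval: float = DEFAULT_EVAL_TIME_H,
               bracket: tuple[float, float] = (1e-6, 0.1),
               rtol: float = 1e-6) -> float:
    """Extravasation rate constant (1/h) reproducing an observed tumor SUV.

    Tumor SUV at fixed time is monotone increasing in ``k_ev``, so the root
    of ``SUV(k_ev) - observed_suv`` is unique; it is found with a bracketed
    scalar root finder.  All other parameters are held fixed.
    """
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise DomainError("bracket must satisfy 0 <= lo < hi")
    floor = suv_floor(params, t_eval)
    if observed_suv <= floor:
        raise InversionError(
            f"observed SUV {observed_suv:.4g} is at or below the vascular-only "
            f"floor {floor:.4g}; no extravasation rate can reproduce it")

    def objective(k_ev: float) -> float:
        traj = simulate(replace_flat(params, k_ev=k_ev), t_end=t_eval, n_points=2)
        return float(traj.suv_tumor[-1]) - observed_suv

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise InversionError(
            f"bracket {bracket} does not straddle the observed SUV "
            f"(f(lo)={f_lo:.4g}, f(hi)={f_hi:.4g}); widen the bracket")
    k_ev = float(brentq(objective, lo, hi, rtol=rtol))
    logger.debug("invert_kev suv=%g t_eval=%g -> k_ev=%.6g", observed_suv, t_eval, k_ev)
    return k_ev
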