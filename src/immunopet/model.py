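"""Mechanistic model of radiolabeled-antibody disposition in tumor tissue.

The model tracks a labeled (``l``) and an unlabeled (``u``) antibody species
through plasma, a remainder-of-body exchange compartment and the tumor
interstitial space, with quasi-equilibrium binding to a cell-surface target,
target turnover, and irreversible trapping of the residualizing radiolabel
after internalization of antibody--target complexes.  The readout is the
standardized uptake value (SUV) of the label in the tumor.

Units convention: time in hours, amounts in nmole, concentrations in nM,
volumes in litres.  SUV is dimensionless assuming tissue density 1 g/mL
(so nM is numerically nmol/kg).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DomainError",
    "IntegrationError",
    "TumorTissueParams",
    "TargetParams",
    "DoseParams",
    "PlasmaPKParams",
    "FixedParams",
    "ModelParams",
    "ModelState",
    "Trajectory",
    "mass_to_moles",
    "fraction_unbound",
    "ode_rhs",
    "simulate",
    "FLAT_KEYS",
    "params_to_flat",
    "params_from_flat",
    "replace_flat",
]

logger = logging.getLogger("immunopet")

DEFAULT_EVAL_TIME_H = 120.0  #: standard readout time, hours post-injection


class DomainError(ValueError):
    """An input is outside the physical domain of the operation."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorTissueParams:
    """Tumor tissue composition and vascular exchange.

    pvf
        Plasma (vascular) volume fraction of the tumor, dimensionless.
    ivf
        Interstitial volume fraction accessible to antibody, dimensionless.
    k_ev
        Extravasation rate constant (1/h), lumping vascular permeability and
        the degree of vascularization.
    """

    pvf: float = 0.04
    ivf: float = 0.2
    k_ev: float = 0.012

    def __post_init__(self) -> None:
        if self.pvf < 0 or self.ivf < 0:
            raise DomainError("volume fractions must be non-negative")
        if self.pvf + self.ivf > 1.0 + 1e-12:
            raise DomainError("pvf + ivf must not exceed 1")
        if self.k_ev < 0:
            raise DomainError("k_ev must be non-negative")


@dataclass(frozen=True)
class TargetParams:
    """Target (antigen) concentration, affinity and turnover.

    T0
        Initial (pre-dose steady-state) target concentration in the
        interstitial space, nM.
    KD
        Equilibrium dissociation constant of the antibody--target complex, nM.
    k_syn
        Zeroth-order target synthesis rate, nM/h.  ``None`` (the default)
        derives it as ``k_deg * T0``, the pre-therapy synthesis/degradation
        balance.
    k_deg
        First-order degradation rate of free target, 1/h.
    k_int
        First-order internalization rate of antibody--target complexes, 1/h.
    """

    T0: float = 0.0
    KD: float = 5.0
    k_deg: float = 0.19
    k_int: float = 0.19
    k_syn: float | None = None

    def __post_init__(self) -> None:
        vals = [self.T0, self.KD, self.k_deg, self.k_int]
        if self.k_syn is not None:
            vals.append(self.k_syn)
        if any(v < 0 for v in vals):
            raise DomainError("target parameters must be non-negative")

    @property
    def k_syn_effective(self) -> float:
        """Synthesis rate actually used: explicit, or ``k_deg * T0``."""
        return self.k_deg * self.T0 if self.k_syn is None else self.k_syn


@dataclass(frozen=True)
class DoseParams:
    """Injected antibody doses.

    ID_l_mass, ID_u_mass
        Injected mass of labeled / unlabeled antibody, mg.
    molecular_weight
        Antibody molar mass, g/mol; default 150 000 (standard IgG
        approximation).  It sets where dose-driven target saturation occurs
        but cancels out of SUV in the linear (target-free) regime.
    """

    ID_l_mass: float = 3.0
    ID_u_mass: float = 47.0
    molecular_weight: float = 150_000.0

    def __post_init__(self) -> None:
        if self.ID_l_mass < 0 or self.ID_u_mass < 0:
            raise DomainError("doses must be non-negative")
        if self.molecular_weight <= 0:
            raise DomainError("molecular_weight must be positive")

    @property
    def ID_l(self) -> float:
        """Labeled dose in nmole."""
        return mass_to_moles(self.ID_l_mass, self.molecular_weight)

    @property
    def ID_u(self) -> float:
        """Unlabeled dose in nmole."""
        return mass_to_moles(self.ID_u_mass, self.molecular_weight)


@dataclass(frozen=True)
class PlasmaPKParams:
    """Two-compartment systemic pharmacokinetics driving tumor uptake.

    k1 : plasma -> normal-tissue exchange rate, 1/h.
    k2 : normal-tissue -> plasma exchange rate, 1/h.
    k_cl : first-order clearance from plasma, 1/h.
    """

    k1: float = 0.0722
    k2: float = 0.1366
    k_cl: float = 0.0083

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0 or self.k_cl < 0:
            raise DomainError("plasma PK rates must be non-negative")


@dataclass(frozen=True)
class FixedParams:
    """Anatomical constants: plasma volume, tumor volume, body weight."""

    V_p: float = 3.0
    V_t: float = 0.001
    BW: float = 80.0

    def __post_init__(self) -> None:
        if self.V_p <= 0 or self.V_t <= 0 or self.BW <= 0:
            raise DomainError("volumes and body weight must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle for one simulation."""

    tissue: TumorTissueParams = field(default_factory=TumorTissueParams)
    target: TargetParams = field(default_factory=TargetParams)
    dose: DoseParams = field(default_factory=DoseParams)
    pk: PlasmaPKParams = field(default_factory=PlasmaPKParams)
    fixed: FixedParams = field(default_factory=FixedParams)

    @classmethod
    def default(cls) -> "ModelParams":
        return cls()


# Flat-key access (config files, sensitivity analysis) ----------------------

FLAT_KEYS: tuple[str, ...] = (
    "pvf", "ivf", "k_ev",
    "T0", "KD", "k_syn", "k_deg", "k_int",
    "ID_l_mg", "ID_u_mg", "MW",
    "k1", "k2", "k_cl",
    "V_p", "V_t", "BW",
)

_FLAT_MAP = {
    "pvf": ("tissue", "pvf"), "ivf": ("tissue", "ivf"), "k_ev": ("tissue", "k_ev"),
    "T0": ("target", "T0"), "KD": ("target", "KD"), "k_syn": ("target", "k_syn"),
    "k_deg": ("target", "k_deg"), "k_int": ("target", "k_int"),
    "ID_l_mg": ("dose", "ID_l_mass"), "ID_u_mg": ("dose", "ID_u_mass"),
    "MW": ("dose", "molecular_weight"),
    "k1": ("pk", "k1"), "k2": ("pk", "k2"), "k_cl": ("pk", "k_cl"),
    "V_p": ("fixed", "V_p"), "V_t": ("fixed", "V_t"), "BW": ("fixed", "BW"),
}


def params_to_flat(params: ModelParams) -> dict[str, float | None]:
    """Flatten a :class:`ModelParams` to the flat key convention."""
    return {k: getattr(getattr(params, grp), attr) for k, (grp, attr) in _FLAT_MAP.items()}


def params_from_flat(flat: dict[str, float | None]) -> ModelParams:
    """Build :class:`ModelParams` from flat keys; unknown keys raise."""
    unknown = set(flat) - set(FLAT_KEYS)
    if unknown:
        raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
    groups: dict[str, dict[str, float | None]] = {}
    for key, value in flat.items():
        grp, attr = _FLAT_MAP[key]
        groups.setdefault(grp, {})[attr] = value
    return ModelParams(
        tissue=TumorTissueParams(**groups.get("tissue", {})),
        target=TargetParams(**groups.get("target", {})),
        dose=DoseParams(**groups.get("dose", {})),
        pk=PlasmaPKParams(**groups.get("pk", {})),
        fixed=FixedParams(**groups.get("fixed", {})),
    )


def replace_flat(params: ModelParams, **overrides: float | None) -> ModelParams:
    """Return a copy of ``params`` with flat-key overrides applied.

    Overriding ``T0`` or ``k_deg`` while ``k_syn`` is derived (``None``)
    keeps the derivation, preserving the pre-dose steady state.
    """
    flat = params_to_flat(params)
    for key, value in overrides.items():
        if key not in _FLAT_MAP:
            raise DomainError(f"unknown parameter key: {key!r}")
        flat[key] = value
    return params_from_flat(flat)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

class ModelState(NamedTuple):
    """The eight-dimensional model state.

    Amounts are nmole; ``T`` is the free-target concentration in nM.
    """

    Xp_l: float    #: labeled antibody in plasma
    Xp_u: float    #: unlabeled antibody in plasma
    XRoB_l: float  #: labeled antibody in remainder of body
    XRoB_u: float  #: unlabeled antibody in remainder of body
    Xi_l: float    #: labeled antibody in tumor interstitium
    Xi_u: float    #: unlabeled antibody in tumor interstitium
    T: float       #: free target concentration (nM)
    Xr: float      #: residualized radiolabel in tumor cells

    @classmethod
    def initial(cls, params: ModelParams) -> "ModelState":
        """Bolus initial condition: all antibody in plasma, target at T0."""
        return cls(params.dose.ID_l, params.dose.ID_u, 0.0, 0.0, 0.0, 0.0,
                   params.target.T0, 0.0)


STATE_NAMES = ModelState._fields


# ---------------------------------------------------------------------------
# Binding equilibrium
# ---------------------------------------------------------------------------

def fraction_unbound(Xi_l: float, Xi_u: float, T: float, KD: float,
                     ivf: float, V_t: float) -> float:
    """Fraction of interstitial antibody not bound to target.

    Binding is treated as an instantaneous mass-action equilibrium between
    the combined (labeled + unlabeled) interstitial antibody at total
    concentration ``A = (Xi_l + Xi_u)/(ivf*V_t)`` and target at
    concentration ``T``; the bound concentration is the physical root of

        B**2 - (KD + T + A)*B + A*T = 0

    and ``f_u = 1 - B/A``.  Evaluated in the cancellation-safe conjugate
    form ``f_u = 1 - 2*T/(s + sqrt(s**2 - 4*A*T))`` with ``s = KD + T + A``,
    which is exact for ``A -> 0`` as well (limit ``KD/(KD+T)``).
    """
    if min(Xi_l, Xi_u, T, KD) < 0:
        raise DomainError("fraction_unbound: negative input")
    vol = ivf * V_t
    if vol <= 0:
        raise DomainError("fraction_unbound: ivf*V_t must be positive")
    A = (Xi_l + Xi_u) / vol
    s = KD + T + A
    if s == 0.0:  # KD = T = A = 0: nothing to bind to
        return 1.0
    disc = s * s - 4.0 * A * T
    fu = 1.0 - 2.0 * T / (s + math.sqrt(max(disc, 0.0)))
    return min(max(fu, 0.0), 1.0)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def ode_rhs(t: float, state: np.ndarray | ModelState,
            params: ModelParams) -> np.ndarray:
    """Time derivatives of the eight state variables.

    Labeled and unlabeled species follow identical kinetics and share a
    single unbound fraction computed from their combined interstitial
    amount.  Tiny negative solver excursions are clamped to zero before the
    binding equilibrium is evaluated.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise IntegrationError(f"non-finite state component(s): {bad}")
    Xp_l, Xp_u, XRoB_l, XRoB_u, Xi_l, Xi_u, T, Xr = np.maximum(y, 0.0)

    ts, tg, pk, fx = params.tissue, params.target, params.pk, params.fixed
    fu = fraction_unbound(Xi_l, Xi_u, T, tg.KD, ts.ivf, fx.V_t)

    # per-species extravasation flux (nmole/h), concentration-gradient driven
    ev_l = ts.k_ev * (Xp_l / fx.V_p * fx.V_t - fu * Xi_l / ts.ivf)
    ev_u = ts.k_ev * (Xp_u / fx.V_p * fx.V_t - fu * Xi_u / ts.ivf)

    dXp_l = -(pk.k1 + pk.k_cl) * Xp_l + pk.k2 * XRoB_l - ev_l
    dXp_u = -(pk.k1 + pk.k_cl) * Xp_u + pk.k2 * XRoB_u - ev_u
    dXRoB_l = pk.k1 * Xp_l - pk.k2 * XRoB_l
    dXRoB_u = pk.k1 * Xp_u - pk.k2 * XRoB_u
    dXi_l = ev_l - tg.k_int * (1.0 - fu) * Xi_l
    dXi_u = ev_u - tg.k_int * (1.0 - fu) * Xi_u
    # bound complexes are removed by internalization instead of degradation
    dT = (tg.k_syn_effective - tg.k_deg * T
          - (tg.k_int - tg.k_deg) * (1.0 - fu) * (Xi_l + Xi_u) / (ts.ivf * fx.V_t))
    dXr = tg.k_int * (1.0 - fu) * Xi_l

    return np.array([dXp_l, dXp_u, dXRoB_l, dXRoB_u, dXi_l, dXi_u, dT, dXr])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model states plus derived imaging quantities.

    ``states`` has shape ``(n_times, 8)`` with columns in
    :data:`STATE_NAMES` order.  ``C_t`` is the total label concentration in
    the tumor (nM); ``suv_tumor`` and ``suv_plasma`` are standardized uptake
    values.
    """

    times: np.ndarray
    states: np.ndarray
    f_u: np.ndarray
    C_t: np.ndarray
    suv_tumor: np.ndarray
    suv_plasma: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the standard export column names."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df = df.rename(columns={"T": "T_nM"})
        df.insert(0, "time_h", self.times)
        df["f_u"] = self.f_u
        df["C_t_nM"] = self.C_t
        df["SUV_tumor"] = self.suv_tumor
        df["SUV_plasma"] = self.suv_plasma
        return df

    def at(self, time: float) -> pd.Series:
        """Row of derived quantities at grid time ``time`` (must be on grid)."""
        idx = int(np.argmin(np.abs(self.times - time)))
        if not math.isclose(self.times[idx], time, rel_tol=1e-9, abs_tol=1e-9):
            raise DomainError(f"time {time} h is not on the simulation grid")
        return self.to_frame().iloc[idx]


def simulate(params: ModelParams, t_end: float = DEFAULT_EVAL_TIME_H,
             n_points: int = 241, method: str = "LSODA",
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the model from the bolus initial condition.

    Returns a :class:`Trajectory` on a uniform grid of ``n_points`` times in
    ``[0, t_end]``, with the unbound fraction, tumor label concentration

        C_t = (Xp_l / V_p) * pvf + (Xi_l + Xr) / V_t

    and the SUVs ``suv_tumor = C_t * BW / ID_l`` and
    ``suv_plasma = (Xp_l / V_p) * BW / ID_l`` attached.
    """
    if t_end <= 0:
        raise DomainError("t_end must be positive")
    if n_points < 2:
        raise DomainError("n_points must be at least 2")
    y0 = np.array(ModelState.initial(params), dtype=float)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(ode_rhs, (0.0, t_end), y0, args=(params,), method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(
            f"solver {method} failed (rtol={rtol}, atol={atol}): {sol.message}")

    states = np.maximum(sol.y.T, 0.0)  # clamp solver-noise negatives
    ts, tg, fx = params.tissue, params.target, params.fixed
    fu = np.array([
        fraction_unbound(s[4], s[5], s[6], tg.KD, ts.ivf, fx.V_t)
        for s in states
    ])
    Cp_l = states[:, 0] / fx.V_p
    C_t = Cp_l * ts.pvf + (states[:, 4] + states[:, 7]) / fx.V_t
    ID_l = params.dose.ID_l
    if ID_l <= 0:
        raise DomainError("labeled dose must be positive to define SUV")
    suv_tumor = C_t * fx.BW / ID_l
    suv_plasma = Cp_l * fx.BW / ID_l

    logger.debug("simulate t_end=%g n=%d suv_tumor(end)=%.6g",
                 t_end, n_points, suv_tumor[-1])
    return Trajectory(times=sol.t, states=states, f_u=fu, C_t=C_t,
                      suv_tumor=suv_tumor, suv_plasma=suv_plasma)


def suv_at(params: ModelParams, t_eval: float = DEFAULT_EVAL_TIME_H,
           **sim_kwargs) -> float:
    """Tumor SUV at a single time point (integrates up to ``t_eval``)."""
    traj = simulate(params, t_end=t_eval, n_points=2, **sim_kwargs)
    return float(traj.suv_tumor[-1])


def mass_to_moles(mass: float, molecular_weight: float) -> float:
    """Convert an antibody mass in mg to nmole: ``mass * 1e6 / MW``."""
    if mass < 0:
        raise DomainError("mass must be non-negative")
    if molecular_weight <= 0:
        raise DomainError("molecular_weight must be positive")
    return mass * 1e6 / molecular_weight
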