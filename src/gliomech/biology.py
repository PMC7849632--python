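"""Go-or-grow phenotype dynamics and oxygen transport.

Three cell populations share the radial grid: proliferative ``C_p``
(fast-dividing, weakly motile), hypoxic ``C_m`` (motile, slowly dividing
or quiescent) and necrotic ``C_n`` (inert, never removed).  Oxygen is the
only metabolite; smooth tanh switch factors centred on the hypoxia and
necrosis thresholds drive the phenotype transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .numerics import (CFLError, RadialGrid, advect_fct, courant_number,
                       diffuse_cn)
from .params import SimulationParams

__all__ = [
    "CellFields",
    "OxygenField",
    "switch_factors",
    "phenotype_sources",
    "oxygen_step",
    "cell_transport_step",
]

logger = logging.getLogger(__name__)

#: hard cap on advective sub-cycles before giving up
_MAX_SUBCYCLES = 64


@dataclass
class CellFields:
    """Radial concentration profiles of the three phenotypes (cells/mm^3)."""

    C_p: np.ndarray
    C_m: np.ndarray
    C_n: np.ndarray

    @property
    def C_tot(self) -> np.ndarray:
        return self.C_p + self.C_m + self.C_n

    def copy(self) -> "CellFields":
        return CellFields(self.C_p.copy(), self.C_m.copy(), self.C_n.copy())

    def validate(self) -> None:
        for name in ("C_p", "C_m", "C_n"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative concentrations")


@dataclass
class OxygenField:
    """Radial oxygen concentration profile (mg/L)."""

    n_ox: np.ndarray

    def copy(self) -> "OxygenField":
        return OxygenField(self.n_ox.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.n_ox)):
            raise ValueError("n_ox contains non-finite values")
        if np.any(self.n_ox < 0):
            raise ValueError("n_ox contains negative concentrations")


def switch_factors(n_ox: np.ndarray | float, params: SimulationParams):
    """Smooth step factors (h_pm, h_mp, h_nec) in (0, 1).

    h_pm = (1 - tanh((n_ox - xi_h)/lambda))/2 rises towards 1 below the
    hypoxia threshold; h_mp = 1 - h_pm is its reverse; h_nec is the same
    sigmoid centred on the necrosis threshold.
    """
    n = np.asarray(n_ox, dtype=float)
    lam = params.lambda_switch
    h_pm = 0.5 * (1.0 - np.tanh((n - params.xi_h) / lam))
    h_mp = 1.0 - h_pm
    h_nec = 0.5 * (1.0 - np.tanh((n - params.xi_n) / lam))
    return h_pm, h_mp, h_nec


def phenotype_sources(C_p, C_m, C_n, n_ox, params: SimulationParams):
    """Source terms (S_p, S_m, S_n) in cells/(mm^3 day).

    Logistic proliferation scaled by oxygen availability n_ox/n_max, plus
    the three phenotype transitions.  Transitions conserve cells exactly:
    S_p + S_m + S_n reduces to the proliferation terms alone.  The logistic
    factor is clamped at zero on transient overshoot above the carrying
    capacity (crowding halts division but does not kill).
    """
    C_p = np.asarray(C_p, dtype=float)
    C_m = np.asarray(C_m, dtype=float)
    C_n = np.asarray(C_n, dtype=float)
    C_tot = C_p + C_m + C_n
    logistic = 1.0 - C_tot / params.C_q
    if np.any(logistic < 0):
        logger.debug("carrying-capacity overshoot: logistic factor clamped at 0")
        logistic = np.clip(logistic, 0.0, None)
    oxy = np.asarray(n_ox, dtype=float) / params.n_max
    h_pm, h_mp, h_nec = switch_factors(n_ox, params)
    growth_p = C_p / params.tau_p * logistic * oxy
    growth_m = params.h_m_flag * C_m / params.tau_m * logistic * oxy
    t_pm = h_pm * C_p / params.tau_pm
    t_mp = h_mp * C_m / params.tau_mp
    t_nec = h_nec * C_m / params.tau_n
    S_p = growth_p - t_pm + t_mp
    S_m = growth_m + t_pm - t_mp - t_nec
    S_n = t_nec
    return S_p, S_m, S_n


def oxygen_step(n_ox: np.ndarray, C_p: np.ndarray, C_m: np.ndarray,
                dt: float, params: SimulationParams, grid: RadialGrid) -> np.ndarray:
    """One split step of oxygen transport: CN diffusion, then explicit uptake.

    Uptake -(alpha_p C_p + alpha_m C_m) dt is not modulated by n_ox; the
    result is clamped at zero (the clamped mass is logged at debug level).
    Boundary: closed wall under RBC, fixed n0 under PSBC.
    """
    bc = ("dirichlet", params.n0) if params.oxygen_bc == "PSBC" else "no_flux"
    n = diffuse_cn(n_ox, params.D_ox, dt, grid, bc=bc)
    n = n - (params.alpha_p * C_p + params.alpha_m * C_m) * dt
    neg = n < 0.0
    if np.any(neg):
        clamped = -float(np.dot(grid.w[neg], n[neg]))
        logger.debug("oxygen clamped at 0 (deficit mass %.3g mg)", clamped)
        n = np.clip(n, 0.0, None)
    if params.oxygen_bc == "PSBC":
        n[-1] = params.n0
    return n


def _advect_subcycled(field: np.ndarray, v: np.ndarray, dt: float,
                      grid: RadialGrid) -> np.ndarray:
    """FCT advection with automatic sub-cycling to satisfy the CFL contract."""
    nu = courant_number(v, dt, grid)
    n_sub = max(1, int(np.ceil(nu / 0.45)))
    if n_sub > _MAX_SUBCYCLES:
        raise CFLError(
            f"advection needs {n_sub} sub-cycles (Courant {nu:.3g} at dt={dt}); "
            "the flow is too fast for the chosen dt/dr")
    sub = dt / n_sub
    out = field
    for _ in range(n_sub):
        out = advect_fct(out, v, sub, grid)
    return out


def cell_transport_step(fields: CellFields, v_D: np.ndarray, dt: float,
                        n_ox: np.ndarray, params: SimulationParams,
                        grid: RadialGrid) -> CellFields:
    """One split transport step for all phenotypes.

    Per phenotype: FCT advection with the shared drift velocity, then
    Crank–Nicolson diffusion (D_p / D_m; necrotic cells do not move), then
    an explicit Euler source update, then a clamp at zero with the corrected
    mass logged.  All cell boundaries are no-flux.
    """
    C_p = _advect_subcycled(fields.C_p, v_D, dt, grid)
    C_m = _advect_subcycled(fields.C_m, v_D, dt, grid)
    C_n = _advect_subcycled(fields.C_n, v_D, dt, grid)
    if params.D_p > 0:
        C_p = diffuse_cn(C_p, params.D_p, dt, grid, bc="no_flux")
    if params.D_m > 0:
        C_m = diffuse_cn(C_m, params.D_m, dt, grid, bc="no_flux")
    S_p, S_m, S_n = phenotype_sources(C_p, C_m, C_n, n_ox, params)
    C_p = C_p + S_p * dt
    C_m = C_m + S_m * dt
    C_n = C_n + S_n * dt
    for name, arr in (("C_p", C_p), ("C_m", C_m), ("C_n", C_n)):
        neg = arr < 0.0
        if np.any(neg):
            corrected = -float(np.dot(grid.w[neg], arr[neg]))
            logger.debug("%s clamped at 0 (mass correction %.3g cells)", name, corrected)
            np.clip(arr, 0.0, None, out=arr)
    return CellFields(C_p, C_m, C_n)
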