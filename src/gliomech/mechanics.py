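"""Stress structure of the cell–ECM composite.

The cell aggregate carries an intercellular stress ``sigma_C`` that changes
sign at the equilibrium concentration: repulsive (positive) above ``C_eq``,
adhesive traction (negative) between the cut-off ``C_inf`` and ``C_eq``,
with the 27/4-normalised quadratic envelope guaranteeing that the deepest
traction equals exactly ``-sigma_att`` at C = (2 C_eq + C_inf)/3.

The ECM is a compressible linear-elastic scaffold; its displacement field is
driven by the gradient of the intercellular stress (quasi-static balance),
and the composite total stress follows the iso-strain mixture rule weighted
by the cell volume fraction.  The drift velocity of cells down the total
stress gradient is Darcy-like, optionally modulated by the pore-stretch
permeability factor (1 - eps_v/3)^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .numerics import RadialGrid, radial_gradient, solve_displacement
from .params import SimulationParams

__all__ = [
    "MechanicalState",
    "adhesion_prefactor",
    "intercellular_stress",
    "ecm_stress",
    "total_stress",
    "drift_velocity",
    "solve_mechanics",
]

logger = logging.getLogger(__name__)


@dataclass
class MechanicalState:
    """Quasi-static mechanical fields on the radial grid (mm / Pa / mm·day⁻¹)."""

    u: np.ndarray            # ECM displacement
    eps_rr: np.ndarray       # radial strain du/dr
    eps_tt: np.ndarray       # tangential strain u/r
    eps_v: np.ndarray        # dilatation eps_rr + 2 eps_tt
    sigma_C: np.ndarray      # intercellular stress
    sigma_rr: np.ndarray     # ECM radial stress
    sigma_tt: np.ndarray     # ECM tangential stress
    sigma_ECM: np.ndarray    # (2 sigma_tt + sigma_rr)/3
    sigma_tot: np.ndarray    # iso-strain composite stress
    v_D: np.ndarray          # drift velocity
    phi_c: np.ndarray        # cell volume fraction C_tot/C_max


def adhesion_prefactor(C_tot: np.ndarray | float, params: SimulationParams) -> np.ndarray:
    """Piecewise prefactor gamma(C_tot) of the intercellular stress law.

    gamma = 1 above C_eq (linear repulsive branch); on [C_inf, C_eq) the
    quadratic adhesion envelope whose 27/4 normalisation pins the deepest
    traction to -sigma_att; 0 below the interaction cut-off.
    """
    C = np.asarray(C_tot, dtype=float)
    C_eq, C_inf = params.C_eq, params.C_inf
    gamma_adh = (27.0 / 4.0) * (params.sigma_att / params.K_C0) * C_eq \
        * (C - C_inf) ** 2 / (C_eq - C_inf) ** 3
    return np.where(C >= C_eq, 1.0, np.where(C >= C_inf, gamma_adh, 0.0))


def intercellular_stress(C_tot: np.ndarray | float, params: SimulationParams) -> np.ndarray:
    """Intercellular stress sigma_C(C_tot) = gamma * K_C0 * (C_tot/C_eq - 1).

    sigma_C is continuous everywhere (both branch boundaries of gamma
    evaluate to zero stress).
    """
    C = np.asarray(C_tot, dtype=float)
    return adhesion_prefactor(C, params) * params.K_C0 * (C / params.C_eq - 1.0)


def ecm_stress(u: np.ndarray, params: SimulationParams, grid: RadialGrid):
    """Strains and ECM stresses from the displacement profile.

    eps_rr = du/dr (centred differences, one-sided at the boundaries),
    eps_tt = u/r with the symmetry limit eps_tt(0) = eps_rr(0);
    sigma_rr = K_ECM/(1+nu) * ((1-nu) eps_rr + 2 nu eps_tt),
    sigma_tt = K_ECM/(1+nu) * (nu eps_rr + eps_tt).

    Returns (eps_rr, eps_tt, eps_v, sigma_rr, sigma_tt, sigma_ECM).
    """
    eps_rr = radial_gradient(u, grid)
    eps_tt = np.empty_like(eps_rr)
    eps_tt[1:] = u[1:] / grid.r[1:]
    eps_tt[0] = eps_rr[0]
    eps_v = eps_rr + 2.0 * eps_tt
    pref = params.K_ECM / (1.0 + params.nu_ECM)
    nu = params.nu_ECM
    sigma_rr = pref * ((1.0 - nu) * eps_rr + 2.0 * nu * eps_tt)
    sigma_tt = pref * (nu * eps_rr + eps_tt)
    sigma_ECM = (2.0 * sigma_tt + sigma_rr) / 3.0
    return eps_rr, eps_tt, eps_v, sigma_rr, sigma_tt, sigma_ECM


def total_stress(sigma_C: np.ndarray, sigma_ECM: np.ndarray,
                 C_tot: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Iso-strain composite stress, volume-fraction-weighted mixture."""
    C = np.asarray(C_tot, dtype=float)
    if np.any(C > params.C_max) or np.any(C < 0.0):
        over = float(np.max(C - params.C_max, initial=0.0))
        logger.warning("C_tot outside [0, C_max] (max overshoot %.3g); clipping for the mixture rule", over)
        C = np.clip(C, 0.0, params.C_max)
    phi = C / params.C_max
    return (1.0 - phi) * sigma_ECM + phi * sigma_C


def drift_velocity(sigma_tot: np.ndarray, eps_v: np.ndarray,
                   params: SimulationParams, grid: RadialGrid) -> np.ndarray:
    """Darcy drift v_D = -M_eff * d(sigma_tot)/dr, with v_D(0) = 0 by symmetry.

    In "strain" permeability mode M_eff = M0 * max(0, 1 - eps_v/3)^2: matrix
    compression closes pores and slows cells, tension opens them.
    """
    grad = radial_gradient(sigma_tot, grid)
    if params.permeability_mode == "strain":
        factor = np.clip(1.0 - eps_v / 3.0, 0.0, None) ** 2
        M_eff = params.M0 * factor
    else:
        M_eff = params.M0
    v = -M_eff * grad
    v = np.asarray(v, dtype=float).copy()
    v[0] = 0.0
    return v


def solve_mechanics(C_tot: np.ndarray, params: SimulationParams,
                    grid: RadialGrid) -> MechanicalState:
    """Full quasi-static mechanics solve for a given total cell concentration.

    Pipeline: intercellular stress -> volumetric source
    delta_v = (1/K_ECM) d(sigma_C)/dr -> displacement BVP -> ECM strains and
    stresses -> iso-strain total stress -> drift velocity.
    """
    sigma_C = intercellular_stress(C_tot, params)
    if params.delta_v_form == "gamma_outside":
        # chain-rule approximation: gamma frozen outside the derivative
        C = np.asarray(C_tot, dtype=float)
        delta_v = adhesion_prefactor(C, params) * params.K_C0 / params.K_ECM \
            * radial_gradient(C / params.C_eq, grid)
    else:
        delta_v = radial_gradient(sigma_C, grid) / params.K_ECM
    u = solve_displacement(delta_v, params.nu_ECM, grid)
    eps_rr, eps_tt, eps_v, sigma_rr, sigma_tt, sigma_ECM = ecm_stress(u, params, grid)
    sigma_tot = total_stress(sigma_C, sigma_ECM, C_tot, params)
    v_D = drift_velocity(sigma_tot, eps_v, params, grid)
    phi_c = np.clip(np.asarray(C_tot, dtype=float) / params.C_max, 0.0, 1.0)
    return MechanicalState(u=u, eps_rr=eps_rr, eps_tt=eps_tt, eps_v=eps_v,
                           sigma_C=sigma_C, sigma_rr=sigma_rr, sigma_tt=sigma_tt,
                           sigma_ECM=sigma_ECM, sigma_tot=sigma_tot, v_D=v_D,
                           phi_c=phi_c)
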