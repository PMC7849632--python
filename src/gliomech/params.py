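"""Physical parameters of the cell–ECM composite model.

All quantities are stored internally in a single unit system:
millimetre, day, pascal, mg/L (oxygen), cells/mm^3.  The closed-form
derivation helpers below accept the units the source measurements are
quoted in (μm, pN, m², Pa·s) and convert on the way in.

The parameter set couples three ingredient groups:

* cell-packing geometry — single-cell volume fixes the maximal packing
  concentration ``C_max``; intercellular force–distance characteristics fix
  the cut-off (``C_inf``), maximum-attraction (``C_att``) and equilibrium
  (``C_eq``) concentrations of the visco-elastic cell aggregate;
* rheology — bulk moduli of the cell aggregate (``K_C0``) and the elastic
  compressible ECM scaffold (``K_ECM`` from Young's modulus and Poisson
  ratio), Darcy-type mobility ``M0 = k0/mu`` of cells forced through the
  scaffold;
* go-or-grow biology — phenotype diffusivities, doubling and transition
  times, oxygen uptake rates and the hypoxia/necrosis thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ParameterError",
    "SimulationParams",
    "max_packing_concentration",
    "concentration_from_spacing",
    "max_contractile_stress",
    "mobility_from_permeability",
    "bulk_modulus_from_young",
    "load_config",
]

#: μm^3 per mm^3
_UM3_PER_MM3 = 1.0e9
#: conversion m^2/(Pa·s) -> mm^2/(Pa·day)
_M2_PAS_TO_MM2_PADAY = 1.0e6 * 86400.0


class ParameterError(ValueError):
    """A physical parameter violates its validity constraint."""


# ---------------------------------------------------------------------------
# closed-form parameter derivations
# ---------------------------------------------------------------------------

def max_packing_concentration(v_cell_um3: float) -> float:
    """Maximal packing concentration (cells/mm^3) from single-cell volume (μm^3).

    Dense packing with no fluid or matrix content corresponds to one cell
    per cell volume, ``C_max = 1/V_cell``.
    """
    if v_cell_um3 <= 0:
        raise ParameterError(f"cell volume must be positive, got {v_cell_um3}")
    return _UM3_PER_MM3 / v_cell_um3


def concentration_from_spacing(r_um: float) -> float:
    """Concentration (cells/mm^3) at uniform centre-to-centre spacing r (μm).

    Assumes cubic packing: one cell per r^3 volume.  Used to translate the
    characteristic separations of the intercellular force–distance curve
    (cut-off and maximum-attraction distances) into concentrations.
    """
    if r_um <= 0:
        raise ParameterError(f"spacing must be positive, got {r_um}")
    return _UM3_PER_MM3 / r_um**3


def max_contractile_stress(f_max_pn: float, n_neighbors: float, s_cell_um2: float) -> float:
    """Maximum adhesive (contractile) stress in Pa.

    ``n_neighbors`` adhesive contacts, each exerting up to ``f_max`` (pN),
    act over the cell surface area ``S_cell`` (μm^2).  1 pN/μm^2 = 1 Pa.
    """
    if f_max_pn < 0:
        raise ParameterError(f"force must be non-negative, got {f_max_pn}")
    if n_neighbors <= 0 or s_cell_um2 <= 0:
        raise ParameterError("neighbor count and surface area must be positive")
    return n_neighbors * f_max_pn / s_cell_um2


def mobility_from_permeability(k_m2: float, mu_pa_s: float) -> float:
    """Darcy mobility M = k/μ converted to mm^2/(Pa·day).

    ``k`` is the hydrogel permeability (m^2) and ``μ`` the dynamic viscosity
    of the cell phase (Pa·s).
    """
    if k_m2 <= 0 or mu_pa_s <= 0:
        raise ParameterError("permeability and viscosity must be positive")
    return k_m2 / mu_pa_s * _M2_PAS_TO_MM2_PADAY


def bulk_modulus_from_young(e_pa: float, nu: float) -> float:
    """Bulk modulus K = E / (3(1 − 2ν)) for an isotropic linear-elastic solid."""
    if e_pa <= 0:
        raise ParameterError(f"Young's modulus must be positive, got {e_pa}")
    if not 0 <= nu < 0.5:
        raise ParameterError(f"Poisson ratio must lie in [0, 0.5), got {nu}")
    return e_pa / (3.0 * (1.0 - 2.0 * nu))


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------

_OXYGEN_BCS = ("RBC", "PSBC")
_SWITCH_MODES = ("stiff", "overlap")
_PERMEABILITY_MODES = ("constant", "strain")

_HOUR = 1.0 / 24.0


@dataclass
class SimulationParams:
    """All physical constants, thresholds and scenario switches.

    Defaults are the study conditions of the baseline glioma-spheroid setup:
    U87-like cells (V_cell = 1200 μm^3) in a collagen hydrogel, initial
    spheroid radius 250 μm at one fifth of the equilibrium concentration,
    uniform 4 mg/L oxygen.
    """

    # -- cell packing geometry (cells/mm^3 unless noted)
    V_cell: float = 1200.0          # μm^3, single-cell volume
    C_max: float = field(default=None)  # type: ignore[assignment]
    C_eq: float = 3.5e5
    C_inf: float = 2.8e4            # adhesion cut-off
    C_att: float = 2.35e5           # maximum-attraction concentration
    sigma_att: float = 10.0         # Pa, maximal contractile stress
    # -- rheology
    K_C0: float = 500.0             # Pa, cell-aggregate bulk modulus at C_eq
    E_ECM: float = 1000.0           # Pa, ECM Young's modulus (0.5–2.5 kPa range)
    nu_ECM: float = 0.13
    K_ECM: float = field(default=None)  # type: ignore[assignment]
    k0: float = 1.0e-12             # m^2, unstressed ECM permeability
    mu_cell: float = 300.0          # Pa·s, cell dynamic viscosity
    M0: float = field(default=None)  # type: ignore[assignment]  # mm^2/(Pa·day)
    # -- motility / diffusion (mm^2/day)
    D_m: float = 2.0e-2
    D_p: float = field(default=None)  # type: ignore[assignment]
    D_ox: float = 86.4
    # -- oxygen metabolism
    alpha_p: float = 1.38e-2        # (mm^3/cell)·mg/(L·day)
    alpha_m: float = field(default=None)  # type: ignore[assignment]
    xi_h: float = 1.0               # mg/L, hypoxia threshold
    xi_n: float = 0.8               # mg/L, necrosis threshold
    lambda_switch: float = 1.0      # mg/L, tanh smoothing width
    # -- proliferation and phenotype transitions (day)
    tau_p: float = 1.0
    tau_m: float = 2.0
    tau_pm: float = 1.0 * _HOUR
    tau_mp: float = 96.0 * _HOUR
    tau_n: float = 32.0 * _HOUR
    h_m_flag: float = field(default=None)  # type: ignore[assignment]
    C_q: float = field(default=None)  # type: ignore[assignment]
    # -- initial / domain conditions
    n0: float = 4.0                 # mg/L
    n_max: float = field(default=None)  # type: ignore[assignment]
    R0: float = 0.25                # mm, initial spheroid radius
    C_init: float = 7.0e4
    R_dom: float = 1.5              # mm, domain radius
    # -- scenario switches
    oxygen_bc: str = "RBC"
    switch_mode: str = "overlap"
    permeability_mode: str = "constant"
    # volumetric source of the elasticity problem: "exact" differences the
    # sigma_C profile directly; "gamma_outside" uses the chain-rule
    # approximation gamma * K_C0/K_ECM * d(C_tot/C_eq)/dr with gamma frozen
    # outside the derivative (sensitivity studies only)
    delta_v_form: str = "exact"

    def __post_init__(self) -> None:
        # derived defaults, computed only where the config did not pin them
        if self.C_max is None:
            self.C_max = max_packing_concentration(self.V_cell)
        if self.K_ECM is None:
            self.K_ECM = bulk_modulus_from_young(self.E_ECM, self.nu_ECM)
        if self.M0 is None:
            self.M0 = mobility_from_permeability(self.k0, self.mu_cell)
        if self.alpha_m is None:
            self.alpha_m = self.alpha_p / 5.0
        if self.C_q is None:
            self.C_q = self.C_max
        if self.n_max is None:
            self.n_max = self.n0
        if self.D_p is None:
            self.D_p = 0.0 if self.switch_mode == "stiff" else self.D_m / 10.0
        if self.h_m_flag is None:
            self.h_m_flag = 0.0 if self.switch_mode == "stiff" else 1.0
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise ParameterError naming the first violated one."""
        if self.oxygen_bc not in _OXYGEN_BCS:
            raise ParameterError(f"oxygen_bc must be one of {_OXYGEN_BCS}, got {self.oxygen_bc!r}")
        if self.switch_mode not in _SWITCH_MODES:
            raise ParameterError(f"switch_mode must be one of {_SWITCH_MODES}, got {self.switch_mode!r}")
        if self.permeability_mode not in _PERMEABILITY_MODES:
            raise ParameterError(
                f"permeability_mode must be one of {_PERMEABILITY_MODES}, got {self.permeability_mode!r}")
        if self.delta_v_form not in ("exact", "gamma_outside"):
            raise ParameterError(
                f"delta_v_form must be 'exact' or 'gamma_outside', got {self.delta_v_form!r}")
        if not (0.0 < self.C_inf < self.C_att < self.C_eq < self.C_q <= self.C_max):
            raise ParameterError(
                "concentration ordering violated: require 0 < C_inf < C_att < C_eq < C_q <= C_max, got "
                f"C_inf={self.C_inf}, C_att={self.C_att}, C_eq={self.C_eq}, C_q={self.C_q}, C_max={self.C_max}")
        if not (0.0 < self.nu_ECM < 0.5):
            raise ParameterError(f"nu_ECM must lie in (0, 0.5), got {self.nu_ECM}")
        if self.E_ECM <= 0 or self.K_ECM <= 0 or self.K_C0 <= 0:
            raise ParameterError("elastic moduli E_ECM, K_ECM, K_C0 must be positive")
        for name in ("tau_p", "tau_m", "tau_pm", "tau_mp", "tau_n"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"characteristic time {name} must be positive")
        for name in ("D_p", "D_m", "D_ox"):
            if getattr(self, name) < 0:
                raise ParameterError(f"diffusivity {name} must be non-negative")
        if not (0.0 <= self.xi_n < self.xi_h < self.n0):
            raise ParameterError(
                f"oxygen thresholds must satisfy 0 <= xi_n < xi_h < n0, got "
                f"xi_n={self.xi_n}, xi_h={self.xi_h}, n0={self.n0}")
        if not (0.0 < self.R0 < self.R_dom):
            raise ParameterError(f"require 0 < R0 < R_dom, got R0={self.R0}, R_dom={self.R_dom}")
        if self.sigma_att < 0 or self.M0 < 0:
            raise ParameterError("sigma_att and M0 must be non-negative")
        if self.lambda_switch <= 0:
            raise ParameterError("lambda_switch must be positive")
        if self.alpha_p < 0 or self.alpha_m < 0:
            raise ParameterError("oxygen uptake rates must be non-negative")
        if self.C_init <= 0 or self.n0 <= 0 or self.n_max <= 0:
            raise ParameterError("C_init, n0 and n_max must be positive")
        if self.switch_mode == "stiff" and (self.D_p != 0.0 or self.h_m_flag != 0.0):
            raise ParameterError("stiff switch mode requires D_p = 0 and h_m_flag = 0")
        if self.switch_mode == "overlap" and self.h_m_flag != 1.0:
            raise ParameterError("overlap switch mode requires h_m_flag = 1")

    # -- (de)serialisation ---------------------------------------------------

    def replace(self, **overrides: Any) -> "SimulationParams":
        """Return a validated copy with ``overrides`` applied.

        Fields derived from overridden inputs (e.g. K_ECM from E_ECM, D_p and
        h_m_flag from switch_mode) are re-derived unless pinned explicitly.
        """
        current = dataclasses.asdict(self)
        unknown = set(overrides) - set(current)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        current.update(overrides)
        # re-derive dependent defaults unless the caller pinned them
        if "E_ECM" in overrides and "K_ECM" not in overrides:
            current["K_ECM"] = None
        if ("k0" in overrides or "mu_cell" in overrides) and "M0" not in overrides:
            current["M0"] = None
        if "V_cell" in overrides and "C_max" not in overrides:
            current["C_max"] = None
            if "C_q" not in overrides:
                current["C_q"] = None
        if "switch_mode" in overrides:
            current.setdefault("switch_mode", self.switch_mode)
            if "D_p" not in overrides:
                current["D_p"] = None
            if "h_m_flag" not in overrides:
                current["h_m_flag"] = None
        if "alpha_p" in overrides and "alpha_m" not in overrides:
            current["alpha_m"] = None
        if "n0" in overrides and "n_max" not in overrides:
            current["n_max"] = None
        return SimulationParams(**current)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set, recorded in run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> SimulationParams:
    """Load a flat key/value YAML configuration.

    Keys must match :class:`SimulationParams` field names exactly; a
    ``scenario:`` section of the same keys may override the top level.
    Unknown keys raise :class:`ParameterError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError("config must be a mapping of parameter names to values")
    scenario = raw.pop("scenario", {})
    if not isinstance(scenario, dict):
        raise ParameterError("scenario section must be a mapping")
    merged = {**raw, **scenario}
    fields = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(merged) - fields
    if unknown:
        raise ParameterError(f"unknown configuration key(s): {sorted(unknown)}")
    # YAML leaves exponent-style numbers without a decimal point as strings
    for key, value in merged.items():
        if isinstance(value, str) and key not in ("oxygen_bc", "switch_mode",
                                                  "permeability_mode",
                                                  "delta_v_form"):
            try:
                merged[key] = float(value)
            except ValueError as exc:
                raise ParameterError(f"non-numeric value for {key!r}: {value!r}") from exc
    return SimulationParams(**merged)
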