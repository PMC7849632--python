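"""Radial mesh and numerical kernels for the spherically symmetric model.

Three standalone kernels operate on profiles defined on a uniform radial
mesh with node 0 at the sphere centre:

* :func:`diffuse_cn` — Crank–Nicolson step for the spherical diffusion
  operator (1/r^2) d/dr (D r^2 df/dr), conservative finite-volume form;
* :func:`advect_fct` — flux-corrected transport (SHASTA-family) step for
  the conservative advection (1/r^2) d/dr (r^2 v f): a diffusive low-order
  donor-cell transport followed by limited antidiffusion in the spirit of
  Boris–Book/Zalesak, guaranteeing positivity and no new extrema;
* :func:`solve_displacement` — second-order symmetric discretisation of the
  radial elasticity boundary-value problem
  d/dr[(1/r^2) d(r^2 u)/dr] = ((1+nu)/(1-nu)) * delta_v
  with u(0) = 0 (regularity) and u(R_dom) = 0.

All kernels are pure functions: they return new arrays and never mutate
their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "RadialGrid",
    "NumericsError",
    "CFLError",
    "diffuse_cn",
    "advect_fct",
    "solve_displacement",
    "radial_gradient",
]


class NumericsError(RuntimeError):
    """A numerical kernel failed (degenerate system, non-finite result)."""


class CFLError(NumericsError):
    """Advective CFL condition violated; the caller must sub-cycle."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform node-centred radial mesh on [0, R_dom].

    Node i sits at r_i = i*dr; the control volume of node i is the spherical
    shell between the mid-faces (clipped to the domain at both ends), so the
    conservative weights ``w`` sum exactly to the domain volume (4/3)πR³.
    """

    R_dom: float
    n_intervals: int
    dr: float = field(init=False)
    r: np.ndarray = field(init=False, repr=False)
    r_face: np.ndarray = field(init=False, repr=False)
    w: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.R_dom <= 0 or self.n_intervals < 4:
            raise NumericsError("need R_dom > 0 and at least 4 radial intervals")
        dr = self.R_dom / self.n_intervals
        r = np.linspace(0.0, self.R_dom, self.n_intervals + 1)
        # faces: centre, mid-points, outer wall
        r_face = np.concatenate(([0.0], 0.5 * (r[:-1] + r[1:]), [self.R_dom]))
        w = 4.0 * np.pi / 3.0 * np.diff(r_face**3)
        object.__setattr__(self, "dr", dr)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "r_face", r_face)
        object.__setattr__(self, "w", w)

    @classmethod
    def from_spacing(cls, R_dom: float, dr: float) -> "RadialGrid":
        n = int(round(R_dom / dr))
        if abs(n * dr - R_dom) > 1e-9 * R_dom:
            raise NumericsError(f"dr={dr} does not evenly divide R_dom={R_dom}")
        return cls(R_dom, n)

    @property
    def n_nodes(self) -> int:
        return self.n_intervals + 1

    def integrate(self, f: np.ndarray) -> float:
        """Conservative spherical integral  ∫ f dV  ≈  Σ w_i f_i."""
        return float(np.dot(self.w, f))

    def _key(self) -> tuple:
        return (self.R_dom, self.n_intervals)


def radial_gradient(f: np.ndarray, grid: RadialGrid) -> np.ndarray:
    """df/dr by centred differences, second-order one-sided at the boundaries."""
    return np.gradient(f, grid.dr, edge_order=2)


# ---------------------------------------------------------------------------
# Crank–Nicolson spherical diffusion
# ---------------------------------------------------------------------------

# cache of assembled operators keyed by (grid key, D, dt, bc kind)
_CN_CACHE: dict[tuple, tuple] = {}


def _cn_operator(grid: RadialGrid, D: float, dt: float, bc_kind: str) -> tuple:
    key = (grid._key(), D, dt, bc_kind)
    hit = _CN_CACHE.get(key)
    if hit is not None:
        return hit
    n = grid.n_nodes
    dr = grid.dr
    a = grid.r_face**2          # face "areas" (4π dropped consistently)
    vol = grid.w / (4.0 * np.pi)
    # spatial operator L: (L f)_i = [a_{i+1}(f_{i+1}-f_i) - a_i(f_i - f_{i-1})] * D/(vol_i dr)
    lo = np.zeros(n)   # coefficient of f_{i-1}
    di = np.zeros(n)
    up = np.zeros(n)   # coefficient of f_{i+1}
    inner = a[:-1] * D / (vol * dr)    # face below node i (zero at i=0)
    outer = a[1:] * D / (vol * dr)     # face above node i
    outer[-1] = 0.0                    # no flux through the outer wall by default
    lo[1:] = inner[1:]
    up[:-1] = outer[:-1]
    di = -(inner + outer)
    di[0] = -outer[0]
    # banded LHS of (I - dt/2 L), scipy ordering (upper, diag, lower)
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * dt * up[:-1]
    ab[1, :] = 1.0 - 0.5 * dt * di
    ab[2, :-1] = -0.5 * dt * lo[1:]
    if bc_kind == "dirichlet":
        # pin the boundary node (identity row); interior rows keep their
        # coupling to the pinned value
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
    out = (ab, lo, di, up)
    _CN_CACHE[key] = out
    return out


def diffuse_cn(field: np.ndarray, D: float, dt: float, grid: RadialGrid,
               bc: str | tuple[str, float] = "no_flux") -> np.ndarray:
    """One Crank–Nicolson step of spherical diffusion.

    Parameters
    ----------
    bc : "no_flux" or ("dirichlet", value)
        Outer boundary condition; the centre always carries the symmetry
        condition df/dr = 0.

    Under "no_flux" the weighted total Σ w_i f_i is conserved to round-off.
    """
    if dt <= 0:
        raise NumericsError(f"dt must be positive, got {dt}")
    if D < 0:
        raise NumericsError(f"diffusivity must be non-negative, got {D}")
    f = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(f)):
        raise NumericsError("input profile contains non-finite values")
    if D == 0.0:
        return f.copy()
    if isinstance(bc, tuple):
        bc_kind, bc_value = bc
    else:
        bc_kind, bc_value = bc, None
    if bc_kind not in ("no_flux", "dirichlet"):
        raise NumericsError(f"unknown boundary condition {bc!r}")
    ab, lo, di, up = _cn_operator(grid, D, dt, bc_kind)
    # rhs = f + dt/2 * L f
    Lf = di * f
    Lf[1:] += lo[1:] * f[:-1]
    Lf[:-1] += up[:-1] * f[1:]
    rhs = f + 0.5 * dt * Lf
    if bc_kind == "dirichlet":
        rhs[-1] = bc_value
    try:
        out = solve_banded((1, 1), ab, rhs, check_finite=False)
    except Exception as exc:  # pragma: no cover - degenerate coefficients
        raise NumericsError(f"tridiagonal solve failed: {exc}") from exc
    if not np.all(np.isfinite(out)):
        raise NumericsError("diffusion step produced non-finite values")
    return out


# ---------------------------------------------------------------------------
# flux-corrected transport
# ---------------------------------------------------------------------------

def courant_number(v: np.ndarray, dt: float, grid: RadialGrid) -> float:
    """Generalised advective Courant number on the spherical mesh.

    max_i dt (sum of outgoing face fluxes A_f v_f) / V_i — reduces to the
    planar |v| dt/dr in uniform flow but is stricter near the origin, where
    cell volumes shrink faster than face areas.  Donor-cell positivity needs
    this number below 1; the FCT kernel enforces 0.5 for its extrema bounds.
    """
    u = np.asarray(v, dtype=float)
    vf = 0.5 * (u[:-1] + u[1:])
    a = grid.r_face**2
    vol = grid.w / (4.0 * np.pi)
    load = np.zeros(grid.n_nodes)
    load[:-1] += a[1:-1] * np.maximum(vf, 0.0)   # outflow through outer face
    load[1:] += a[1:-1] * np.maximum(-vf, 0.0)   # outflow through inner face
    return float(dt * np.max(load / vol))


def advect_fct(field: np.ndarray, v: np.ndarray, dt: float, grid: RadialGrid) -> np.ndarray:
    """One conservative FCT step of (1/r^2) d(r^2 v f)/dr.

    ``v`` is the node-centred drift velocity (mm/day); face velocities are
    its arithmetic mean, the r = 0 face flux is identically zero and the
    outer wall is closed.  The update is the donor-cell (low-order) transport
    plus Zalesak-limited antidiffusive fluxes: non-negative input stays
    non-negative and no new local extrema are created beyond the low-order
    transported bounds.

    Raises
    ------
    CFLError
        If max|v| dt / dr > 0.5; the caller should sub-cycle.
    """
    f = np.asarray(field, dtype=float)
    u = np.asarray(v, dtype=float)
    if dt <= 0:
        raise NumericsError(f"dt must be positive, got {dt}")
    if f.shape != u.shape or f.shape != grid.r.shape:
        raise NumericsError("field/velocity shape mismatch with the grid")
    n = grid.n_nodes
    dr = grid.dr
    cfl = courant_number(u, dt, grid)
    if cfl > 0.5 + 1e-12:
        raise CFLError(f"Courant number {cfl:.3f} exceeds 0.5; sub-cycle the advection")
    vol = grid.w / (4.0 * np.pi)
    a = grid.r_face**2
    # interior faces 1..n-1 between nodes (i-1, i); boundary fluxes are zero
    vf = 0.5 * (u[:-1] + u[1:])
    a_int = a[1:-1]
    # low-order donor-cell flux
    upwind = np.where(vf >= 0.0, f[:-1], f[1:])
    F_lo = a_int * vf * upwind
    # transported low-order solution: f_i <- f_i - dt (F_outer - F_inner)/vol_i
    div_lo = np.zeros(n)
    div_lo[:-1] += F_lo
    div_lo[1:] -= F_lo
    f_td = f - dt * div_lo / vol
    # high-order flux: Lax–Wendroff (second order in space and time on
    # smooth profiles); its excess over the donor flux is the antidiffusion
    c_face = vf * dt / dr
    F_hi = a_int * vf * (0.5 * (f[:-1] + f[1:]) - 0.5 * c_face * (f[1:] - f[:-1]))
    A = F_hi - F_lo
    # Boris–Book prelimiting: discard antidiffusion that would steepen
    # an opposing low-order gradient
    slope = f_td[1:] - f_td[:-1]
    A = np.where(A * slope < 0.0, 0.0, A)
    # Zalesak limiter bounds from old and transported values of node + neighbours
    hi = np.maximum(f, f_td)
    lo_ = np.minimum(f, f_td)
    f_max = hi.copy()
    f_max[:-1] = np.maximum(f_max[:-1], hi[1:])
    f_max[1:] = np.maximum(f_max[1:], hi[:-1])
    f_min = lo_.copy()
    f_min[:-1] = np.minimum(f_min[:-1], lo_[1:])
    f_min[1:] = np.minimum(f_min[1:], lo_[:-1])
    # antidiffusive in/out fluxes per node (A_j on face j enters node j, leaves node j-1
    # when positive in the +r direction; sign bookkeeping below)
    Ap = np.maximum(A, 0.0)
    Am = np.minimum(A, 0.0)
    P_in = np.zeros(n)
    P_in[1:] += Ap          # inner face positive flux enters node
    P_in[:-1] += -Am        # outer face negative flux enters node
    P_out = np.zeros(n)
    P_out[:-1] += Ap        # outer face positive flux leaves node
    P_out[1:] += -Am        # inner face negative flux leaves node
    # the tiny additive guard avoids 0/0 when fluxes underflow to denormals
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        Rp = np.where(P_in > 0.0,
                      np.minimum(1.0, (f_max - f_td) * vol / (dt * P_in + tiny)), 1.0)
        Rm = np.where(P_out > 0.0,
                      np.minimum(1.0, (f_td - f_min) * vol / (dt * P_out + tiny)), 1.0)
    Rp = np.clip(Rp, 0.0, 1.0)
    Rm = np.clip(Rm, 0.0, 1.0)
    # face limiter: a positive A on face j moves mass from node j-1 into node j
    C = np.where(A >= 0.0, np.minimum(Rp[1:], Rm[:-1]), np.minimum(Rp[:-1], Rm[1:]))
    F_corr = C * A
    div_c = np.zeros(n)
    div_c[:-1] += F_corr
    div_c[1:] -= F_corr
    out = f_td - dt * div_c / vol
    if not np.all(np.isfinite(out)):
        raise NumericsError("advection step produced non-finite values")
    # the limiter guarantees non-negativity up to round-off; scrub dust
    if out.min() < 0.0:
        floor = -1e-12 * max(float(np.max(np.abs(f))), 1.0)
        if out.min() < floor:
            raise NumericsError("flux limiter failed: negative concentrations")
        np.clip(out, 0.0, None, out=out)
    return out


# ---------------------------------------------------------------------------
# radial elasticity boundary-value problem
# ---------------------------------------------------------------------------

def solve_displacement(delta_v: np.ndarray, nu: float, grid: RadialGrid) -> np.ndarray:
    """Solve d/dr[(1/r^2) d(r^2 u)/dr] = ((1+nu)/(1-nu)) delta_v for u(r).

    Boundary conditions: u(0) = 0 (regularity at the centre) and
    u(R_dom) = 0 at the outer wall.  Interior nodes use the second-order
    symmetric stencil of the expanded operator u'' + 2u'/r - 2u/r^2.
    """
    if not (0 <= nu < 0.5):
        raise NumericsError(f"Poisson ratio must lie in [0, 0.5), got {nu}")
    g = np.asarray(delta_v, dtype=float) * (1.0 + nu) / (1.0 - nu)
    if not np.all(np.isfinite(g)):
        raise NumericsError("source profile contains non-finite values")
    n = grid.n_nodes
    dr = grid.dr
    r = grid.r
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    ri = r[1:-1]
    ab[0, 2:] = 1.0 / dr**2 + 1.0 / (ri * dr)          # u_{i+1}
    ab[1, 1:-1] = -2.0 / dr**2 - 2.0 / ri**2           # u_i
    ab[2, :-2] = 1.0 / dr**2 - 1.0 / (ri * dr)         # u_{i-1}
    rhs[1:-1] = g[1:-1]
    ab[1, 0] = 1.0
    ab[1, -1] = 1.0
    ab[0, 1] = 0.0
    ab[2, -2] = 0.0
    try:
        u = solve_banded((1, 1), ab, rhs, check_finite=False)
    except Exception as exc:
        raise NumericsError(f"elasticity solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise NumericsError("elasticity solve produced non-finite values")
    return u
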