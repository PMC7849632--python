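"""Post-processing of trajectories into invasion observables.

The invasive zone (IZ) has no sharp physical boundary; following common
spheroid practice it is tracked by outer isolines of the total cell
density (thresholds such as 4e2 and 4e3 cells/mm^3).  Proliferative rims
are local maxima of C_p; the "main rim" band used for the hypoxic-fraction
observable is frozen at an early time and re-used later, mirroring how such
rims are followed visually on radial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .engine import Snapshot
from .numerics import RadialGrid

__all__ = [
    "NOT_ATTAINED",
    "IsolineTrack",
    "isoline_radius",
    "track_isoline",
    "invasion_speed",
    "central_fold_change",
    "detect_rims",
    "main_rim_band",
    "rim_hypoxic_fraction",
    "DEFAULT_THRESHOLDS",
]

#: sentinel for "profile never attains the threshold"
NOT_ATTAINED = float("nan")

#: isoline thresholds used on the concentration maps (cells/mm^3)
DEFAULT_THRESHOLDS = (4.0e2, 4.0e3, 4.0e4, 8.0e4, 1.6e5)


@dataclass
class IsolineTrack:
    """Outer radius of one total-density isoline as a function of time."""

    threshold: float
    t: np.ndarray          # day
    r_outer: np.ndarray    # mm; NaN where the threshold is not attained

    def at(self, t: float) -> float:
        idx = np.argmin(np.abs(self.t - t))
        if abs(self.t[idx] - t) > 1e-9:
            raise ValueError(f"no track point at t={t}; nearest is {self.t[idx]}")
        return float(self.r_outer[idx])


def isoline_radius(profile: np.ndarray, threshold: float, grid: RadialGrid) -> float:
    """Outermost radius where the profile crosses ``threshold`` from above.

    Linear interpolation between nodes; returns :data:`NOT_ATTAINED` (NaN)
    when the profile never reaches the threshold, and R_dom when even the
    boundary node is above it.
    """
    c = np.asarray(profile, dtype=float)
    above = c >= threshold
    if not above.any():
        return NOT_ATTAINED
    i = int(np.max(np.nonzero(above)))
    if i == len(c) - 1:
        return float(grid.R_dom)
    # crossing between node i (above) and i+1 (below)
    frac = (c[i] - threshold) / (c[i] - c[i + 1])
    return float(grid.r[i] + frac * grid.dr)


def track_isoline(snapshots: list[Snapshot], threshold: float,
                  grid: RadialGrid) -> IsolineTrack:
    t = np.array([s.t for s in snapshots])
    r = np.array([isoline_radius(s.cells.C_tot, threshold, grid) for s in snapshots])
    return IsolineTrack(threshold=threshold, t=t, r_outer=r)


def invasion_speed(track: IsolineTrack, t0: float, t1: float) -> float:
    """Mean outward speed of the isoline between t0 and t1 (mm/day)."""
    if t1 <= t0:
        raise ValueError(f"need t1 > t0, got t0={t0}, t1={t1}")
    return (track.at(t1) - track.at(t0)) / (t1 - t0)


def central_fold_change(snapshots: list[Snapshot], t: float, C_init: float) -> float:
    """C_tot at the centre node at time t relative to the seeding density."""
    for s in snapshots:
        if abs(s.t - t) < 1e-9:
            return float(s.cells.C_tot[0]) / C_init
    raise ValueError(f"no snapshot at t={t}")


def detect_rims(C_p: np.ndarray, grid: RadialGrid,
                min_prominence: float = 1.0e3) -> list[tuple[float, float]]:
    """Local maxima of the proliferative profile at r > 0.

    Returns (radius, peak concentration) pairs sorted by radius; prominence
    below ``min_prominence`` (cells/mm^3) is treated as noise.
    """
    c = np.asarray(C_p, dtype=float)
    peaks, props = find_peaks(c, prominence=min_prominence)
    peaks = peaks[peaks > 0]
    return [(float(grid.r[i]), float(c[i])) for i in peaks]


def main_rim_band(C_p: np.ndarray, grid: RadialGrid,
                  min_prominence: float = 1.0e3) -> tuple[float, float]:
    """Radial band of the main proliferative rim.

    The main rim is the local C_p maximum with the highest peak
    concentration among all rims strictly inside the outermost one (when at
    least two rims exist; with a single rim it is that rim).  The band spans
    the surrounding local minima (or the points where C_p falls below half
    the peak, whichever is narrower).
    """
    c = np.asarray(C_p, dtype=float)
    rims = detect_rims(c, grid, min_prominence)
    if not rims:
        raise ValueError("no proliferative rim found")
    if len(rims) == 1:
        r_peak = rims[0][0]
    else:
        inner = rims[:-1]
        r_peak = max(inner, key=lambda rc: rc[1])[0]
    i_peak = int(round(r_peak / grid.dr))
    half = 0.5 * c[i_peak]
    lo = i_peak
    while lo > 0 and c[lo - 1] <= c[lo] and c[lo - 1] > half:
        lo -= 1
    hi = i_peak
    n = len(c)
    while hi < n - 1 and c[hi + 1] <= c[hi] and c[hi + 1] > half:
        hi += 1
    return float(grid.r[lo]), float(grid.r[hi])


def rim_hypoxic_fraction(snap: Snapshot, band: tuple[float, float],
                         grid: RadialGrid, include_necrotic: bool = False) -> float:
    """Volume-weighted hypoxic fraction of the cells in a radial band.

    Default denominator excludes necrotic cells (the go-vs-grow split of the
    still-living rim population); ``include_necrotic=True`` reports the
    alternative convention.
    """
    r_lo, r_hi = band
    if not (0.0 <= r_lo < r_hi <= grid.R_dom):
        raise ValueError(f"band {band} outside the domain [0, {grid.R_dom}]")
    mask = (grid.r >= r_lo - 1e-12) & (grid.r <= r_hi + 1e-12)
    w = grid.w[mask]
    C_m = snap.cells.C_m[mask]
    denom = snap.cells.C_p[mask] + C_m
    if include_necrotic:
        denom = denom + snap.cells.C_n[mask]
    total = float(np.dot(w, denom))
    if total <= 0.0:
        return NOT_ATTAINED
    return float(np.dot(w, C_m)) / total
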