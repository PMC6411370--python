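"""Per-cell pressure, coarse-grained fields, edge-referenced azimuthal
profiles, and the headline colony observables.

Conventions
-----------
* Layers are center-height slabs of thickness w0: layer k holds cells whose
  center z lies in [(k-1) w0, k w0).
* The colony edge is azimuth-local: in each of ``n_sectors`` angular sectors
  the edge radius is the outermost bottom-layer cell center plus w0/2; the
  signed edge distance of a cell is ``dr = r_cell - R_edge(sector)``
  (negative = into the colony).
* Pressures are the virial per cell volume, ``P_i = V_i^{-1} sum_j F_ji .
  r_ji``, in units of P0 = gamma_surf / w0.
* A cell is "vertical" when its director makes an angle of at most 45
  degrees with the z axis (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import Cell, spherocylinder_volume
from .engine import Snapshot, Trajectory
from .nutrient_solver import NutrientField

__all__ = [
    "CoarseFields", "Observables",
    "cell_pressure", "coarse_grain", "azimuthal_profiles",
    "colony_observables", "growth_zone_and_verticalization",
    "layer_index", "bottom_layer_mask",
]

VERTICAL_COS = math.cos(math.radians(45.0))


# ---------------------------------------------------------------------------
# Pressure
# ---------------------------------------------------------------------------


def cell_pressure(cell: Cell, ledger: Sequence[Tuple[np.ndarray, np.ndarray]],
                  w0: float = 1.0) -> float:
    """Virial pressure ``P_i = V_i^{-1} sum_j F_ji . r_ji`` where ``r_ji``
    points from the application point to the cell center."""
    V = spherocylinder_volume(cell.l, w0)
    s = 0.0
    for F, offset in ledger:
        s += float(np.dot(F, offset))
    return s / V


# ---------------------------------------------------------------------------
# Layer helpers
# ---------------------------------------------------------------------------


def layer_index(z: np.ndarray, w0: float) -> np.ndarray:
    """Layer number (1-based) from center height; layer k = [(k-1)w0, k w0)."""
    return np.floor(np.asarray(z) / w0).astype(int) + 1


def bottom_layer_mask(snapshot: Snapshot) -> np.ndarray:
    return layer_index(snapshot.r[:, 2], snapshot.w0) == 1


# ---------------------------------------------------------------------------
# Coarse graining
# ---------------------------------------------------------------------------


@dataclass
class CoarseFields:
    """Mass density, velocity, nematic director, and pressure on a coarse
    grid (default 4 um boxes).  Empty boxes are masked, never zero-filled."""

    edges: Tuple[np.ndarray, np.ndarray, np.ndarray]
    density: np.ndarray
    velocity: np.ndarray          # (..., 3), mass-weighted mean
    director: np.ndarray          # (..., 3), principal nematic axis
    order: np.ndarray             # scalar nematic order parameter
    pressure: np.ndarray          # volume-weighted mean of P_i
    mask: np.ndarray              # True where at least one cell

    @property
    def centers(self):
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


def coarse_grain(snapshot: Snapshot, box: float = 4.0,
                 rho_cell: float = 0.137e-12) -> CoarseFields:
    """Bin cells (by center) into cubic boxes and average.

    Density is total dry mass per box volume; the director is the principal
    eigenvector of the nematic order tensor Q = <n (x) n - I/3> (headless:
    invariant under n -> -n), with order parameter S = (3/2) lambda_max.
    """
    if snapshot.n_cells == 0:
        raise ValueError("coarse_grain requires at least one cell")
    r = snapshot.r
    w0 = snapshot.w0
    vol = spherocylinder_volume(snapshot.l, w0)
    mass = vol * rho_cell
    lo = np.floor(r.min(axis=0) / box) * box
    hi = np.ceil((r.max(axis=0) + 1e-9) / box) * box
    edges = tuple(np.arange(lo[d], hi[d] + box / 2, box) for d in range(3))
    shape = tuple(len(e) - 1 for e in edges)
    idx = tuple(
        np.clip(np.floor((r[:, d] - lo[d]) / box).astype(int),
                0, shape[d] - 1)
        for d in range(3))

    msum = np.zeros(shape)
    np.add.at(msum, idx, mass)
    mask = msum > 0

    vel = np.zeros(shape + (3,))
    for d in range(3):
        acc = np.zeros(shape)
        np.add.at(acc, idx, mass * snapshot.v[:, d])
        vel[..., d] = np.divide(acc, msum, out=np.full(shape, np.nan),
                                where=mask)

    # nematic tensor, mass weighted
    Q = np.zeros(shape + (3, 3))
    for a in range(3):
        for b in range(3):
            acc = np.zeros(shape)
            comp = snapshot.n[:, a] * snapshot.n[:, b] - (a == b) / 3.0
            np.add.at(acc, idx, mass * comp)
            Q[..., a, b] = np.divide(acc, msum, out=np.zeros(shape),
                                     where=mask)
    director = np.full(shape + (3,), np.nan)
    order = np.full(shape, np.nan)
    flat_mask = np.argwhere(mask)
    for ijk in flat_mask:
        q = Q[tuple(ijk)]
        evals, evecs = np.linalg.eigh(q)
        director[tuple(ijk)] = evecs[:, -1]
        order[tuple(ijk)] = 1.5 * evals[-1]

    vsum = np.zeros(shape)
    np.add.at(vsum, idx, vol)
    pacc = np.zeros(shape)
    np.add.at(pacc, idx, vol * snapshot.pressure)
    press = np.divide(pacc, vsum, out=np.full(shape, np.nan), where=mask)

    density = np.zeros(shape)
    density[:] = msum / box ** 3

    return CoarseFields(edges=edges, density=density, velocity=vel,
                        director=director, order=order, pressure=press,
                        mask=mask)


# ---------------------------------------------------------------------------
# Azimuthal, edge-referenced profiles
# ---------------------------------------------------------------------------


def _sector_edges(snapshot: Snapshot, n_sectors: int,
                  center: np.ndarray) -> np.ndarray:
    """Edge radius per azimuthal sector from bottom-layer cell centers."""
    bl = bottom_layer_mask(snapshot)
    if not bl.any():
        bl = np.ones(snapshot.n_cells, dtype=bool)
    x = snapshot.r[bl, 0] - center[0]
    y = snapshot.r[bl, 1] - center[1]
    rad = np.hypot(x, y)
    ang = np.mod(np.arctan2(y, x), 2 * np.pi)
    sec = np.minimum((ang / (2 * np.pi) * n_sectors).astype(int),
                     n_sectors - 1)
    edges = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        m = sec == s
        if m.any():
            edges[s] = rad[m].max() + 0.5 * snapshot.w0
    # fill empty sectors from the neighbors (circular nearest fill)
    if np.isnan(edges).any() and not np.isnan(edges).all():
        good = np.where(~np.isnan(edges))[0]
        for s in np.where(np.isnan(edges))[0]:
            d = np.minimum(np.abs(good - s), n_sectors - np.abs(good - s))
            edges[s] = edges[good[np.argmin(d)]]
    return edges


def azimuthal_profiles(snapshot: Snapshot, bottom_layer_only: bool = True,
                       n_sectors: int = 36, dr_bin: float = 2.0,
                       center: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Azimuthally averaged radial velocity Vr, vertical velocity Vz, local
    height H, and pressure P versus the signed edge distance dr.

    ``dr = r_cell - R_edge(azimuth)``; negative dr is inside the colony.
    Returns a DataFrame with one row per dr bin.
    """
    if center is None:
        bl = bottom_layer_mask(snapshot)
        sel = bl if bl.any() else np.ones(snapshot.n_cells, bool)
        center = snapshot.r[sel][:, :2].mean(axis=0)
    center = np.asarray(center, float)
    edges = _sector_edges(snapshot, n_sectors, center)

    if bottom_layer_only:
        m = bottom_layer_mask(snapshot)
        if not m.any():
            m = np.ones(snapshot.n_cells, bool)
    else:
        m = np.ones(snapshot.n_cells, bool)
    x = snapshot.r[m, 0] - center[0]
    y = snapshot.r[m, 1] - center[1]
    rad = np.hypot(x, y)
    ang = np.mod(np.arctan2(y, x), 2 * np.pi)
    sec = np.minimum((ang / (2 * np.pi) * n_sectors).astype(int),
                     n_sectors - 1)
    dr = rad - edges[sec]
    with np.errstate(invalid="ignore", divide="ignore"):
        rhatx = np.where(rad > 1e-9, x / rad, 0.0)
        rhaty = np.where(rad > 1e-9, y / rad, 0.0)
    vr = snapshot.v[m, 0] * rhatx + snapshot.v[m, 1] * rhaty
    vz = snapshot.v[m, 2]
    top = (snapshot.r[m, 2] + 0.5 * snapshot.l[m] * np.abs(snapshot.n[m, 2])
           + 0.5 * snapshot.w0)
    press = snapshot.pressure[m]

    bins = np.floor(dr / dr_bin).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append({
            "dr": (b + 0.5) * dr_bin,
            "Vr": float(np.mean(vr[sel])),
            "Vz": float(np.mean(vz[sel])),
            "H": float(np.max(top[sel])),
            "P": float(np.mean(press[sel])),
            "n_cells": int(sel.sum()),
        })
    return pd.DataFrame(rows).sort_values("dr").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


@dataclass
class Observables:
    """Time series R(t), H(t), layer radii, and the derived scalars."""

    t: np.ndarray
    R: np.ndarray                 # mean bottom-layer edge radius (um)
    H: np.ndarray                 # height at the colony center (um)
    r1: np.ndarray
    r2: np.ndarray
    VR: float = float("nan")
    VH: float = float("nan")
    t_buckle: Optional[float] = None
    Wb: float = float("nan")
    HS: float = float("nan")
    fit_window: Tuple[float, float] = (float("nan"), float("nan"))

    def summary(self) -> dict:
        return {
            "VR_um_per_h": self.VR, "VH_um_per_h": self.VH,
            "t_buckle_h": self.t_buckle, "Wb_um": self.Wb, "HS_um": self.HS,
            "R_final_um": float(self.R[-1]) if len(self.R) else float("nan"),
            "H_final_um": float(self.H[-1]) if len(self.H) else float("nan"),
        }


def _auto_fit_window(t: np.ndarray, R: np.ndarray,
                     min_points: int = 3, r2_min: float = 0.995):
    """Longest suffix of R(t) on which a linear fit has R^2 > r2_min."""
    best = None
    n = len(t)
    for start in range(0, n - min_points + 1):
        tt = t[start:]
        rr = R[start:]
        if len(tt) < min_points:
            break
        coef = np.polyfit(tt, rr, 1)
        resid = rr - np.polyval(coef, tt)
        ss_tot = np.sum((rr - rr.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        if r2 > r2_min:
            best = (tt[0], tt[-1])
            break
    if best is None:
        best = (t[max(0, n - min_points)], t[-1])
    return best


def _layer_radius(snapshot: Snapshot, layer: int, n_sectors: int,
                  center: np.ndarray) -> float:
    m = layer_index(snapshot.r[:, 2], snapshot.w0) == layer
    if not m.any():
        return float("nan")
    x = snapshot.r[m, 0] - center[0]
    y = snapshot.r[m, 1] - center[1]
    rad = np.hypot(x, y)
    ang = np.mod(np.arctan2(y, x), 2 * np.pi)
    sec = np.minimum((ang / (2 * np.pi) * n_sectors).astype(int),
                     n_sectors - 1)
    vals = [rad[sec == s].max() + 0.5 * snapshot.w0
            for s in range(n_sectors) if (sec == s).any()]
    return float(np.mean(vals))


def colony_observables(trajectory: Trajectory,
                       fit_window: Optional[Tuple[float, float]] = None,
                       n_sectors: int = 36) -> Observables:
    """R(t), H(t), layer radii and the derived speeds/widths.

    R is the mean over azimuthal sectors of the bottom layer's outermost
    envelope; H is the smoothed height field at the colony centroid.  VR and
    VH are least-squares slopes over ``fit_window`` (auto-detected linear
    regime when not given); t_buckle is the first time H exceeds 1.5 w0; Wb
    is the mean of r1 - r2 over the fit window.
    """
    from .mechanics import HeightField, build_height_field_nb, smooth3x3_nb

    snaps = trajectory.snapshots
    if len(snaps) < 1:
        raise ValueError("empty trajectory")
    p = trajectory.params
    t = np.array([s.t for s in snaps])
    R = np.zeros(len(snaps))
    H = np.zeros(len(snaps))
    r1 = np.zeros(len(snaps))
    r2 = np.zeros(len(snaps))
    for k, s in enumerate(snaps):
        center = s.r[:, :2].mean(axis=0)
        r1[k] = _layer_radius(s, 1, n_sectors, center)
        r2[k] = _layer_radius(s, 2, n_sectors, center)
        R[k] = r1[k] if np.isfinite(r1[k]) else _layer_radius(
            s, int(np.median(layer_index(s.r[:, 2], s.w0))), n_sectors, center)
        ix0, iy0, h_raw = build_height_field_nb(
            s.r, s.n, s.l, s.n_cells, s.w0, p.hf_bin, 2)
        hf = HeightField(ix0, iy0, p.hf_bin, h_raw, smooth3x3_nb(h_raw),
                         p.delta_h)
        H[k] = hf.height_at(center[0], center[1])

    if fit_window is None:
        fit_window = _auto_fit_window(t, R)
    else:
        if fit_window[0] < t[0] - 1e-9 or fit_window[1] > t[-1] + 1e-9:
            raise ValueError(
                f"fit window {fit_window} outside trajectory "
                f"[{t[0]}, {t[-1]}]")
    sel = (t >= fit_window[0] - 1e-9) & (t <= fit_window[1] + 1e-9)
    if sel.sum() >= 2:
        VR = float(np.polyfit(t[sel], R[sel], 1)[0])
        VH = float(np.polyfit(t[sel], H[sel], 1)[0])
    else:
        VR = VH = float("nan")

    above = H > 1.5 * p.w0
    t_buckle = float(t[above][0]) if above.any() else None

    wb_vals = (r1 - r2)[sel & np.isfinite(r2)]
    Wb = float(np.mean(wb_vals)) if len(wb_vals) else float("nan")

    return Observables(t=t, R=R, H=H, r1=r1, r2=r2, VR=VR, VH=VH,
                       t_buckle=t_buckle, Wb=Wb,
                       fit_window=(float(fit_window[0]),
                                   float(fit_window[1])))


# ---------------------------------------------------------------------------
# Growth zone and verticalization
# ---------------------------------------------------------------------------


def growth_zone_and_verticalization(snapshot: Snapshot,
                                    field: NutrientField,
                                    r_bin: float = 5.0):
    """Growth-zone thickness HS and the vertical-cell fraction vs radius.

    HS is the smallest height on the colony axis where the solved nutrient
    concentration falls to the Monod constant K_S (linear interpolation
    between grid samples).  If the concentration stays above K_S everywhere,
    HS is the colony height and the result is flagged as not
    nutrient-limited.  Returns ``(HS, profile DataFrame, nutrient_limited)``.
    """
    p = field.params
    center = snapshot.r[:, :2].mean(axis=0)
    top = float((snapshot.r[:, 2]
                 + 0.5 * snapshot.l * np.abs(snapshot.n[:, 2])
                 + 0.5 * snapshot.w0).max())
    zs, Cs = field.on_axis_profile(center[0], center[1])
    m = zs <= max(top, zs[0] + 1e-9)
    zs, Cs = zs[m], Cs[m]
    Ks = p.K_S_mass
    HS = top
    limited = False
    below = np.where(Cs <= Ks)[0]
    if len(below):
        k = below[0]
        limited = True
        if k == 0:
            HS = float(zs[0])
        else:
            z0, z1 = zs[k - 1], zs[k]
            c0, c1 = Cs[k - 1], Cs[k]
            HS = float(z0 + (c0 - Ks) / (c0 - c1) * (z1 - z0))

    rad = np.hypot(snapshot.r[:, 0] - center[0],
                   snapshot.r[:, 1] - center[1])
    vertical = np.abs(snapshot.n[:, 2]) >= VERTICAL_COS - 1e-12
    bins = np.floor(rad / r_bin).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append({"radius": (b + 0.5) * r_bin,
                     "vertical_fraction": float(np.mean(vertical[sel])),
                     "n_cells": int(sel.sum())})
    return HS, pd.DataFrame(rows), limited


# ---------------------------------------------------------------------------
# Plotting helpers
# ---------------------------------------------------------------------------


def plot_growth_curves(obs: Observables, ax=None):
    """Radius and height vs time with their linear fits (Fig-3C-style)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(obs.t, obs.R, "o-", color="tab:red", label="R(t)")
    ax.plot(obs.t, obs.H, "s-", color="tab:blue", label="H(t)")
    lo, hi = obs.fit_window
    if np.isfinite(lo) and np.isfinite(obs.VR):
        tt = np.linspace(lo, hi, 10)
        R0 = np.interp(lo, obs.t, obs.R)
        H0 = np.interp(lo, obs.t, obs.H)
        ax.plot(tt, R0 + obs.VR * (tt - lo), "--", color="tab:red")
        ax.plot(tt, H0 + obs.VH * (tt - lo), "--", color="tab:blue")
    ax.set_xlabel("t (h)")
    ax.set_ylabel("length (um)")
    ax.legend()
    return ax


def plot_vertical_fraction(profile: pd.DataFrame, ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile["radius"], profile["vertical_fraction"], "o-")
    ax.set_xlabel("radius (um)")
    ax.set_ylabel("vertical fraction")
    ax.set_ylim(-0.05, 1.05)
    return ax


def plot_edge_profiles(profiles: pd.DataFrame, ax=None):
    """Vr, H and P against the signed edge distance (Fig-8-style)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profiles["dr"], profiles["Vr"], "o-", label="Vr (um/h)")
    ax.plot(profiles["dr"], profiles["H"], "s-", label="H (um)")
    ax.plot(profiles["dr"], profiles["P"], "^-", label="P (P0)")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("dr from edge (um)")
    ax.legend()
    return ax
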