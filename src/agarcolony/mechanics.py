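"""Forces and torques on cells.

Four force families act on a cell:

* cell-cell contact: Hertzian elastic repulsion ``F_elas = k_n delta^{3/2}``
  plus normal dissipation ``~ sqrt(delta) v_n``, and a tangential
  static-friction drag ``~ delta v_t`` capped by the dynamic-friction yield
  criterion ``mu_cc F_elas`` (velocity independent once sliding);
* cell-agar contact: the same force forms against a rough, static agar
  surface (roughness amplitude ``h_ran``), with cap ``mu_ca F_elas``;
* Stokes drag ``-eta v`` (and rotational drag ``-eta_rot omega``);
* cell-level surface tension: a restoring force ``pi gamma_surf w0`` on any
  cell protruding above the smoothed liquid film covering the colony, with a
  linear ramp over the first ``w0/10`` of protrusion.

The compiled per-contact helpers here are the single source of truth: the
engine's inner-loop kernel calls exactly these functions, and the Python
wrappers used in tests call them too.

Numerical-stability clamp: the viscous (velocity-proportional) parts of every
contact force are clamped to ``m_eff |v| / (2 dt)`` so that a dissipative
force can never reverse a relative velocity within a single timestep.  The
dynamic-friction caps are unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .model_core import (
    Cell,
    Contact,
    SimulationParams,
    seg_min_dist_nb,
    PV_W0, PV_KN, PV_GAMMA_N, PV_GAMMA_T, PV_MU_CC, PV_MU_CA, PV_HRAN,
    PV_GSURF, PV_DELTA_H, PV_ETA, PV_ETA_ROT, PV_MASS, PV_DT, PV_AGAR_NDISS,
)

__all__ = [
    "ForceAccumulator",
    "HeightField",
    "AgarSurface",
    "cell_cell_force",
    "cell_agar_force",
    "viscous_drag",
    "surface_tension_force",
    "colony_height_field",
    "surface_tension_magnitude",
]


# ---------------------------------------------------------------------------
# Compiled building blocks
# ---------------------------------------------------------------------------


@njit(cache=True)
def agar_height_nb(ix, iy, seed, hran):
    """Static agar roughness: per-bin uniform offset in [-h_ran, h_ran].

    A seeded integer hash of the absolute bin index, so the surface is
    reproducible, uncorrelated bin to bin, and independent of array layout.
    """
    z = (np.uint64(np.int64(ix)) * np.uint64(0x9E3779B97F4A7C15)
         + np.uint64(np.int64(iy)) * np.uint64(0xC2B2AE3D27D4EB4F)
         + np.uint64(np.int64(seed)) * np.uint64(0x165667B19E3779F9))
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    u = float(z) / 18446744073709551616.0
    return (2.0 * u - 1.0) * hran


@njit(cache=True)
def cell_cell_force_nb(rA, nA, lA, vA, oA, rB, nB, lB, vB, oB, pv):
    """Contact force on cell A from cell B.

    Returns ``(in_contact, F, rc, F_elas)`` where ``F`` is the force on A
    applied at the contact center ``rc``; the force on B is ``-F`` at the
    same point (Newton's third law by construction).
    """
    w0 = pv[PV_W0]
    F = np.zeros(3)
    rc = np.zeros(3)
    pAx = rA[0] + 0.5 * lA * nA[0]
    pAy = rA[1] + 0.5 * lA * nA[1]
    pAz = rA[2] + 0.5 * lA * nA[2]
    qAx = rA[0] - 0.5 * lA * nA[0]
    qAy = rA[1] - 0.5 * lA * nA[1]
    qAz = rA[2] - 0.5 * lA * nA[2]
    pBx = rB[0] + 0.5 * lB * nB[0]
    pBy = rB[1] + 0.5 * lB * nB[1]
    pBz = rB[2] + 0.5 * lB * nB[2]
    qBx = rB[0] - 0.5 * lB * nB[0]
    qBy = rB[1] - 0.5 * lB * nB[1]
    qBz = rB[2] - 0.5 * lB * nB[2]
    d, ax, ay, az, bx, by, bz = seg_min_dist_nb(
        np.array((pAx, pAy, pAz)), np.array((qAx, qAy, qAz)),
        np.array((pBx, pBy, pBz)), np.array((qBx, qBy, qBz)))
    if d >= w0:
        return False, F, rc, 0.0
    delta = w0 - d
    if d > 1e-12:
        nhx = (ax - bx) / d
        nhy = (ay - by) / d
        nhz = (az - bz) / d
    else:
        nhx, nhy, nhz = 0.0, 0.0, 1.0
    rc[0] = 0.5 * (ax + bx)
    rc[1] = 0.5 * (ay + by)
    rc[2] = 0.5 * (az + bz)
    # relative velocity of the contact point (A minus B)
    dxA = rc[0] - rA[0]
    dyA = rc[1] - rA[1]
    dzA = rc[2] - rA[2]
    dxB = rc[0] - rB[0]
    dyB = rc[1] - rB[1]
    dzB = rc[2] - rB[2]
    vrx = (vA[0] + oA[1] * dzA - oA[2] * dyA) - (vB[0] + oB[1] * dzB - oB[2] * dyB)
    vry = (vA[1] + oA[2] * dxA - oA[0] * dzA) - (vB[1] + oB[2] * dxB - oB[0] * dzB)
    vrz = (vA[2] + oA[0] * dyA - oA[1] * dxA) - (vB[2] + oB[0] * dyB - oB[1] * dxB)
    vn = vrx * nhx + vry * nhy + vrz * nhz
    F_elas = pv[PV_KN] * delta * math.sqrt(delta)
    # normal dissipation, stability-clamped
    m_red = 0.5 * pv[PV_MASS]
    cap_visc = 0.5 * m_red / pv[PV_DT]
    c_n = min(pv[PV_GAMMA_N] * math.sqrt(delta), cap_visc)
    Fn = F_elas - c_n * vn
    if Fn < 0.0:
        Fn = 0.0          # no adhesion: contacts cannot pull
    vtx = vrx - vn * nhx
    vty = vry - vn * nhy
    vtz = vrz - vn * nhz
    vt = math.sqrt(vtx * vtx + vty * vty + vtz * vtz)
    Ftx = 0.0
    Fty = 0.0
    Ftz = 0.0
    if vt > 1e-12:
        c_t = min(pv[PV_GAMMA_T] * delta, cap_visc)
        Ft = min(c_t * vt, pv[PV_MU_CC] * F_elas)
        Ftx = -Ft * vtx / vt
        Fty = -Ft * vty / vt
        Ftz = -Ft * vtz / vt
    F[0] = Fn * nhx + Ftx
    F[1] = Fn * nhy + Fty
    F[2] = Fn * nhz + Ftz
    return True, F, rc, F_elas


@njit(cache=True)
def agar_cap_force_nb(cap, rcell, v, o, h_local, pv):
    """Cell-agar contact force at one hemispherical cap.

    ``h_local`` is the local rough agar surface height; the overlap is
    ``delta_ca = w0/2 - (z_cap - h_local)``.  Returns ``(in_contact, F, rca,
    F_elas)`` with the force applied at ``rca`` below the cap center.
    """
    w0 = pv[PV_W0]
    F = np.zeros(3)
    rca = np.zeros(3)
    delta = 0.5 * w0 - (cap[2] - h_local)
    if delta <= 0.0:
        return False, F, rca, 0.0
    rca[0] = cap[0]
    rca[1] = cap[1]
    rca[2] = cap[2] - 0.5 * w0 + 0.5 * delta
    dx = rca[0] - rcell[0]
    dy = rca[1] - rcell[1]
    dz = rca[2] - rcell[2]
    vcx = v[0] + o[1] * dz - o[2] * dy
    vcy = v[1] + o[2] * dx - o[0] * dz
    vcz = v[2] + o[0] * dy - o[1] * dx
    F_elas = pv[PV_KN] * delta * math.sqrt(delta)
    Fn = F_elas
    cap_visc = 0.5 * pv[PV_MASS] / pv[PV_DT]
    if pv[PV_AGAR_NDISS] > 0.5:
        c_n = min(pv[PV_GAMMA_N] * math.sqrt(delta), cap_visc)
        Fn = F_elas - c_n * vcz
        if Fn < 0.0:
            Fn = 0.0
    vt = math.sqrt(vcx * vcx + vcy * vcy)
    Ftx = 0.0
    Fty = 0.0
    if vt > 1e-12:
        c_t = min(pv[PV_GAMMA_T] * delta, cap_visc)
        Ft = min(c_t * vt, pv[PV_MU_CA] * F_elas)
        Ftx = -Ft * vcx / vt
        Fty = -Ft * vcy / vt
    F[0] = Ftx
    F[1] = Fty
    F[2] = Fn
    return True, F, rca, F_elas


@njit(cache=True)
def surface_tension_magnitude_nb(dz, w0, gamma_surf):
    """Restoring-force magnitude vs protrusion height dz = h_cell - h_w.

    Zero for submerged cells, a linear ramp over 0 < dz < w0/10, and the
    saturated value ``pi gamma_surf w0`` beyond: piecewise-linear continuous.
    """
    if dz <= 0.0:
        return 0.0
    ramp = 0.1 * w0
    F0 = math.pi * gamma_surf * w0
    if dz >= ramp:
        return F0
    return F0 * dz / ramp


@njit(cache=True)
def build_height_field_nb(r, n, l, count, w0, binsize, pad):
    """Raw colony height on a (x, y) grid: per-bin upper envelope of cell
    tops, cells sampled at 5 points along their axis.  Bins are anchored to
    the absolute lattice ``floor(x / binsize)`` so the grid is stable as the
    colony grows.  Returns ``(ix0, iy0, h_raw)``."""
    xmin = 1e30
    xmax = -1e30
    ymin = 1e30
    ymax = -1e30
    for i in range(count):
        half = 0.5 * l[i] + w0
        if r[i, 0] - half < xmin:
            xmin = r[i, 0] - half
        if r[i, 0] + half > xmax:
            xmax = r[i, 0] + half
        if r[i, 1] - half < ymin:
            ymin = r[i, 1] - half
        if r[i, 1] + half > ymax:
            ymax = r[i, 1] + half
    ix0 = int(math.floor(xmin / binsize)) - pad
    iy0 = int(math.floor(ymin / binsize)) - pad
    nx = int(math.floor(xmax / binsize)) + pad + 1 - ix0
    ny = int(math.floor(ymax / binsize)) + pad + 1 - iy0
    h_raw = np.zeros((nx, ny))
    for i in range(count):
        for k in range(5):
            s = -0.5 + 0.25 * k
            x = r[i, 0] + s * l[i] * n[i, 0]
            y = r[i, 1] + s * l[i] * n[i, 1]
            top = r[i, 2] + s * l[i] * n[i, 2] + 0.5 * w0
            bx = int(math.floor(x / binsize)) - ix0
            by = int(math.floor(y / binsize)) - iy0
            if 0 <= bx < nx and 0 <= by < ny:
                if top > h_raw[bx, by]:
                    h_raw[bx, by] = top
    return ix0, iy0, h_raw


@njit(cache=True)
def smooth3x3_nb(h):
    """3x3 mean filter over the colony footprint.

    Only occupied bins (h > 0) enter the average, so the smoothed liquid
    film hugs the colony surface instead of being dragged toward zero by
    empty neighbors; outside the footprint h stays exactly 0.
    """
    nx, ny = h.shape
    out = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            if h[i, j] <= 0.0:
                continue
            s = 0.0
            c = 0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    ii = i + di
                    jj = j + dj
                    if 0 <= ii < nx and 0 <= jj < ny and h[ii, jj] > 0.0:
                        s += h[ii, jj]
                        c += 1
            out[i, j] = s / c
    return out


# ---------------------------------------------------------------------------
# Python-level containers and wrappers
# ---------------------------------------------------------------------------


@dataclass
class HeightField:
    """Coarse-grained colony height h(x, y) and liquid level hw = h + delta_h."""

    ix0: int
    iy0: int
    binsize: float
    h_raw: np.ndarray          # per-bin upper envelope (before smoothing)
    h: np.ndarray              # smoothed height
    delta_h: float

    @property
    def hw(self) -> np.ndarray:
        return self.h + self.delta_h

    def _index(self, x: float, y: float) -> Tuple[int, int]:
        bx = int(math.floor(x / self.binsize)) - self.ix0
        by = int(math.floor(y / self.binsize)) - self.iy0
        bx = min(max(bx, 0), self.h.shape[0] - 1)
        by = min(max(by, 0), self.h.shape[1] - 1)
        return bx, by

    def height_at(self, x: float, y: float) -> float:
        bx, by = self._index(x, y)
        return float(self.h[bx, by])

    def liquid_level_at(self, x: float, y: float) -> float:
        return self.height_at(x, y) + self.delta_h

    def normal_at(self, x: float, y: float) -> np.ndarray:
        """Upward unit normal of the (smoothed) liquid surface, from central
        differences of hw (adding delta_h does not change the gradient)."""
        bx, by = self._index(x, y)
        nx, ny = self.h.shape
        ip = min(bx + 1, nx - 1)
        im = max(bx - 1, 0)
        jp = min(by + 1, ny - 1)
        jm = max(by - 1, 0)
        gx = (self.h[ip, by] - self.h[im, by]) / ((ip - im) * self.binsize)
        gy = (self.h[bx, jp] - self.h[bx, jm]) / ((jp - jm) * self.binsize)
        v = np.array([-gx, -gy, 1.0])
        return v / np.linalg.norm(v)


def colony_height_field(cells: Sequence[Cell], grid_spacing: float,
                        params: SimulationParams) -> HeightField:
    """Smoothed upper envelope of cell tops, binned on an (x, y) grid.

    Empty bins have h = 0; hw = h + delta_h everywhere.
    """
    if len(cells) == 0:
        raise ValueError("height field needs at least one cell")
    r = np.array([c.r for c in cells], dtype=float)
    n = np.array([c.n for c in cells], dtype=float)
    l = np.array([c.l for c in cells], dtype=float)
    ix0, iy0, h_raw = build_height_field_nb(r, n, l, len(cells),
                                            params.w0, grid_spacing, 2)
    return HeightField(ix0, iy0, grid_spacing, h_raw, smooth3x3_nb(h_raw),
                       params.delta_h)


class AgarSurface:
    """The static, seeded rough agar surface (mean plane z = 0)."""

    def __init__(self, params: SimulationParams, seed: Optional[int] = None):
        self.hran = params.h_ran
        self.binsize = params.hf_bin
        self.seed = params.seed if seed is None else seed

    def height_at(self, x: float, y: float) -> float:
        ix = int(math.floor(x / self.binsize))
        iy = int(math.floor(y / self.binsize))
        return agar_height_nb(ix, iy, self.seed, self.hran)


class ForceAccumulator:
    """Per-cell net force/torque plus the (force, application-offset) ledger
    retained for the virial pressure computation."""

    def __init__(self, n_cells: int):
        self.F_net = np.zeros((n_cells, 3))
        self.T_net = np.zeros((n_cells, 3))
        # ledger[i] = list of (applied force, offset r_ji from application
        # point to the cell center)
        self.ledger: List[List[Tuple[np.ndarray, np.ndarray]]] = [
            [] for _ in range(n_cells)
        ]

    def add(self, i: int, F: np.ndarray, application_point: np.ndarray,
            r_center: np.ndarray) -> None:
        offset = r_center - application_point
        self.F_net[i] += F
        self.T_net[i] += np.cross(application_point - r_center, F)
        self.ledger[i].append((np.asarray(F, float).copy(),
                               np.asarray(offset, float).copy()))

    def add_central(self, i: int, F: np.ndarray) -> None:
        """A force applied at the cell center (no torque, no virial)."""
        self.F_net[i] += F


def _pv(params: SimulationParams) -> np.ndarray:
    return params.pack()


def cell_cell_force(contact: Contact, cell_a: Cell, cell_b: Cell,
                    params: SimulationParams):
    """Force/torque pair of a cell-cell contact.

    Returns ``((F_a, T_a), (F_b, T_b))``; the two forces are exactly equal
    and opposite and are applied at the contact center, so the pair obeys
    Newton's third law component-wise.  Zero relative tangential velocity
    yields zero tangential force (no sliding direction is defined).
    """
    ok, F, rc, _ = cell_cell_force_nb(
        cell_a.r, cell_a.n, cell_a.l, cell_a.v, cell_a.omega,
        cell_b.r, cell_b.n, cell_b.l, cell_b.v, cell_b.omega, _pv(params))
    if not ok:
        z = np.zeros(3)
        return (z, z.copy()), (z.copy(), z.copy())
    T_a = np.cross(rc - cell_a.r, F)
    T_b = np.cross(rc - cell_b.r, -F)
    return (F, T_a), (-F, T_b)


def cell_agar_force(cell: Cell, agar: AgarSurface, params: SimulationParams):
    """Net cell-agar force/torque, testing both hemispherical caps against
    the local rough surface.  A cell fully above the surface feels nothing."""
    pv = _pv(params)
    F_net = np.zeros(3)
    T_net = np.zeros(3)
    entries = []
    for cap in (cell.p, cell.q) if cell.l > 1e-12 else (cell.r,):
        h_local = agar.height_at(cap[0], cap[1])
        ok, F, rca, F_elas = agar_cap_force_nb(
            np.asarray(cap, float), cell.r, cell.v, cell.omega, h_local, pv)
        if ok:
            F_net += F
            T_net += np.cross(rca - cell.r, F)
            entries.append((F, rca, F_elas))
    return F_net, T_net, entries


def viscous_drag(cell: Cell, params: SimulationParams):
    """Stokes drag ``F = -eta_drag v`` at the cell center, plus rotational
    drag ``T = -eta_rot omega`` (if enabled)."""
    F = -params.eta_drag * cell.v
    T = (-params.eta_rot * cell.omega) if params.rot_drag_on else np.zeros(3)
    return F, T


def surface_tension_magnitude(dz: float, params: SimulationParams) -> float:
    return surface_tension_magnitude_nb(dz, params.w0, params.gamma_surf)


def surface_tension_force(cell: Cell, height_field: HeightField,
                          params: SimulationParams):
    """Surface-tension restoring force on a cell protruding above the liquid.

    The protrusion is ``dz = h_cell - hw`` at the cell's (x, y); the force is
    normal to the (smoothed) liquid surface, pointing into the colony, and is
    applied at the centroid of the protruding part of the cell axis (the
    center for a level cell, near the tip for a tilted one, so a flat
    protruding cell is pressed down without being levered over).
    Returns ``(F, T, application_point)``.
    """
    w0 = params.w0
    h_cell = cell.r[2] + 0.5 * cell.l * abs(cell.n[2]) + 0.5 * w0
    hw = height_field.liquid_level_at(cell.r[0], cell.r[1])
    dz = h_cell - hw
    mag = surface_tension_magnitude_nb(dz, w0, params.gamma_surf)
    if mag == 0.0:
        z = np.zeros(3)
        return z, z.copy(), cell.r
    nz = cell.n[2]
    if abs(nz) > 1e-6:
        s_cross = (hw - 0.5 * w0 - cell.r[2]) / nz
        if nz > 0:
            lo = max(-0.5 * cell.l, min(s_cross, 0.5 * cell.l))
            app_s = 0.5 * (lo + 0.5 * cell.l)
        else:
            hi = min(0.5 * cell.l, max(s_cross, -0.5 * cell.l))
            app_s = 0.5 * (hi - 0.5 * cell.l)
    else:
        app_s = 0.0
    app = cell.r + app_s * cell.n
    n_up = height_field.normal_at(cell.r[0], cell.r[1])
    F = -mag * n_up
    T = np.cross(app - cell.r, F)
    return F, T, app
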