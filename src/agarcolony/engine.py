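"""Time integration: inner mechanics loop and outer nutrient/region loop.

The integrator is velocity Verlet on Newton's second law with fictitious
mass/inertia chosen so the dynamics are effectively overdamped (contact
velocities relax within ~10 inner steps).  One *outer* loop consists of
``inner_per_outer`` inner steps followed by region re-classification, a
steady nutrient solve (warm-started), and a growth-rate re-read at every
cell center.  Per inner step each cell elongates, divides when its cylinder
length reaches l_div, and moves under cell-cell, cell-agar, drag, and
surface-tension forces.

The inner loop is a single compiled kernel; all stochastic draws (division
noise, director perturbations, angular-velocity kicks) consume a per-chunk
seed derived deterministically from the master seed, so runs are
reproducible bit-for-bit at fixed seed.
"""

from __future__ import annotations

import math
import time as _time
from dataclasses import dataclass, field as dc_field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd
from numba import njit

from . import mechanics
from .mechanics import (
    agar_height_nb, agar_cap_force_nb, cell_cell_force_nb,
    build_height_field_nb, smooth3x3_nb, surface_tension_magnitude_nb,
)
from .model_core import (
    Cell, SimulationParams, spherocylinder_volume,
    PV_W0, PV_LDIV, PV_L0, PV_SIGMA, PV_ETA, PV_ETA_ROT, PV_MASS,
    PV_INERTIA, PV_DT, PV_DIV_NOISE, PV_ANG_NOISE, PV_OMEGA_KICK,
    PV_HF_BIN, PV_HF_EVERY, PV_MAX_DISP, PV_LAMBDA_S, PV_KS_MASS,
    PV_GSURF, PV_DELTA_H, PV_HRAN, PV_LAM_INNER,
)
from .nutrient_solver import (
    NutrientGrid, NutrientField, classify_regions, solve_steady_nutrient,
    solve_two_level, sample_concentration,
)

__all__ = ["SimulationState", "Snapshot", "Trajectory",
           "initialize", "step_inner", "run", "compute_forces"]

SNAPSHOT_COLUMNS = ["id", "t", "x", "y", "z", "nx", "ny", "nz", "l",
                    "vx", "vy", "vz", "t_birth", "lambda_local", "pressure"]

STATUS_OK = 0
STATUS_UNSTABLE = 1
STATUS_CAPACITY = 2


# ---------------------------------------------------------------------------
# Compiled inner-loop kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sample_trilinear_nb(C, x0, y0, z0, sp, nx, ny, nz, x, y, z):
    fx = (x - x0) / sp - 0.5
    fy = (y - y0) / sp - 0.5
    fz = (z - z0) / sp - 0.5
    i0 = int(math.floor(fx))
    j0 = int(math.floor(fy))
    k0 = int(math.floor(fz))
    i0 = min(max(i0, 0), nx - 2) if nx > 1 else 0
    j0 = min(max(j0, 0), ny - 2) if ny > 1 else 0
    k0 = min(max(k0, 0), nz - 2) if nz > 1 else 0
    tx = min(max(fx - i0, 0.0), 1.0) if nx > 1 else 0.0
    ty = min(max(fy - j0, 0.0), 1.0) if ny > 1 else 0.0
    tz = min(max(fz - k0, 0.0), 1.0) if nz > 1 else 0.0
    i1 = min(i0 + 1, nx - 1)
    j1 = min(j0 + 1, ny - 1)
    k1 = min(k0 + 1, nz - 1)
    v = ((1 - tx) * ((1 - ty) * ((1 - tz) * C[i0, j0, k0] + tz * C[i0, j0, k1])
                     + ty * ((1 - tz) * C[i0, j1, k0] + tz * C[i0, j1, k1]))
         + tx * ((1 - ty) * ((1 - tz) * C[i1, j0, k0] + tz * C[i1, j0, k1])
                 + ty * ((1 - tz) * C[i1, j1, k0] + tz * C[i1, j1, k1])))
    return max(v, 0.0)


@njit(cache=True)
def run_chunk(r, n, l, v, om, tb, lam, ids, F, T, virial,
              N, next_id, nsteps, t0, pv, chunk_seed, rough_seed,
              Cf, cx0, cy0, cz0, csp):
    """Advance the colony by ``nsteps`` inner steps.  Mutates the state
    arrays in place and returns ``(N, next_id, status, max_disp, n_div,
    t_first_above)`` where ``t_first_above`` is the first time a cell center
    exceeded z = w0 (-1 if none): the engine-level buckling event."""
    np.random.seed(chunk_seed)
    w0 = pv[PV_W0]
    dt = pv[PV_DT]
    dt2 = 0.5 * dt
    M = pv[PV_MASS]
    I = pv[PV_INERTIA]
    ldiv = pv[PV_LDIV]
    l0 = pv[PV_L0]
    sigma = pv[PV_SIGMA]
    eta = pv[PV_ETA]
    eta_rot = pv[PV_ETA_ROT]
    hfbin = pv[PV_HF_BIN]
    hf_every = int(pv[PV_HF_EVERY])
    gsurf = pv[PV_GSURF]
    delta_h = pv[PV_DELTA_H]
    hran = pv[PV_HRAN]
    lam_inner = pv[PV_LAM_INNER] > 0.5
    lamS = pv[PV_LAMBDA_S]
    Ks = pv[PV_KS_MASS]
    cnx, cny, cnz = Cf.shape

    cutoff = ldiv * 1.1 + 2.0 * w0
    max_disp_all = 0.0
    n_div = 0
    t_first_above = -1.0
    cap = r.shape[0]

    # height-field working arrays (rebuilt every hf_every steps)
    hx0 = 0
    hy0 = 0
    hs = np.zeros((1, 1))

    status = STATUS_OK
    for step in range(nsteps):
        # ---- first half-kick (forces from previous step) ----
        for i in range(N):
            for d in range(3):
                v[i, d] += F[i, d] / M * dt2
                om[i, d] += T[i, d] / I * dt2
        # ---- drift, director update, growth ----
        for i in range(N):
            dmax = 0.0
            for d in range(3):
                dx = v[i, d] * dt
                r[i, d] += dx
                if abs(dx) > dmax:
                    dmax = abs(dx)
            if dmax > max_disp_all:
                max_disp_all = dmax
            # n' = n + (omega x n) dt, renormalized
            ox = om[i, 1] * n[i, 2] - om[i, 2] * n[i, 1]
            oy = om[i, 2] * n[i, 0] - om[i, 0] * n[i, 2]
            oz = om[i, 0] * n[i, 1] - om[i, 1] * n[i, 0]
            n[i, 0] += ox * dt
            n[i, 1] += oy * dt
            n[i, 2] += oz * dt
            nn = math.sqrt(n[i, 0] ** 2 + n[i, 1] ** 2 + n[i, 2] ** 2)
            n[i, 0] /= nn
            n[i, 1] /= nn
            n[i, 2] /= nn
            if lam_inner:
                c = _sample_trilinear_nb(Cf, cx0, cy0, cz0, csp,
                                         cnx, cny, cnz,
                                         r[i, 0], r[i, 1], r[i, 2])
                lam[i] = lamS * c / (c + Ks)
            l[i] *= math.exp(sigma * lam[i] * dt)
        if max_disp_all > pv[PV_MAX_DISP]:
            return N, next_id, STATUS_UNSTABLE, max_disp_all, n_div, t_first_above
        # ---- divisions ----
        t_now = t0 + (step + 1) * dt
        Ncur = N
        for i in range(Ncur):
            if l[i] >= ldiv:
                if N >= cap:
                    return N, next_id, STATUS_CAPACITY, max_disp_all, n_div, t_first_above
                u = np.random.uniform(-pv[PV_DIV_NOISE], pv[PV_DIV_NOISE])
                uA = u
                uB = -u
                eps = pv[PV_ANG_NOISE]
                pertA = np.random.uniform(-eps, eps, 3)
                pertB = np.random.uniform(-eps, eps, 3)
                kickA = np.random.uniform(-pv[PV_OMEGA_KICK], pv[PV_OMEGA_KICK], 3)
                kickB = np.random.uniform(-pv[PV_OMEGA_KICK], pv[PV_OMEGA_KICK], 3)
                lA = l0 * (1.0 + uA)
                lB = l0 * (1.0 + uB)
                lm = l[i]
                # caps of the mother
                px = r[i, 0] + 0.5 * lm * n[i, 0]
                py = r[i, 1] + 0.5 * lm * n[i, 1]
                pz = r[i, 2] + 0.5 * lm * n[i, 2]
                qx = r[i, 0] - 0.5 * lm * n[i, 0]
                qy = r[i, 1] - 0.5 * lm * n[i, 1]
                qz = r[i, 2] - 0.5 * lm * n[i, 2]
                nAx = n[i, 0] + pertA[0]
                nAy = n[i, 1] + pertA[1]
                nAz = n[i, 2] + pertA[2]
                sA = math.sqrt(nAx * nAx + nAy * nAy + nAz * nAz)
                nBx = n[i, 0] + pertB[0]
                nBy = n[i, 1] + pertB[1]
                nBz = n[i, 2] + pertB[2]
                sB = math.sqrt(nBx * nBx + nBy * nBy + nBz * nBz)
                j = N
                # daughter B keeps the q cap
                r[j, 0] = qx + 0.5 * lB * n[i, 0]
                r[j, 1] = qy + 0.5 * lB * n[i, 1]
                r[j, 2] = qz + 0.5 * lB * n[i, 2]
                n[j, 0] = nBx / sB
                n[j, 1] = nBy / sB
                n[j, 2] = nBz / sB
                l[j] = lB
                for d in range(3):
                    v[j, d] = v[i, d]
                    om[j, d] = om[i, d] + kickB[d]
                    F[j, d] = 0.0
                    T[j, d] = 0.0
                tb[j] = t_now
                lam[j] = lam[i]
                ids[j] = next_id
                virial[j] = 0.0
                next_id += 1
                # daughter A keeps the p cap (reuses the mother's slot)
                r[i, 0] = px - 0.5 * lA * n[i, 0]
                r[i, 1] = py - 0.5 * lA * n[i, 1]
                r[i, 2] = pz - 0.5 * lA * n[i, 2]
                n[i, 0] = nAx / sA
                n[i, 1] = nAy / sA
                n[i, 2] = nAz / sA
                l[i] = lA
                for d in range(3):
                    om[i, d] += kickA[d]
                tb[i] = t_now
                N += 1
                n_div += 1
        # ---- height field (rebuild on schedule) ----
        if step % hf_every == 0 or step == 0:
            hx0, hy0, hraw = build_height_field_nb(r, n, l, N, w0, hfbin, 2)
            hs = smooth3x3_nb(hraw)
        hnx, hny = hs.shape
        # ---- forces ----
        for i in range(N):
            virial[i] = 0.0
            for d in range(3):
                F[i, d] = -eta * v[i, d]
                T[i, d] = -eta_rot * om[i, d]
        # cell binning (linked lists)
        xmin = 1e30
        ymin = 1e30
        zmin = 1e30
        xmax = -1e30
        ymax = -1e30
        zmax = -1e30
        for i in range(N):
            if r[i, 0] < xmin:
                xmin = r[i, 0]
            if r[i, 0] > xmax:
                xmax = r[i, 0]
            if r[i, 1] < ymin:
                ymin = r[i, 1]
            if r[i, 1] > ymax:
                ymax = r[i, 1]
            if r[i, 2] < zmin:
                zmin = r[i, 2]
            if r[i, 2] > zmax:
                zmax = r[i, 2]
        nbx = int((xmax - xmin) / cutoff) + 1
        nby = int((ymax - ymin) / cutoff) + 1
        nbz = int((zmax - zmin) / cutoff) + 1
        head = -np.ones(nbx * nby * nbz, dtype=np.int64)
        nxt = -np.ones(N, dtype=np.int64)
        binof = np.empty((N, 3), dtype=np.int64)
        for i in range(N):
            bi = int((r[i, 0] - xmin) / cutoff)
            bj = int((r[i, 1] - ymin) / cutoff)
            bk = int((r[i, 2] - zmin) / cutoff)
            if bi >= nbx:
                bi = nbx - 1
            if bj >= nby:
                bj = nby - 1
            if bk >= nbz:
                bk = nbz - 1
            binof[i, 0] = bi
            binof[i, 1] = bj
            binof[i, 2] = bk
            b = (bi * nby + bj) * nbz + bk
            nxt[i] = head[b]
            head[b] = i
        # cell-cell contacts
        for i in range(N):
            bi = binof[i, 0]
            bj = binof[i, 1]
            bk = binof[i, 2]
            for di in range(-1, 2):
                ii = bi + di
                if ii < 0 or ii >= nbx:
                    continue
                for dj in range(-1, 2):
                    jj = bj + dj
                    if jj < 0 or jj >= nby:
                        continue
                    for dk in range(-1, 2):
                        kk = bk + dk
                        if kk < 0 or kk >= nbz:
                            continue
                        j = head[(ii * nby + jj) * nbz + kk]
                        while j != -1:
                            if j > i:
                                dx = r[i, 0] - r[j, 0]
                                dy = r[i, 1] - r[j, 1]
                                dz = r[i, 2] - r[j, 2]
                                reach = 0.5 * (l[i] + l[j]) + w0
                                if dx * dx + dy * dy + dz * dz < reach * reach:
                                    ok, Fij, rc, _ = cell_cell_force_nb(
                                        r[i], n[i], l[i], v[i], om[i],
                                        r[j], n[j], l[j], v[j], om[j], pv)
                                    if ok:
                                        ax = rc[0] - r[i, 0]
                                        ay = rc[1] - r[i, 1]
                                        az = rc[2] - r[i, 2]
                                        bx2 = rc[0] - r[j, 0]
                                        by2 = rc[1] - r[j, 1]
                                        bz2 = rc[2] - r[j, 2]
                                        F[i, 0] += Fij[0]
                                        F[i, 1] += Fij[1]
                                        F[i, 2] += Fij[2]
                                        F[j, 0] -= Fij[0]
                                        F[j, 1] -= Fij[1]
                                        F[j, 2] -= Fij[2]
                                        T[i, 0] += ay * Fij[2] - az * Fij[1]
                                        T[i, 1] += az * Fij[0] - ax * Fij[2]
                                        T[i, 2] += ax * Fij[1] - ay * Fij[0]
                                        T[j, 0] -= by2 * Fij[2] - bz2 * Fij[1]
                                        T[j, 1] -= bz2 * Fij[0] - bx2 * Fij[2]
                                        T[j, 2] -= bx2 * Fij[1] - by2 * Fij[0]
                                        virial[i] += (-ax * Fij[0] - ay * Fij[1]
                                                      - az * Fij[2])
                                        virial[j] += (bx2 * Fij[0] + by2 * Fij[1]
                                                      + bz2 * Fij[2])
                            j = nxt[j]
        # cell-agar and surface tension
        for i in range(N):
            # agar contact at both caps
            for sgn in (1.0, -1.0):
                capx = r[i, 0] + sgn * 0.5 * l[i] * n[i, 0]
                capy = r[i, 1] + sgn * 0.5 * l[i] * n[i, 1]
                capz = r[i, 2] + sgn * 0.5 * l[i] * n[i, 2]
                hx = int(math.floor(capx / hfbin))
                hy = int(math.floor(capy / hfbin))
                h_local = agar_height_nb(hx, hy, rough_seed, hran)
                cap3 = np.array((capx, capy, capz))
                ok, Fa, rca, _ = agar_cap_force_nb(cap3, r[i], v[i], om[i],
                                                   h_local, pv)
                if ok:
                    ax = rca[0] - r[i, 0]
                    ay = rca[1] - r[i, 1]
                    az = rca[2] - r[i, 2]
                    F[i, 0] += Fa[0]
                    F[i, 1] += Fa[1]
                    F[i, 2] += Fa[2]
                    T[i, 0] += ay * Fa[2] - az * Fa[1]
                    T[i, 1] += az * Fa[0] - ax * Fa[2]
                    T[i, 2] += ax * Fa[1] - ay * Fa[0]
                    virial[i] += -(ax * Fa[0] + ay * Fa[1] + az * Fa[2])
                if l[i] <= 1e-12:
                    break
            # surface tension on the protruding part of the cell
            hcell = r[i, 2] + 0.5 * l[i] * abs(n[i, 2]) + 0.5 * w0
            bx = int(math.floor(r[i, 0] / hfbin)) - hx0
            by = int(math.floor(r[i, 1] / hfbin)) - hy0
            if bx < 0:
                bx = 0
            if bx > hnx - 1:
                bx = hnx - 1
            if by < 0:
                by = 0
            if by > hny - 1:
                by = hny - 1
            hw_loc = hs[bx, by] + delta_h
            dzp = hcell - hw_loc
            mag = surface_tension_magnitude_nb(dzp, w0, gsurf)
            if mag > 0.0:
                # application point: centroid of the protruding axis segment
                # (cell center for a level cell, near the tip when tilted)
                nzc = n[i, 2]
                if abs(nzc) > 1e-6:
                    s_cross = (hw_loc - 0.5 * w0 - r[i, 2]) / nzc
                    if nzc > 0.0:
                        lo = max(-0.5 * l[i], min(s_cross, 0.5 * l[i]))
                        app_s = 0.5 * (lo + 0.5 * l[i])
                    else:
                        hi = min(0.5 * l[i], max(s_cross, -0.5 * l[i]))
                        app_s = 0.5 * (hi - 0.5 * l[i])
                else:
                    app_s = 0.0
                cx = r[i, 0] + app_s * n[i, 0]
                cy = r[i, 1] + app_s * n[i, 1]
                cz = r[i, 2] + app_s * n[i, 2]
                ip = bx + 1 if bx + 1 < hnx else bx
                im = bx - 1 if bx - 1 >= 0 else bx
                jp = by + 1 if by + 1 < hny else by
                jm = by - 1 if by - 1 >= 0 else by
                gx = (hs[ip, by] - hs[im, by]) / ((ip - im) * hfbin) if ip != im else 0.0
                gy = (hs[bx, jp] - hs[bx, jm]) / ((jp - jm) * hfbin) if jp != jm else 0.0
                nrm = math.sqrt(gx * gx + gy * gy + 1.0)
                Fsx = mag * gx / nrm
                Fsy = mag * gy / nrm
                Fsz = -mag / nrm
                ax = cx - r[i, 0]
                ay = cy - r[i, 1]
                az = cz - r[i, 2]
                F[i, 0] += Fsx
                F[i, 1] += Fsy
                F[i, 2] += Fsz
                T[i, 0] += ay * Fsz - az * Fsy
                T[i, 1] += az * Fsx - ax * Fsz
                T[i, 2] += ax * Fsy - ay * Fsx
                virial[i] += -(ax * Fsx + ay * Fsy + az * Fsz)
            if t_first_above < 0.0 and r[i, 2] > w0:
                t_first_above = t_now
        # ---- second half-kick ----
        for i in range(N):
            for d in range(3):
                v[i, d] += F[i, d] / M * dt2
                om[i, d] += T[i, d] / I * dt2
    return N, next_id, status, max_disp_all, n_div, t_first_above


# ---------------------------------------------------------------------------
# State, snapshots, trajectory
# ---------------------------------------------------------------------------


@dataclass
class Snapshot:
    """Per-cell record of the colony at one instant."""

    t: float
    ids: np.ndarray
    r: np.ndarray
    n: np.ndarray
    l: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    t_birth: np.ndarray
    lambda_local: np.ndarray
    pressure: np.ndarray
    w0: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.l)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "t": self.t,
            "x": self.r[:, 0], "y": self.r[:, 1], "z": self.r[:, 2],
            "nx": self.n[:, 0], "ny": self.n[:, 1], "nz": self.n[:, 2],
            "l": self.l,
            "vx": self.v[:, 0], "vy": self.v[:, 1], "vz": self.v[:, 2],
            "t_birth": self.t_birth, "lambda_local": self.lambda_local,
            "pressure": self.pressure,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, w0: float = 1.0) -> "Snapshot":
        return cls(
            t=float(df["t"].iloc[0]) if len(df) else 0.0,
            ids=df["id"].to_numpy(int),
            r=df[["x", "y", "z"]].to_numpy(float),
            n=df[["nx", "ny", "nz"]].to_numpy(float),
            l=df["l"].to_numpy(float),
            v=df[["vx", "vy", "vz"]].to_numpy(float),
            omega=np.zeros((len(df), 3)),
            t_birth=df["t_birth"].to_numpy(float),
            lambda_local=df["lambda_local"].to_numpy(float),
            pressure=df["pressure"].to_numpy(float),
            w0=w0,
        )


class Trajectory:
    """A run's snapshots plus the per-outer-loop log and a manifest."""

    def __init__(self, params: SimulationParams):
        self.params = params
        self.snapshots: List[Snapshot] = []
        self.log_records: List[dict] = []
        self.events: List[dict] = []

    @property
    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_records)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def save(self, out_dir) -> None:
        import hashlib
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, snap in enumerate(self.snapshots):
            snap.to_dataframe().to_csv(out / f"snapshot_{k:05d}.csv",
                                       index=False)
        self.log.to_csv(out / "log.csv", index=False)
        cfg = yaml_dump(self.params.to_dict())
        (out / "config.yaml").write_text(cfg)
        manifest = {
            "seed": self.params.seed,
            "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
            "n_snapshots": len(self.snapshots),
            "snapshot_columns": SNAPSHOT_COLUMNS,
            "events": self.events,
        }
        (out / "manifest.yaml").write_text(yaml_dump(manifest))

    @classmethod
    def load(cls, out_dir) -> "Trajectory":
        import pathlib

        out = pathlib.Path(out_dir)
        params = SimulationParams.from_yaml(out / "config.yaml")
        traj = cls(params)
        for f in sorted(out.glob("snapshot_*.csv")):
            traj.snapshots.append(
                Snapshot.from_dataframe(pd.read_csv(f), w0=params.w0))
        logf = out / "log.csv"
        if logf.exists() and logf.stat().st_size > 1:
            try:
                df = pd.read_csv(logf)
                traj.log_records = df.to_dict("records")
            except pd.errors.EmptyDataError:
                pass
        return traj


def yaml_dump(obj) -> str:
    import yaml
    return yaml.safe_dump(obj, sort_keys=False)


@dataclass
class SimulationState:
    """Mutable state of a running simulation (capacity-managed arrays)."""

    params: SimulationParams
    t: float = 0.0
    count: int = 0
    next_id: int = 0
    chunk_counter: int = 0
    r: np.ndarray = None
    n: np.ndarray = None
    l: np.ndarray = None
    v: np.ndarray = None
    omega: np.ndarray = None
    t_birth: np.ndarray = None
    lam: np.ndarray = None
    ids: np.ndarray = None
    F: np.ndarray = None
    T: np.ndarray = None
    virial: np.ndarray = None
    nutrient: Optional[NutrientField] = None
    grid: Optional[NutrientGrid] = None
    t_buckle_engine: Optional[float] = None
    events: List[dict] = dc_field(default_factory=list)

    def _alloc(self, capacity: int) -> None:
        self.r = np.zeros((capacity, 3))
        self.n = np.zeros((capacity, 3))
        self.l = np.zeros(capacity)
        self.v = np.zeros((capacity, 3))
        self.omega = np.zeros((capacity, 3))
        self.t_birth = np.zeros(capacity)
        self.lam = np.zeros(capacity)
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.F = np.zeros((capacity, 3))
        self.T = np.zeros((capacity, 3))
        self.virial = np.zeros(capacity)

    def ensure_capacity(self, needed: int) -> None:
        cap = len(self.l)
        if needed <= cap:
            return
        new = max(needed, 2 * cap)
        for name in ("r", "n", "v", "omega", "F", "T"):
            arr = np.zeros((new, 3))
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)
        for name, dtype in (("l", float), ("t_birth", float), ("lam", float),
                            ("virial", float), ("ids", np.int64)):
            arr = np.zeros(new, dtype=dtype)
            arr[:cap] = getattr(self, name)
            setattr(self, name, arr)

    def cells(self) -> List[Cell]:
        p = self.params
        return [
            Cell(id=int(self.ids[i]), r=self.r[i].copy(), n=self.n[i].copy(),
                 l=float(self.l[i]), v=self.v[i].copy(),
                 omega=self.omega[i].copy(), M=p.mass, I=p.inertia,
                 t_birth=float(self.t_birth[i]),
                 lambda_local=float(self.lam[i]))
            for i in range(self.count)
        ]

    def snapshot(self) -> Snapshot:
        N = self.count
        vol = spherocylinder_volume(self.l[:N], self.params.w0)
        return Snapshot(
            t=self.t,
            ids=self.ids[:N].copy(), r=self.r[:N].copy(),
            n=self.n[:N].copy(), l=self.l[:N].copy(),
            v=self.v[:N].copy(), omega=self.omega[:N].copy(),
            t_birth=self.t_birth[:N].copy(),
            lambda_local=self.lam[:N].copy(),
            pressure=self.virial[:N] / vol,
            w0=self.params.w0,
        )

    def height_field(self) -> mechanics.HeightField:
        N = self.count
        p = self.params
        ix0, iy0, h_raw = build_height_field_nb(
            self.r[:N], self.n[:N], self.l[:N], N, p.w0, p.hf_bin, 2)
        return mechanics.HeightField(ix0, iy0, p.hf_bin, h_raw,
                                     smooth3x3_nb(h_raw), p.delta_h)


# ---------------------------------------------------------------------------
# Engine operations
# ---------------------------------------------------------------------------


def initialize(params: SimulationParams,
               solve_nutrient: bool = True) -> SimulationState:
    """A single horizontal newborn cell resting at the origin on the (rough)
    agar surface, zero velocity, nutrient field solved once."""
    state = SimulationState(params=params)
    state._alloc(1024)
    w0 = params.w0
    l0 = params.l0
    # rest on the local rough surface under the caps
    h1 = agar_height_nb(int(math.floor(-0.5 * l0 / params.hf_bin)), 0,
                        params.seed, params.h_ran)
    h2 = agar_height_nb(int(math.floor(0.5 * l0 / params.hf_bin)), 0,
                        params.seed, params.h_ran)
    z0 = 0.5 * w0 + max(h1, h2, 0.0)
    state.r[0] = (0.0, 0.0, z0)
    state.n[0] = (1.0, 0.0, 0.0)
    state.l[0] = l0
    state.ids[0] = 0
    state.count = 1
    state.next_id = 1
    state.grid = NutrientGrid(params.L, params.a, params.b,
                              params.uniform_spacing)
    if solve_nutrient:
        outer_update(state)
    else:
        state.lam[:1] = params.lambda_S * params.C_s_mass / (
            params.C_s_mass + params.K_S_mass)
    return state


def _chunk_seed(params: SimulationParams, counter: int) -> int:
    return int((params.seed * 1000003 + counter * 7919 + 12345) % (2 ** 31))


def step_inner(state: SimulationState, n_steps: int = 1) -> SimulationState:
    """Advance the mechanics/growth inner loop by ``n_steps`` timesteps."""
    p = state.params
    state.ensure_capacity(2 * state.count + 64)
    if state.nutrient is not None:
        Cf = state.nutrient.C
        g = state.nutrient.grid
        meta = (g.x0, g.y0, g.z0, g.spacing)
    else:
        Cf = np.full((1, 1, 1), p.C_s_mass)
        meta = (-1e6, -1e6, -1e6, 2e6)
    seed = _chunk_seed(p, state.chunk_counter)
    state.chunk_counter += 1
    (N, next_id, status, max_disp, n_div, t_above) = run_chunk(
        state.r, state.n, state.l, state.v, state.omega, state.t_birth,
        state.lam, state.ids, state.F, state.T, state.virial,
        state.count, state.next_id, n_steps, state.t, p.pack(),
        seed, p.seed, Cf, *meta)
    state.count = N
    state.next_id = next_id
    state.t += n_steps * p.dt
    if status == STATUS_UNSTABLE:
        raise RuntimeError(
            f"integration unstable: per-step displacement {max_disp:.3g} um "
            f"exceeded {p.max_disp_frac} * w0 at t={state.t:.4f} h "
            f"(N={N}); reduce dt")
    if status == STATUS_CAPACITY:
        raise RuntimeError("cell capacity exceeded within one chunk")
    if t_above >= 0 and state.t_buckle_engine is None:
        state.t_buckle_engine = float(t_above)
        state.events.append({"event": "buckling",
                             "t": float(t_above)})
    if n_div:
        state.events.append({"event": "divisions", "t": state.t,
                             "count": int(n_div)})
    return state


def outer_update(state: SimulationState) -> None:
    """Region classification + steady nutrient solve + growth-rate re-read."""
    p = state.params
    N = state.count
    cells = (state.r[:N], state.l[:N])
    if p.grid_mode == "two_level":
        fine, coarse = solve_two_level(cells, p)
        state.nutrient = fine
        field_for_sampling = fine
    else:
        labels = classify_regions(cells, state.grid, p)
        C0 = state.nutrient.C if state.nutrient is not None else None
        state.nutrient = solve_steady_nutrient(labels, p, state.grid, C0=C0)
        field_for_sampling = state.nutrient
    g = field_for_sampling.grid
    for i in range(N):
        x = min(max(state.r[i, 0], g.x0 + 1e-9),
                g.x0 + g.nx * g.spacing - 1e-9)
        y = min(max(state.r[i, 1], g.y0 + 1e-9),
                g.y0 + g.ny * g.spacing - 1e-9)
        z = min(max(state.r[i, 2], g.z0 + 1e-9),
                g.z0 + g.nz * g.spacing - 1e-9)
        c = sample_concentration(field_for_sampling, (x, y, z))
        state.lam[i] = p.lambda_S * c / (c + p.K_S_mass)


def check_state(state: SimulationState) -> None:
    """Engine invariants: directors unit-norm; no cell sunk into the agar
    deeper than the equilibrium Hertzian overlap under a generous maximum
    vertical load (a few saturated surface-tension forces)."""
    N = state.count
    p = state.params
    norms = np.linalg.norm(state.n[:N], axis=1)
    assert np.all(np.abs(norms - 1.0) < 1e-6), "director norm drift"
    delta_max = (5.0 * p.F_surf0 / p.k_n) ** (2.0 / 3.0) + p.h_ran
    low = np.minimum(
        state.r[:N, 2] + 0.5 * state.l[:N] * state.n[:N, 2],
        state.r[:N, 2] - 0.5 * state.l[:N] * state.n[:N, 2]) - 0.5 * p.w0
    assert low.min() >= -delta_max - 1e-9, (
        f"cell sunk {-low.min():.3f} um into agar (limit {delta_max:.3f})")


def run(params: SimulationParams, t_max: float,
        snapshot_interval: float = 0.25,
        out_dir=None,
        stop_when: Optional[Callable[[SimulationState], bool]] = None,
        log_fn: Optional[Callable[[str], None]] = None,
        validate: bool = True) -> Trajectory:
    """Run the two-loop simulation to ``t_max`` hours.

    Alternates ``inner_per_outer`` compiled inner steps with an outer loop
    (region classification, steady nutrient solve, growth-rate re-read).
    Snapshots (with per-cell pressures) are recorded every
    ``snapshot_interval`` hours; ``stop_when(state)`` is evaluated each outer
    loop for early termination.  Returns the trajectory; optionally saves it
    to ``out_dir``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    p = params
    state = initialize(p)
    traj = Trajectory(p)
    traj.snapshots.append(state.snapshot())
    outer_dt = p.inner_per_outer * p.dt
    next_snap = snapshot_interval
    t_wall0 = _time.time()
    while state.t < t_max - 1e-12:
        step_inner(state, p.inner_per_outer)
        outer_update(state)
        hf = state.height_field()
        N = state.count
        cx = float(state.r[:N, 0].mean())
        cy = float(state.r[:N, 1].mean())
        H = hf.height_at(cx, cy)
        rad = np.hypot(state.r[:N, 0] - cx, state.r[:N, 1] - cy)
        rec = {
            "t": round(state.t, 10), "n_cells": N,
            "R_quick": float(rad.max()) + 0.5 * p.w0, "H": H,
            "picard": state.nutrient.picard_iterations,
            "residual": state.nutrient.residual,
            "wall_s": _time.time() - t_wall0,
        }
        traj.log_records.append(rec)
        if log_fn is not None:
            log_fn(f"t={rec['t']:.2f}h N={N} R={rec['R_quick']:.1f}um "
                   f"H={H:.2f}um picard={rec['picard']} "
                   f"wall={rec['wall_s']:.0f}s")
        if state.t >= next_snap - 1e-9:
            if validate:
                check_state(state)
            traj.snapshots.append(state.snapshot())
            next_snap += snapshot_interval
        if stop_when is not None and stop_when(state):
            break
    traj.events = list(state.events)
    if out_dir is not None:
        traj.save(out_dir)
    return traj


# ---------------------------------------------------------------------------
# Ledger-recording force evaluation (test-scale, shares the kernels)
# ---------------------------------------------------------------------------


def compute_forces(cells: List[Cell], params: SimulationParams,
                   with_agar: bool = True, with_surface: bool = True,
                   with_drag: bool = True,
                   height_field: Optional[mechanics.HeightField] = None,
                   ) -> mechanics.ForceAccumulator:
    """Evaluate all forces on an explicit list of cells, recording the full
    (force, offset) ledger.  O(N^2); intended for analysis and tests - the
    engine's compiled kernel performs the same computation with cell lists."""
    from .model_core import Contact

    acc = mechanics.ForceAccumulator(len(cells))
    agar = mechanics.AgarSurface(params)
    hf = height_field
    if with_surface and hf is None and cells:
        hf = mechanics.colony_height_field(cells, params.hf_bin, params)
    for i, ci in enumerate(cells):
        for j in range(i + 1, len(cells)):
            cj = cells[j]
            contact = Contact.between_cells(ci, cj, params.w0)
            if contact.delta <= 0:
                continue
            (Fa, _), (Fb, _) = mechanics.cell_cell_force(contact, ci, cj,
                                                         params)
            acc.add(i, Fa, contact.center, ci.r)
            acc.add(j, Fb, contact.center, cj.r)
        if with_agar:
            _, _, entries = mechanics.cell_agar_force(ci, agar, params)
            for Fc, rca, _ in entries:
                acc.add(i, Fc, rca, ci.r)
        if with_surface and hf is not None:
            Fs, _, pt = mechanics.surface_tension_force(ci, hf, params)
            if np.any(Fs != 0):
                acc.add(i, Fs, pt, ci.r)
        if with_drag:
            Fd, Td = mechanics.viscous_drag(ci, params)
            acc.add_central(i, Fd)
            acc.T_net[i] += Td
    return acc
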