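"""Quasi-static nutrient concentration over agar + colony + air.

The steady diffusion-consumption problem

    0 = D(r) Laplacian(C) - rho0 * lambda_S * C / ((C + K_S) * Y)   (colony)
    0 = D(r) Laplacian(C)                                           (agar)

is solved on a 3D finite-difference grid spanning the computational box
Omega = (-L, L) x (-L, L) x (-a, b).  Agar occupies z < 0 with diffusivity
D_minus, the colony occupies the density-thresholded region above the agar
with diffusivity D_plus, and air voxels carry no equation.  Concentration and
flux continuity at the agar-colony interface are enforced by harmonic-mean
face diffusivities; boundary conditions are no-flux everywhere except a
Dirichlet condition C = C_s on the lateral agar wall.

The nonlinear Monod sink is handled by Picard iteration with a lagged
coefficient (sink linearized as ``s(C_prev) * C``), each linearized system
being symmetric positive definite and solved by Jacobi-preconditioned
conjugate gradients.  Concentrations are internal mass units (g/um^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .model_core import SimulationParams, spherocylinder_volume

__all__ = [
    "AIR", "COLONY", "AGAR",
    "NutrientGrid", "NutrientField",
    "classify_regions", "solve_steady_nutrient", "solve_two_level",
    "sample_concentration", "conservation_residual",
]

AIR = 0
COLONY = 1
AGAR = 2


@dataclass
class NutrientGrid:
    """Uniform voxel grid over (-L, L)^2 x (-a, b); z = 0 is a voxel face."""

    L: float
    a: float
    b: float
    spacing: float
    x0: float = None  # lower corner; defaults to -L, -L, -a
    y0: float = None

    def __post_init__(self):
        sp = self.spacing
        if self.x0 is None:
            self.x0 = -self.L
        if self.y0 is None:
            self.y0 = -self.L
        self.nx = max(int(round(2 * self.L / sp)), 1)
        self.ny = self.nx
        self.n_agar = max(int(round(self.a / sp)), 1)
        self.n_above = max(int(round(self.b / sp)), 1)
        self.nz = self.n_agar + self.n_above
        self.z0 = -self.n_agar * sp

    @property
    def shape(self) -> Tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def y(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.spacing

    @property
    def z(self) -> np.ndarray:
        return self.z0 + (np.arange(self.nz) + 0.5) * self.spacing

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3


@dataclass
class NutrientField:
    """Concentration, region labels, and diffusivity on a grid."""

    grid: NutrientGrid
    C: np.ndarray                 # g/um^3, air voxels hold extrapolated values
    labels: np.ndarray            # int8, AIR/COLONY/AGAR
    params: SimulationParams
    picard_iterations: int = 0
    residual: float = 0.0
    clamped_negative: bool = False

    def sample(self, point) -> float:
        return sample_concentration(self, point)

    def on_axis_profile(self, x: float = 0.0, y: float = 0.0):
        """Vertical concentration profile C(x, y, z) for z >= 0."""
        g = self.grid
        zs = g.z[g.z >= 0]
        vals = np.array([self.sample((x, y, z)) for z in zs])
        return zs, vals

    def to_mM(self) -> np.ndarray:
        """Concentration in mM (for display; internal units are g/um^3)."""
        # g/um^3 -> mol/L is *1e15/M; -> mM is a further *1e3
        return self.C * 1e18 / self.params.molar_mass

    def to_hdf5(self, path) -> None:
        import h5py
        g = self.grid
        with h5py.File(path, "w") as fh:
            fh.create_dataset("C", data=self.C)
            fh.create_dataset("labels", data=self.labels)
            fh.attrs["spacing"] = g.spacing
            fh.attrs["x0"] = g.x0
            fh.attrs["y0"] = g.y0
            fh.attrs["z0"] = g.z0
            fh.attrs["units"] = "g/um^3"


def classify_regions(cells, grid: NutrientGrid,
                     params: SimulationParams) -> np.ndarray:
    """Region labels from the coarse cell density.

    A voxel at z >= 0 is colony if the binned cell dry-mass density reaches
    ``rho_threshold``; every z < 0 voxel is agar; the rest is air.  Enclosed
    air pockets inside the colony are filled so the region is simply
    connected.  ``cells`` may be a sequence of Cell or a tuple of arrays
    ``(r, l)``.
    """
    labels = np.full(grid.shape, AIR, dtype=np.int8)
    labels[:, :, grid.z < 0] = AGAR
    if isinstance(cells, tuple):
        r, l = cells
        r = np.asarray(r, float)
        l = np.asarray(l, float)
    else:
        r = np.array([c.r for c in cells], float).reshape(-1, 3)
        l = np.array([c.l for c in cells], float)
    if len(l) == 0:
        return labels
    vol = spherocylinder_volume(l, params.w0)
    mass = vol * params.rho_cell
    sp = grid.spacing
    ii = np.floor((r[:, 0] - grid.x0) / sp).astype(int)
    jj = np.floor((r[:, 1] - grid.y0) / sp).astype(int)
    kk = np.floor((r[:, 2] - grid.z0) / sp).astype(int)
    ok = ((ii >= 0) & (ii < grid.nx) & (jj >= 0) & (jj < grid.ny)
          & (kk >= 0) & (kk < grid.nz))
    dens = np.zeros(grid.shape)
    np.add.at(dens, (ii[ok], jj[ok], kk[ok]), mass[ok])
    dens /= grid.voxel_volume
    colony = (dens >= params.rho_threshold) & (labels == AIR)
    if params.rho_threshold == 0:
        colony = (dens > 0) & (labels == AIR)
    if colony.any():
        solid = colony | (labels == AGAR)
        solid = ndimage.binary_fill_holes(solid)
        colony = solid & (labels == AIR)
    labels[colony] = COLONY
    return labels


def _face_weights(D: np.ndarray, axis: int, spacing: float) -> np.ndarray:
    """Harmonic-mean face diffusivity / spacing^2 along one axis (interface
    flux continuity); zero wherever either side is impermeable (air)."""
    D1 = D.take(range(D.shape[axis] - 1), axis=axis)
    D2 = D.take(range(1, D.shape[axis]), axis=axis)
    s = D1 + D2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(s > 0, 2.0 * D1 * D2 / np.where(s > 0, s, 1.0), 0.0)
    return w / spacing ** 2


def solve_steady_nutrient(labels: np.ndarray, params: SimulationParams,
                          grid: NutrientGrid,
                          C0: Optional[np.ndarray] = None,
                          extra_dirichlet: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                          ) -> NutrientField:
    """Solve the steady nonlinear diffusion-consumption problem.

    ``extra_dirichlet`` is an optional ``(mask, values)`` pair of additional
    pinned voxels (used by the two-level scheme to impose the coarse solution
    on the fine window boundary).  Raises RuntimeError on non-convergence.
    """
    g = grid
    Cs = params.C_s_mass
    Ks = params.K_S_mass
    tol = params.solver_tol_frac * Cs
    D = np.zeros(g.shape)
    D[labels == AGAR] = params.D_minus_h
    D[labels == COLONY] = params.D_plus_h

    solid = labels != AIR
    # Dirichlet: lateral agar wall
    dir_mask = np.zeros(g.shape, dtype=bool)
    zneg = g.z < 0
    dir_mask[0, :, zneg] = True
    dir_mask[-1, :, zneg] = True
    dir_mask[:, 0, zneg] = True
    dir_mask[:, -1, zneg] = True
    dir_mask &= solid
    dir_vals = np.where(dir_mask, Cs, 0.0)
    if extra_dirichlet is not None:
        m, v = extra_dirichlet
        dir_mask = dir_mask | (m & solid)
        dir_vals = np.where(m & solid, v, dir_vals)

    unknown = solid & ~dir_mask
    n_un = int(unknown.sum())
    if n_un == 0:
        C = np.where(solid, dir_vals, Cs)
        return NutrientField(g, C, labels, params)

    idx = -np.ones(g.shape, dtype=np.int64)
    idx[unknown] = np.arange(n_un)

    rows = []
    cols = []
    vals = []
    diag = np.zeros(n_un)
    rhs0 = np.zeros(n_un)
    for axis in range(3):
        w = _face_weights(D, axis, g.spacing)
        lo = tuple(slice(0, -1) if ax == axis else slice(None) for ax in range(3))
        hi = tuple(slice(1, None) if ax == axis else slice(None) for ax in range(3))
        u_lo = unknown[lo]
        u_hi = unknown[hi]
        d_lo = dir_mask[lo]
        d_hi = dir_mask[hi]
        i_lo = idx[lo]
        i_hi = idx[hi]
        v_lo = dir_vals[lo]
        v_hi = dir_vals[hi]
        # unknown-unknown faces
        m = u_lo & u_hi & (w > 0)
        rows.append(i_lo[m])
        cols.append(i_hi[m])
        vals.append(-w[m])
        rows.append(i_hi[m])
        cols.append(i_lo[m])
        vals.append(-w[m])
        np.add.at(diag, i_lo[m], w[m])
        np.add.at(diag, i_hi[m], w[m])
        # unknown-Dirichlet faces
        m = u_lo & d_hi & (w > 0)
        np.add.at(diag, i_lo[m], w[m])
        np.add.at(rhs0, i_lo[m], w[m] * v_hi[m])
        m = u_hi & d_lo & (w > 0)
        np.add.at(diag, i_hi[m], w[m])
        np.add.at(rhs0, i_hi[m], w[m] * v_lo[m])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    lap = sparse.csr_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n_un)]),
          np.concatenate([cols, np.arange(n_un)]))),
        shape=(n_un, n_un))

    in_colony = labels[unknown] == COLONY
    sink_scale = params.rho0 * params.lambda_S / params.Y  # g/(um^3 h) at C>>Ks

    if C0 is None:
        C_un = np.full(n_un, Cs)
    else:
        C_un = np.clip(C0[unknown], 0.0, Cs)

    clamped = False
    it = 0
    delta = np.inf
    for it in range(1, params.max_picard + 1):
        s_coef = np.zeros(n_un)
        s_coef[in_colony] = sink_scale / (C_un[in_colony] + Ks)
        A = lap + sparse.diags(s_coef)
        d = A.diagonal()
        Minv = sparse.diags(1.0 / np.where(d > 0, d, 1.0))
        C_new, info = cg(A, rhs0, x0=C_un, M=Minv,
                         rtol=1e-12, atol=tol * 1e-3, maxiter=20000)
        if info != 0:
            raise RuntimeError(
                f"nutrient CG failed to converge (info={info}, "
                f"picard iteration {it})")
        if np.any(C_new < 0):
            C_new = np.maximum(C_new, 0.0)
            clamped = True
        delta = float(np.max(np.abs(C_new - C_un)))
        C_un = C_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"nutrient solver: Picard not converged after {params.max_picard}"
            f" sweeps (residual {delta:.3e}, tol {tol:.3e})")

    C = np.zeros(g.shape)
    C[unknown] = C_un
    C[dir_mask] = dir_vals[dir_mask]
    # fill air voxels column-wise from the topmost solid voxel below, so
    # trilinear sampling near the colony surface never mixes in zeros
    _fill_air_columns(C, solid)
    return NutrientField(g, C, labels, params,
                         picard_iterations=it, residual=delta,
                         clamped_negative=clamped)


def _fill_air_columns(C: np.ndarray, solid: np.ndarray) -> None:
    nz = C.shape[2]
    fill = np.zeros(C.shape[:2])
    for k in range(nz):
        s = solid[:, :, k]
        fill = np.where(s, C[:, :, k], fill)
        C[:, :, k] = np.where(s, C[:, :, k], fill)


def conservation_residual(field: NutrientField) -> Tuple[float, float]:
    """Global balance check: (total Monod consumption, net Dirichlet influx),
    both in g/h.  Equal at convergence (discrete divergence theorem)."""
    p = field.params
    g = field.grid
    colony = field.labels == COLONY
    lam = p.lambda_S * field.C / (field.C + p.K_S_mass)
    consumption = float(np.sum(lam[colony]) * p.rho0 / p.Y * g.voxel_volume)

    D = np.zeros(g.shape)
    D[field.labels == AGAR] = p.D_minus_h
    D[field.labels == COLONY] = p.D_plus_h
    Cs = p.C_s_mass
    influx = 0.0
    zneg = g.z < 0
    area = g.spacing  # per-face area / spacing = spacing^2/spacing
    for (wall, inner) in (((0, slice(None)), (1, slice(None))),
                          ((-1, slice(None)), (-2, slice(None)))):
        for orient in ("x", "y"):
            if orient == "x":
                Dw = D[wall[0], :, :][:, zneg]
                Cw = field.C[wall[0], :, :][:, zneg]
                Di = D[inner[0], :, :][:, zneg]
                Ci = field.C[inner[0], :, :][:, zneg]
            else:
                Dw = D[:, wall[0], :][:, zneg]
                Cw = field.C[:, wall[0], :][:, zneg]
                Di = D[:, inner[0], :][:, zneg]
                Ci = field.C[:, inner[0], :][:, zneg]
            s = Dw + Di
            w = np.where(s > 0, 2 * Dw * Di / np.where(s > 0, s, 1), 0)
            influx += float(np.sum(w * (Cw - Ci)) * area)
    return consumption, influx


def sample_concentration(field: NutrientField, point) -> float:
    """Trilinear interpolation of the concentration at a point inside Omega."""
    g = field.grid
    x, y, z = float(point[0]), float(point[1]), float(point[2])
    if not (g.x0 <= x <= g.x0 + g.nx * g.spacing
            and g.y0 <= y <= g.y0 + g.ny * g.spacing
            and g.z0 <= z <= g.z0 + g.nz * g.spacing):
        raise ValueError(f"point {point} outside the computational box")
    sp = g.spacing
    fx = (x - g.x0) / sp - 0.5
    fy = (y - g.y0) / sp - 0.5
    fz = (z - g.z0) / sp - 0.5
    i0 = int(np.clip(math.floor(fx), 0, g.nx - 2)) if g.nx > 1 else 0
    j0 = int(np.clip(math.floor(fy), 0, g.ny - 2)) if g.ny > 1 else 0
    k0 = int(np.clip(math.floor(fz), 0, g.nz - 2)) if g.nz > 1 else 0
    tx = np.clip(fx - i0, 0.0, 1.0) if g.nx > 1 else 0.0
    ty = np.clip(fy - j0, 0.0, 1.0) if g.ny > 1 else 0.0
    tz = np.clip(fz - k0, 0.0, 1.0) if g.nz > 1 else 0.0
    c = field.C
    i1 = min(i0 + 1, g.nx - 1)
    j1 = min(j0 + 1, g.ny - 1)
    k1 = min(k0 + 1, g.nz - 1)
    v = 0.0
    for (ii, wx) in ((i0, 1 - tx), (i1, tx)):
        for (jj, wy) in ((j0, 1 - ty), (j1, ty)):
            for (kk, wz) in ((k0, 1 - tz), (k1, tz)):
                v += wx * wy * wz * c[ii, jj, kk]
    return max(float(v), 0.0)


def solve_two_level(cells, params: SimulationParams,
                    cycles: int = 2,
                    C0_fine: Optional[NutrientField] = None,
                    ) -> Tuple[NutrientField, NutrientField]:
    """Two-level grid scheme: coarse global solve, then a fine solve on a
    window around the colony with Dirichlet data interpolated from the coarse
    solution; the fine solution is restricted back into the coarse grid and
    the pair is cycled.  Stands in for fully adaptive multi-resolution grids.

    Returns ``(fine_field, coarse_field)``.
    """
    coarse = NutrientGrid(params.L, params.a, params.b, params.coarse_spacing)
    labels_c = classify_regions(cells, coarse, params)
    field_c = solve_steady_nutrient(labels_c, params, coarse)

    if isinstance(cells, tuple):
        r = np.asarray(cells[0], float).reshape(-1, 3)
    else:
        r = np.array([c.r for c in cells], float).reshape(-1, 3)
    if len(r) == 0:
        return field_c, field_c
    sp_f = params.fine_spacing
    sp_c = params.coarse_spacing
    margin = 4 * sp_c
    half = max(abs(r[:, :2]).max() + margin, 4 * sp_c)
    half = math.ceil(half / sp_c) * sp_c
    half = min(half, params.L)
    depth = min(math.ceil((margin + 8.0) / sp_c) * sp_c, params.a)
    top = r[:, 2].max() + margin
    top = min(math.ceil(top / sp_c) * sp_c, params.b)
    fine = NutrientGrid(half, depth, top, sp_f)
    labels_f = classify_regions(cells, fine, params)

    # fine-window boundary voxels pinned to the coarse solution
    bmask = np.zeros(fine.shape, dtype=bool)
    bmask[0, :, :] = True
    bmask[-1, :, :] = True
    bmask[:, 0, :] = True
    bmask[:, -1, :] = True
    bmask[:, :, 0] = True
    # top boundary (z = top) stays no-flux unless it touches coarse air: pin
    # it too for consistency with the global field
    bmask[:, :, -1] = True

    field_f = C0_fine
    for _ in range(max(cycles, 1)):
        bvals = np.zeros(fine.shape)
        bi, bj, bk = np.nonzero(bmask)
        pts = np.stack([fine.x[bi], fine.y[bj], fine.z[bk]], axis=1)
        for m, pt in zip(range(len(bi)), pts):
            bvals[bi[m], bj[m], bk[m]] = sample_concentration(field_c, pt)
        C0 = field_f.C if field_f is not None else None
        field_f = solve_steady_nutrient(labels_f, params, fine, C0=C0,
                                        extra_dirichlet=(bmask, bvals))
        # restrict the fine solution into the coarse field over the window
        field_c = _restrict_into_coarse(field_f, field_c)
    return field_f, field_c


def _restrict_into_coarse(fine: NutrientField,
                          coarse: NutrientField) -> NutrientField:
    gf, gc = fine.grid, coarse.grid
    ratio = int(round(gc.spacing / gf.spacing))
    C = coarse.C.copy()
    for i in range(gc.nx):
        x = gc.x[i]
        if not (gf.x0 + gf.spacing <= x <= gf.x0 + (gf.nx - 1) * gf.spacing):
            continue
        for j in range(gc.ny):
            y = gc.y[j]
            if not (gf.y0 + gf.spacing <= y <= gf.y0 + (gf.ny - 1) * gf.spacing):
                continue
            for k in range(gc.nz):
                z = gc.z[k]
                if not (gf.z0 + gf.spacing <= z <= gf.z0 + (gf.nz - 1) * gf.spacing):
                    continue
                if coarse.labels[i, j, k] != AIR:
                    C[i, j, k] = sample_concentration(fine, (x, y, z))
    out = NutrientField(gc, C, coarse.labels, coarse.params,
                        picard_iterations=coarse.picard_iterations,
                        residual=coarse.residual)
    return out
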