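"""Deterministic synthetic fixtures with embedded ground truth.

Each fixture builds a snapshot/trajectory/image whose observables are known
by construction, so every analysis operation can be exercised without
running a simulation and without any external data.  Ring-based colonies
place at least two cells per azimuthal sector at the exact layer radius, so
sector-envelope radii are recovered exactly; the trajectory fixture caps the
colony with a flat patch so the smoothed height field at the centroid equals
the programmed height exactly.

``generate_fixture(name, ...)`` writes files plus a YAML sidecar listing the
ground-truth values; the ``make_*`` functions return in-memory objects.
"""

from __future__ import annotations

import math
import pathlib
from typing import Dict, Tuple

import numpy as np
import yaml

from .engine import Snapshot, Trajectory
from .model_core import SimulationParams

__all__ = [
    "FIXTURE_NAMES",
    "make_monolayer_disk", "make_cone_colony", "make_linear_trajectory",
    "make_stencil_disk_annulus", "make_vertical_rod_lattice",
    "generate_fixture",
]

FIXTURE_NAMES = ("monolayer_disk", "cone_colony", "linear_trajectory",
                 "stencil_disk_annulus", "vertical_rod_lattice")


def _snapshot_from_arrays(t, r, n, l, v=None, w0=1.0) -> Snapshot:
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    l = np.asarray(l, float)
    N = len(l)
    if v is None:
        v = np.zeros((N, 3))
    return Snapshot(t=t, ids=np.arange(N), r=r, n=n, l=l,
                    v=np.asarray(v, float), omega=np.zeros((N, 3)),
                    t_birth=np.zeros(N), lambda_local=np.zeros(N),
                    pressure=np.zeros(N), w0=w0)


def _ring(radius: float, n_min: int, z: float, l: float,
          rng: np.random.Generator, w0: float,
          tangential: bool = True):
    """Cells evenly spaced on a circle, directors tangential (horizontal)."""
    n_cells = max(n_min, int(math.ceil(2 * math.pi * radius / (l + w0))))
    ang = np.arange(n_cells) / n_cells * 2 * math.pi
    r = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                  np.full(n_cells, z)], axis=1)
    if tangential:
        n = np.stack([-np.sin(ang), np.cos(ang), np.zeros(n_cells)], axis=1)
    else:
        n = np.stack([np.cos(ang), np.sin(ang), np.zeros(n_cells)], axis=1)
    return r, n, np.full(n_cells, l)


def _disk_fill(radius: float, z: float, l: float, w0: float,
               rng: np.random.Generator, spacing: float = 2.4):
    """Loose interior fill of lying cells with random azimuthal directors."""
    xs = np.arange(-radius, radius + spacing / 2, spacing)
    pts = []
    for x in xs:
        for y in xs:
            if math.hypot(x, y) <= radius:
                pts.append((x, y, z))
    if not pts:
        pts = [(0.0, 0.0, z)]
    r = np.array(pts)
    # exactly centered so sector radii measured about the colony centroid
    # recover the construction radii without bias
    r[:, :2] -= r[:, :2].mean(axis=0)
    ang = rng.uniform(0, 2 * math.pi, len(pts))
    n = np.stack([np.cos(ang), np.sin(ang), np.zeros(len(pts))], axis=1)
    return r, n, np.full(len(pts), l)


def make_monolayer_disk(R: float = 30.0, seed: int = 0, w0: float = 1.0,
                        l: float = 2.0) -> Tuple[Snapshot, Dict]:
    """A single layer of lying cells in a disk; bottom-layer radius exactly R."""
    rng = np.random.default_rng(seed)
    z = 0.5 * w0
    r1, n1, l1 = _ring(R - 0.5 * w0, 72, z, l, rng, w0)
    r2, n2, l2 = _disk_fill(R - 2.0, z, l, w0, rng)
    snap = _snapshot_from_arrays(0.0, np.vstack([r1, r2]),
                                 np.vstack([n1, n2]),
                                 np.concatenate([l1, l2]), w0=w0)
    truth = {"R": float(R), "r1": float(R), "n_layers": 1}
    return snap, truth


def make_cone_colony(R: float = 60.0, H: float = 20.0, seed: int = 0,
                     w0: float = 1.0, l: float = 2.0) -> Tuple[Snapshot, Dict]:
    """A conic colony built layer by layer: layer k (center z = (k-1/2) w0)
    is a ring at radius R (1 - (k-1) w0 / H), so the layer radii and the
    annulus width Wb = r1 - r2 are known exactly."""
    rng = np.random.default_rng(seed)
    rs = []
    ns = []
    ls = []
    layer_radii = []
    k = 1
    while True:
        z = (k - 0.5) * w0
        rad = R * (1.0 - (k - 1) * w0 / H)
        if rad < 3.0 or z > H:
            break
        layer_radii.append(rad)
        rr, nn, ll = _ring(rad - 0.5 * w0, 72, z, l, rng, w0)
        rs.append(rr)
        ns.append(nn)
        ls.append(ll)
        fr, fn, fl = _disk_fill(rad - 2.0, z, l, w0, rng, spacing=4.0)
        rs.append(fr)
        ns.append(fn)
        ls.append(fl)
        k += 1
    snap = _snapshot_from_arrays(0.0, np.vstack(rs), np.vstack(ns),
                                 np.concatenate(ls), w0=w0)
    truth = {
        "R": float(R), "H_nominal": float(H),
        "r1": float(layer_radii[0]),
        "r2": float(layer_radii[1]) if len(layer_radii) > 1 else None,
        "Wb": float(layer_radii[0] - layer_radii[1])
        if len(layer_radii) > 1 else None,
        "n_layers": len(layer_radii),
    }
    return snap, truth


def _flat_cap(z_top: float, w0: float, half_extent: float = 2.5):
    """A 5x5 um patch of short cells whose tops all sit at exactly z_top, so
    the 3x3-smoothed height field at the center equals z_top."""
    xs = np.arange(-half_extent, half_extent + 0.1, 1.0)
    pts = [(x, y, z_top - 0.5 * w0) for x in xs for y in xs]
    r = np.array(pts)
    n = np.tile([1.0, 0.0, 0.0], (len(pts), 1))
    return r, n, np.zeros(len(pts))


def make_linear_trajectory(VR: float = 18.0, VH: float = 6.0,
                           R0: float = 30.0, H0: float = 10.0,
                           t_max: float = 2.0, dt_snap: float = 0.25,
                           Wb: float = 8.0, seed: int = 0,
                           w0: float = 1.0) -> Tuple[Trajectory, Dict]:
    """A synthetic trajectory with exactly linear R(t) = R0 + VR t and
    H(t) = H0 + VH t, constant annulus width Wb, and a rigid-body radial
    velocity field v = VR * r_hat in the bottom layer."""
    rng = np.random.default_rng(seed)
    params = SimulationParams(seed=seed)
    traj = Trajectory(params)
    times = np.arange(0.0, t_max + dt_snap / 2, dt_snap)
    for t in times:
        R = R0 + VR * t
        H = H0 + VH * t
        rs = []
        ns = []
        ls = []
        vs = []
        # bottom layer ring + fill, radial velocity VR * r_hat
        rr, nn, ll = _ring(R - 0.5 * w0, 72, 0.5 * w0, 2.0, rng, w0)
        rs.append(rr)
        ns.append(nn)
        ls.append(ll)
        rad = np.hypot(rr[:, 0], rr[:, 1])
        vs.append(VR * rr[:, :2] / rad[:, None])
        fr, fn, fl = _disk_fill(R - 3.0, 0.5 * w0, 2.0, w0, rng, spacing=5.0)
        rs.append(fr)
        ns.append(fn)
        ls.append(fl)
        frad = np.hypot(fr[:, 0], fr[:, 1])
        fv = np.where(frad[:, None] > 1e-9, VR * fr[:, :2]
                      / np.maximum(frad[:, None], 1e-9), 0.0)
        vs.append(fv)
        # second layer ring at R - Wb
        rr2, nn2, ll2 = _ring(R - Wb - 0.5 * w0, 72, 1.5 * w0, 2.0, rng, w0)
        rs.append(rr2)
        ns.append(nn2)
        ls.append(ll2)
        vs.append(np.zeros((len(ll2), 2)))
        # flat cap setting the centroid height exactly
        cr, cn, cl = _flat_cap(H, w0)
        rs.append(cr)
        ns.append(cn)
        ls.append(cl)
        vs.append(np.zeros((len(cl), 2)))
        r = np.vstack(rs)
        n = np.vstack(ns)
        l = np.concatenate(ls)
        v2 = np.vstack(vs)
        v = np.column_stack([v2, np.zeros(len(l))])
        traj.snapshots.append(_snapshot_from_arrays(float(t), r, n, l, v, w0))
    truth = {"VR": float(VR), "VH": float(VH), "R0": float(R0),
             "H0": float(H0), "Wb": float(Wb)}
    return traj, truth


def make_stencil_disk_annulus(disk_radius_px: int = 12,
                              ring_radius_px: int = 20,
                              size_px: int = 48,
                              bright: float = 200.0,
                              threshold: float = 100.0,
                              um_per_px: float = 0.84
                              ) -> Tuple[np.ndarray, Dict]:
    """A bright disk (multi-layer core) plus a one-pixel bright circle (dim
    single-layer annulus): disk-interior stencils count >= 16 neighbors,
    pixels on/near the thin circle count 3..15."""
    c = size_px / 2.0 - 0.5
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    rad = np.hypot(xx - c, yy - c)
    img = np.zeros((size_px, size_px))
    img[rad <= disk_radius_px] = bright
    ring = np.abs(rad - ring_radius_px) <= 0.5
    img[ring] = bright
    truth = {"disk_radius_px": int(disk_radius_px),
             "ring_radius_px": int(ring_radius_px),
             "threshold": float(threshold),
             "um_per_px": float(um_per_px)}
    return img, truth


def make_vertical_rod_lattice(nx: int = 6, ny: int = 6,
                              spacing: float = 2.0, l: float = 2.0,
                              w0: float = 1.0) -> Tuple[Snapshot, Dict]:
    """A rectangular lattice of perfectly vertical cells (directors = z)."""
    pts = [(i * spacing + spacing / 2, j * spacing + spacing / 2,
            0.5 * l + 0.5 * w0)
           for i in range(nx) for j in range(ny)]
    r = np.array(pts)
    n = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    snap = _snapshot_from_arrays(0.0, r, n, np.full(len(pts), l), w0=w0)
    truth = {"nx": nx, "ny": ny, "spacing": float(spacing), "l": float(l),
             "w0": float(w0)}
    return snap, truth


def generate_fixture(name: str, out_dir, seed: int = 0, **kwargs):
    """Write the named fixture plus a ``sidecar.yaml`` with its ground truth.

    Same name and seed produce byte-identical output.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "monolayer_disk":
        snap, truth = make_monolayer_disk(seed=seed, **kwargs)
        snap.to_dataframe().to_csv(out / "snapshot.csv", index=False)
    elif name == "cone_colony":
        snap, truth = make_cone_colony(seed=seed, **kwargs)
        snap.to_dataframe().to_csv(out / "snapshot.csv", index=False)
    elif name == "linear_trajectory":
        traj, truth = make_linear_trajectory(seed=seed, **kwargs)
        traj.save(out)
    elif name == "stencil_disk_annulus":
        img, truth = make_stencil_disk_annulus(**kwargs)
        np.savetxt(out / "image.csv", img, delimiter=",", fmt="%.1f")
    elif name == "vertical_rod_lattice":
        snap, truth = make_vertical_rod_lattice(**kwargs)
        snap.to_dataframe().to_csv(out / "snapshot.csv", index=False)
    else:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    with open(out / "sidecar.yaml", "w") as fh:
        yaml.safe_dump({"fixture": name, "seed": seed, "truth": truth}, fh,
                       sort_keys=False)
    return truth
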