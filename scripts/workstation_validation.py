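#!/usr/bin/env python
"""Workstation-scale validation runs (hours of compute; not part of CI).

Two studies on the full model:

1. A standard-parameter run to t = 20 h, reporting the linear-regime radial
   and vertical expansion speeds VR and VH, the growth-zone thickness HS,
   the buckling width Wb, the interior packing density, and the radius at
   which half the interior cells stand vertical.

2. A growth-rate sweep (lambda_S in {0.25, 0.5, 0.75, 1.0} / h) fitting
   VH(lambda_S) = a sqrt(lambda_S) + b  and  VR(lambda_S) = c lambda_S + d,
   plus the same sweep with the static-friction-only cell-agar force (the
   dynamic cap disabled via a very large mu_ca) to expose the
   dynamic-vs-static discrimination (linear vs sublinear VR).

Usage: python scripts/workstation_validation.py --seed 1 --out scratch/ws
"""

import argparse
import json
import math
import pathlib

import numpy as np

from agarcolony import SimulationParams, engine
from agarcolony.analysis import (
    colony_observables, coarse_grain, growth_zone_and_verticalization,
)


def standard_params(seed: int, **kw) -> SimulationParams:
    defaults = dict(L=400.0, a=120.0, b=80.0, uniform_spacing=4.0,
                    grid_mode="uniform", seed=seed)
    defaults.update(kw)
    return SimulationParams(**defaults)


def full_run(seed: int, out: pathlib.Path) -> dict:
    p = standard_params(seed)
    traj = engine.run(p, t_max=20.0, snapshot_interval=0.5,
                      out_dir=out / "standard_run",
                      log_fn=lambda m: print(m, flush=True))
    obs = colony_observables(traj, fit_window=(12.0, 20.0))
    snap = traj.snapshots[-1]

    # interior packing density (bottom half of the colony, inner 60%)
    cf = coarse_grain(snap, box=4.0, rho_cell=p.rho_cell)
    dens = cf.density[cf.mask]
    interior_density_frac = float(np.median(dens) / p.rho_cell)

    # growth zone from the final nutrient field
    from agarcolony.nutrient_solver import (
        NutrientGrid, classify_regions, solve_steady_nutrient)
    grid = NutrientGrid(p.L, p.a, p.b, p.uniform_spacing)
    labels = classify_regions((snap.r, snap.l), grid, p)
    field = solve_steady_nutrient(labels, p, grid)
    HS, vert_profile, _ = growth_zone_and_verticalization(snap, field)
    half = vert_profile[vert_profile["vertical_fraction"] >= 0.5]
    r_half_vertical = float(half["radius"].max()) if len(half) else math.nan

    return {
        "VR_um_per_h": obs.VR,
        "VH_um_per_h": obs.VH,
        "HS_um": HS,
        "Wb_um": obs.Wb,
        "interior_density_over_rho_cell": interior_density_frac,
        "r_half_vertical_um": r_half_vertical,
        "t_buckle_h": obs.t_buckle,
        "n_cells_final": snap.n_cells,
    }


def rate_sweep(seed: int, static_friction: bool) -> dict:
    lams = (0.25, 0.5, 0.75, 1.0)
    VR = []
    VH = []
    for lam in lams:
        kw = {}
        if static_friction:
            # disable the dynamic cap: the static (viscous) branch alone
            kw["mu_ca"] = 1e9
        p = standard_params(seed, lambda_S=lam, **kw)
        traj = engine.run(p, t_max=20.0, snapshot_interval=0.5,
                          log_fn=lambda m: print(m, flush=True))
        obs = colony_observables(traj, fit_window=(12.0, 20.0))
        VR.append(obs.VR)
        VH.append(obs.VH)
    lams = np.array(lams)
    VH_fit = np.polyfit(np.sqrt(lams), VH, 1)       # VH = a sqrt(lam) + b
    VR_fit = np.polyfit(lams, VR, 1)                # VR = c lam + d
    return {
        "lambda_S": list(lams),
        "VR": VR,
        "VH": VH,
        "VH_sqrt_fit_a_b": [float(VH_fit[0]), float(VH_fit[1])],
        "VR_linear_fit_c_d": [float(VR_fit[0]), float(VR_fit[1])],
    }


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("scratch/ws"))
    ap.add_argument("--skip-sweep", action="store_true")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    results = {"standard_run": full_run(args.seed, args.out)}
    if not args.skip_sweep:
        results["sweep_dynamic_friction"] = rate_sweep(args.seed, False)
        results["sweep_static_friction"] = rate_sweep(args.seed, True)
    with open(args.out / "workstation_validation.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(json.dumps(results, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
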