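"""Cell growth-rate readout, elongation, and division.

Growth follows Monod kinetics on the local nutrient concentration,
``lambda = lambda_S * C / (C + K_S)``; cells elongate exponentially in their
cylinder length at rate ``sigma * lambda`` and divide at the critical
cylinder length ``l_div`` into two daughters whose outer cap centers coincide
with the mother's cap centers.

The elongation factor sigma converts mass growth into cylinder-length growth.
Because the hemispherical caps contribute an l-independent volume, a cell's
length must grow *faster* than its mass to complete a division cycle on the
mass-doubling clock.  The default,

    sigma = ln(l_div / l0) / ln 2,

makes the steady-state division cycle time exactly ``ln 2 / lambda``, so the
population count and total biomass both grow at exactly the Monod rate
``lambda`` - the property the nutrient sink term ``rho lambda / Y`` assumes.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .model_core import Cell, SimulationParams

__all__ = [
    "local_growth_rate",
    "elongate",
    "divide",
    "division_length",
]


def local_growth_rate(C, params: SimulationParams, mass_units: bool = False):
    """Monod growth rate ``lambda_S * C / (C + K_S)`` (1/h).

    ``C`` is in uM by default (the units of ``K_S``); pass
    ``mass_units=True`` for g/um^3 (the nutrient solver's internal units).
    Monotone increasing and saturating; lambda(K_S) = lambda_S / 2.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("negative nutrient concentration")
    K = params.K_S_mass if mass_units else params.K_S
    lam = params.lambda_S * C / (C + K)
    return float(lam) if lam.ndim == 0 else lam


def elongate(cell: Cell, lam: float, dt: float,
             params: SimulationParams) -> Cell:
    """Exact exponential length update ``l <- l * exp(sigma lambda dt)``.

    ``lam`` is the cell's mass growth rate; growth changes only the cylinder
    length - position and director are untouched.  Modifies the cell in
    place and returns it.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cell.l *= math.exp(params.sigma * lam * dt)
    return cell


def elongation_rate(lam: float, params: SimulationParams) -> float:
    """Cylinder-length growth rate sigma * lambda (1/h)."""
    return params.sigma * lam


def division_length(lambda_S: float, params: SimulationParams) -> float:
    """Division cylinder length l_div.

    ``fixed`` mode returns the configured constant (default 3 um).  The
    ``growth_rate`` mode follows the exponential cell-size law
    ``l_div(lambda_S) = l_div(1) * exp(alpha (lambda_S - 1))`` - monotone
    increasing in the growth rate and normalized to the fixed value at
    lambda_S = 1/h - standing in for the established growth-rate dependence
    of E. coli cell size.
    """
    if lambda_S <= 0:
        raise ValueError("lambda_S must be positive")
    if params.ldiv_mode == "fixed":
        return params.l_div
    return params.l_div * math.exp(params.ldiv_alpha * (lambda_S - 1.0))


def divide(cell: Cell, rng: np.random.Generator,
           params: SimulationParams, new_id: int,
           t: float = 0.0) -> Tuple[Cell, Cell]:
    """Split a cell of length >= l_div into two daughters.

    The mother's cap centers become the daughters' *outer* cap centers, so
    with zero noise and l0 = (l_div - w0)/2 the daughters' footprints exactly
    tile the mother's.  Daughter lengths are anti-correlated,
    ``l_A = l0 (1 + u)`` and ``l_B = l0 (1 - u)`` with u uniform in
    [-div_noise, div_noise], so the pair always tiles the mother exactly and
    is never born overlapping; directors get independent small angular
    perturbations (uniform in a cone of div_angle_noise_deg); angular
    velocities receive random kicks; both daughters inherit the mother's
    velocity.  Draw order: u, 3 for A's director, 3 for B's director,
    3 for A's omega kick, 3 for B's omega kick.
    """
    l_div = params.division_length()
    if cell.l < l_div:
        raise ValueError(
            f"divide() called with l={cell.l:.4f} < l_div={l_div:.4f}")
    p = cell.p
    q = cell.q
    u = rng.uniform(-params.div_noise, params.div_noise)
    lA = params.l0 * (1.0 + u)
    lB = params.l0 * (1.0 - u)
    eps = math.tan(math.radians(params.div_angle_noise_deg))
    nA = cell.n + rng.uniform(-eps, eps, 3)
    nA /= np.linalg.norm(nA)
    nB = cell.n + rng.uniform(-eps, eps, 3)
    nB /= np.linalg.norm(nB)
    kickA = rng.uniform(-params.omega_kick, params.omega_kick, 3)
    kickB = rng.uniform(-params.omega_kick, params.omega_kick, 3)
    # daughter A keeps the mother's p cap, B keeps the q cap
    rA = p - 0.5 * lA * cell.n
    rB = q + 0.5 * lB * cell.n
    A = Cell(id=cell.id, r=rA, n=nA, l=lA, v=cell.v.copy(),
             omega=cell.omega + kickA, M=cell.M, I=cell.I,
             t_birth=t, lambda_local=cell.lambda_local)
    B = Cell(id=new_id, r=rB, n=nB, l=lB, v=cell.v.copy(),
             omega=cell.omega + kickB, M=cell.M, I=cell.I,
             t_birth=t, lambda_local=cell.lambda_local)
    return A, B
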