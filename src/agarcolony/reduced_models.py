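"""Closed-form / 1D reductions used by the quantitative analysis.

Two reductions capture the two expansion speeds:

* Vertical nutrient penetration.  On the colony axis the steady
  concentration obeys the 1D boundary-value problem

      D+ C''(z) = rho0 * lambda_S * C / ((C + K_S) * Y),   0 < z < H,

  with C(0) = C_bottom and no flux at the top.  The profile drops
  quadratically near the agar (constant-sink regime, C >> K_S) and
  exponentially higher up (linear regime, C << K_S) with decay length
  ``ell = sqrt(Y D+ K_S / (rho0 lambda_S))``; the crossover height HS where
  C = K_S is the growth-zone thickness, and the vertical ascension speed
  scales as VH ~ HS * lambda_S ~ sqrt(lambda_S).  Rescaling z by
  sqrt(lambda_S) removes lambda_S from the equation, so profiles for
  different growth rates collapse onto one curve.

* Monolayer mass conservation.  In the peripheral monolayer annulus the
  growth rate is ~lambda_S and mass conservation div(V) = lambda gives the
  linear radial-velocity law Vr(dr) = VR + lambda_S * dr with
  VR = lambda_S * Wb, where Wb is the buckling width of the annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_bvp

from .model_core import SimulationParams

__all__ = [
    "VerticalProfile",
    "decay_length",
    "solve_vertical_profile",
    "predict_VH",
    "monolayer_radial_velocity",
]

# Calibration constant of the VH estimate (VH = kappa * HS * lambda_S),
# fixed once against a full standard-parameter simulation and then frozen.
KAPPA_VH = 0.6


@dataclass
class VerticalProfile:
    """Steady on-axis nutrient profile and its derived scales."""

    z: np.ndarray                 # heights (um), 0..H
    C: np.ndarray                 # concentration (g/um^3)
    HS: float                     # crossover height where C = K_S (um)
    ell: float                    # asymptotic decay length (um)
    degenerate: bool = False      # C_bottom <= K_S (HS = 0)

    def interp(self, z) -> np.ndarray:
        return np.interp(z, self.z, self.C)


def decay_length(params: SimulationParams,
                 lambda_S: Optional[float] = None) -> float:
    """Deep-colony exponential decay length ell = sqrt(Y D+ K_S / (rho0 lam))."""
    lam = params.lambda_S if lambda_S is None else lambda_S
    return math.sqrt(params.Y * params.D_plus_h * params.K_S_mass
                     / (params.rho0 * lam))


def solve_vertical_profile(params: SimulationParams, H: float,
                           C_bottom: Optional[float] = None,
                           lambda_S: Optional[float] = None,
                           n_grid: int = 400) -> VerticalProfile:
    """Solve the steady 1D nutrient BVP on (0, H).

    ``C_bottom`` is in internal mass units (g/um^3); by default a configured
    fraction (0.3) of C_s, standing in for the 3D solver's on-axis value at
    z = 0+.  Boundary conditions: C(0) = C_bottom, no flux at z = H.
    Raises RuntimeError on non-convergence.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    lam = params.lambda_S if lambda_S is None else lambda_S
    if C_bottom is None:
        C_bottom = 0.3 * params.C_s_mass
    if C_bottom <= 0:
        raise ValueError("C_bottom must be positive")
    Ks = params.K_S_mass
    ell = decay_length(params, lam)
    if C_bottom <= Ks:
        z = np.linspace(0.0, H, n_grid)
        # fully nutrient-starved column: linear-regime exponential decay
        C = C_bottom * np.exp(-z / ell)
        return VerticalProfile(z=z, C=C, HS=0.0, ell=ell, degenerate=True)

    # nondimensionalize (u = C/K_S, zeta = z/ell): u'' = u/(1+u), which is
    # well conditioned regardless of the tiny absolute concentration scale
    u_b = C_bottom / Ks
    zeta_max = H / ell

    def rhs(zeta, y):
        u = np.maximum(y[0], 0.0)
        return np.vstack([y[1], u / (1.0 + u)])

    def bc(ya, yb):
        return np.array([ya[0] - u_b, yb[1]])

    zeta = np.linspace(0.0, zeta_max, n_grid)
    # initial guess: saturated-sink parabola clipped at a small floor
    guess = np.maximum(u_b * (1.0 - zeta / max(math.sqrt(2 * u_b), 1.0)) ** 2,
                       1e-4)
    y0 = np.vstack([guess, np.gradient(guess, zeta)])
    sol = solve_bvp(rhs, bc, zeta, y0, tol=1e-10, max_nodes=200000)
    if not sol.success:
        raise RuntimeError(f"vertical-profile BVP failed: {sol.message}")
    zz = np.linspace(0.0, H, n_grid)
    C = np.maximum(sol.sol(zz / ell)[0], 0.0) * Ks

    # HS: first crossing C = K_S, linearly interpolated
    below = np.where(C <= Ks)[0]
    if len(below):
        k = below[0]
        if k == 0:
            HS = 0.0
        else:
            z0, z1 = zz[k - 1], zz[k]
            c0, c1 = C[k - 1], C[k]
            HS = float(z0 + (c0 - Ks) / (c0 - c1) * (z1 - z0))
    else:
        HS = float(H)
    return VerticalProfile(z=zz, C=C, HS=HS, ell=ell)


def predict_VH(params: SimulationParams,
               lambda_S: Optional[float] = None,
               H: float = 40.0,
               C_bottom: Optional[float] = None,
               kappa: float = KAPPA_VH) -> float:
    """Vertical ascension speed estimate VH = kappa * HS * lambda_S (um/h).

    With HS ~ 1/sqrt(lambda_S) from the profile collapse, the estimate
    follows the square-root law VH ~ sqrt(lambda_S).
    """
    lam = params.lambda_S if lambda_S is None else lambda_S
    if lam == 0:
        return 0.0
    prof = solve_vertical_profile(params, H, C_bottom=C_bottom, lambda_S=lam)
    return kappa * prof.HS * lam


def monolayer_radial_velocity(lambda_S: float, Wb: float,
                              dr: np.ndarray) -> np.ndarray:
    """Monolayer radial-velocity law Vr(dr) = lambda_S * (Wb + dr).

    ``dr`` is the signed distance from the colony edge (negative inside);
    the law is clipped at zero for dr <= -Wb (inner edge of the annulus).
    VR = Vr(0) = lambda_S * Wb.
    """
    if Wb <= 0:
        raise ValueError("Wb must be positive")
    dr = np.asarray(dr, dtype=float)
    return np.maximum(lambda_S * (Wb + dr), 0.0)
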