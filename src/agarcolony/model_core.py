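"""Domain types, parameter registry, and spherocylinder geometry primitives.

Internal unit system
--------------------
length   : micrometres (um)
time     : hours (h)
biomass  : grams of cell dry weight (gCDW)
force    : units of ``gamma_surf * w0`` -- the saturated cell-level
           surface-tension force is ``pi`` in these units, so per-cell
           pressures come out natively in units of ``P0 = gamma_surf / w0``.

Published parameter values given in seconds / uM / mM (diffusivities, Monod
constant, boundary nutrient concentration) are converted to the internal
system when a :class:`SimulationParams` is constructed; nutrient
concentrations are carried internally as mass concentrations (g/um^3), which
is what the consumption sink ``rho * lambda / Y`` requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import yaml
from numba import njit

__all__ = [
    "SimulationParams",
    "Cell",
    "Contact",
    "segment_min_distance",
    "cell_geometry",
    "cell_volume",
    "spherocylinder_volume",
]

# conversion helpers ---------------------------------------------------------

SECONDS_PER_HOUR = 3600.0
LITER_IN_UM3 = 1.0e15


def molar_to_mass_conc(conc_molar: float, molar_mass: float) -> float:
    """mol/L -> g/um^3."""
    return conc_molar * molar_mass / LITER_IN_UM3


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

# YAML section layout: section name -> tuple of field names
_SECTIONS = {
    "growth": (
        "lambda_S", "K_S", "C_s", "Y", "molar_mass", "sigma", "l0", "l_div",
        "ldiv_mode", "ldiv_alpha", "div_noise", "div_angle_noise_deg",
        "omega_kick",
    ),
    "geometry": ("w0", "rho_cell", "rho0_frac"),
    "mechanics": (
        "E_cell", "gamma_n", "gamma_cc_t", "mu_cc", "mu_ca", "h_ran",
        "gamma_surf", "delta_h", "eta_drag", "eta_rot", "mass", "inertia",
        "rot_drag_on", "agar_normal_dissipation",
    ),
    "nutrient": (
        "D_minus", "D_plus", "rho_threshold_frac", "L", "a", "b",
        "grid_mode", "uniform_spacing", "fine_spacing", "coarse_spacing",
        "solver_tol_frac", "max_picard",
    ),
    "numerics": (
        "dt", "inner_per_outer", "hf_bin", "hf_every", "lambda_readout",
        "max_disp_frac", "seed",
    ),
}


@dataclass
class SimulationParams:
    """All physical and numerical constants of the colony model.

    Defaults follow the published standard parameter set where quoted
    (diffusivities, yield, Monod constant, division length, cell width,
    boundary concentration, dry-mass density, and the standard friction set
    mu_ca=0.8, mu_cc=0.1, gamma_cc_t=1e4 um^-1 h^-1, h_ran=0.1 um).
    Quantities not quoted (surface tension, film thickness, contact modulus,
    dissipation coefficients, fictitious mass/inertia) carry the package's
    own calibrated defaults; see docs/methods.md.
    """

    # growth / physiology  (published units: 1/h, uM, mM, gCDW/g, g/mol)
    lambda_S: float = 1.0          # batch-culture growth rate (1/h)
    K_S: float = 20.0              # Monod constant (uM)
    C_s: float = 0.5               # boundary nutrient concentration (mM)
    Y: float = 0.5                 # yield, gCDW per g substrate
    molar_mass: float = 180.0      # substrate molar mass (g/mol, glucose)
    sigma: Optional[float] = None  # elongation factor; None -> ln(l_div/l0)/ln2
    l0: Optional[float] = None     # newborn cylinder length (um); None -> (l_div-w0)/2
    l_div: float = 3.0             # division cylinder length (um)
    ldiv_mode: str = "fixed"       # "fixed" | "growth_rate"
    ldiv_alpha: float = math.log(2.0)  # exponential size-law coefficient
    div_noise: float = 0.05        # daughter length noise amplitude (fraction)
    div_angle_noise_deg: float = 2.0   # daughter director cone half-angle (deg)
    omega_kick: float = 0.05       # angular-velocity kick amplitude (1/h)

    # geometry
    w0: float = 1.0                # cell diameter (um)
    rho_cell: float = 0.137e-12    # cell dry-mass density (g/um^3)
    rho0_frac: float = 0.68        # interior packing fraction (dimensionless)

    # mechanics (force unit = gamma_surf * w0)
    E_cell: float = 900.0          # effective contact modulus (force/um^2)
    gamma_n: float = 2.0           # normal dissipation coefficient
    gamma_cc_t: float = 1.0e4      # tangential dissipation (um^-1 h^-1 force scale)
    mu_cc: float = 0.1             # cell-cell dynamic friction coefficient
    mu_ca: float = 0.8             # cell-agar dynamic friction coefficient
    h_ran: float = 0.1             # agar roughness amplitude (um)
    gamma_surf: float = 1.0        # liquid surface tension (force/um)
    delta_h: float = 0.05          # liquid-film thickness above colony (um)
    eta_drag: float = 0.01         # Stokes drag coefficient (force h/um)
    eta_rot: float = 0.01          # rotational drag coefficient (force um h)
    mass: float = 1.0e-3           # fictitious cell mass (force h^2/um)
    inertia: Optional[float] = None  # fictitious moment of inertia; None -> mass*l_div^2/12
    rot_drag_on: bool = True
    agar_normal_dissipation: bool = True

    # nutrient field (published units: um^2/s for D)
    D_minus: float = 600.0         # diffusivity in agar (um^2/s)
    D_plus: float = 90.0           # diffusivity in colony (um^2/s)
    rho_threshold_frac: float = 0.1   # colony-region density threshold, x rho_cell
    L: float = 500.0               # half box size in x,y (um)
    a: float = 250.0               # agar depth (um)
    b: float = 150.0               # air/colony height (um)
    grid_mode: str = "uniform"     # "uniform" | "two_level"
    uniform_spacing: float = 4.0   # um
    fine_spacing: float = 2.0      # um (two-level mode)
    coarse_spacing: float = 8.0    # um (two-level mode)
    solver_tol_frac: float = 1e-6  # tolerance as fraction of C_s
    max_picard: int = 50

    # numerics
    dt: float = 1e-4               # inner timestep (h)
    inner_per_outer: int = 500     # inner steps per outer loop
    hf_bin: float = 1.0            # height-field bin size (um)
    hf_every: int = 20             # inner steps between height-field rebuilds
    lambda_readout: str = "outer"  # "outer" | "inner"
    max_disp_frac: float = 0.5     # instability guard, fraction of w0 per step
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l0 is None:
            self.l0 = 0.5 * (self.l_div - self.w0)
        if self.sigma is None:
            self.sigma = math.log(self.l_div / self.l0) / math.log(2.0)
        if self.inertia is None:
            self.inertia = self.mass * self.l_div ** 2 / 12.0
        self.validate()

    # -- derived, internal-unit quantities ----------------------------------

    @property
    def D_minus_h(self) -> float:
        """Agar diffusivity in um^2/h."""
        return self.D_minus * SECONDS_PER_HOUR

    @property
    def D_plus_h(self) -> float:
        """Colony diffusivity in um^2/h."""
        return self.D_plus * SECONDS_PER_HOUR

    @property
    def C_s_mass(self) -> float:
        """Boundary concentration in g/um^3 (C_s is in mM)."""
        return molar_to_mass_conc(self.C_s * 1e-3, self.molar_mass)

    @property
    def K_S_mass(self) -> float:
        """Monod constant in g/um^3 (K_S is in uM)."""
        return molar_to_mass_conc(self.K_S * 1e-6, self.molar_mass)

    @property
    def rho0(self) -> float:
        """Constant-density approximation of colony biomass density (g/um^3)."""
        return self.rho0_frac * self.rho_cell

    @property
    def rho_threshold(self) -> float:
        """Colony-region coarse density threshold (g/um^3)."""
        return self.rho_threshold_frac * self.rho_cell

    @property
    def k_n(self) -> float:
        """Hertzian prefactor k_n = (2/3) E* sqrt(w0/2); F = k_n delta^{3/2}."""
        return (2.0 / 3.0) * self.E_cell * math.sqrt(self.w0 / 2.0)

    @property
    def F_surf0(self) -> float:
        """Saturated surface-tension force pi*gamma_surf*w0."""
        return math.pi * self.gamma_surf * self.w0

    @property
    def P0(self) -> float:
        """Pressure unit gamma_surf / w0."""
        return self.gamma_surf / self.w0

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        errors = []
        positive = (
            "lambda_S", "K_S", "C_s", "Y", "molar_mass", "sigma", "l0",
            "l_div", "w0", "rho_cell", "E_cell", "gamma_n", "gamma_cc_t",
            "mu_cc", "mu_ca", "gamma_surf", "eta_drag", "eta_rot", "mass",
            "inertia", "D_minus", "D_plus", "L", "a", "b", "uniform_spacing",
            "fine_spacing", "coarse_spacing", "dt", "hf_bin",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                errors.append(f"{name} must be strictly positive")
        if not 0 < self.rho0_frac <= 1:
            errors.append("rho0_frac must be in (0, 1]")
        if self.h_ran < 0 or self.delta_h < 0:
            errors.append("h_ran and delta_h must be non-negative")
        if not 1 <= self.inner_per_outer:
            errors.append("inner_per_outer must be >= 1")
        if self.l0 >= self.l_div:
            errors.append("l0 must be smaller than l_div")
        if self.ldiv_mode not in ("fixed", "growth_rate"):
            errors.append("ldiv_mode must be 'fixed' or 'growth_rate'")
        if self.grid_mode not in ("uniform", "two_level"):
            errors.append("grid_mode must be 'uniform' or 'two_level'")
        if self.lambda_readout not in ("outer", "inner"):
            errors.append("lambda_readout must be 'outer' or 'inner'")
        if errors:
            raise ValueError(
                "invalid parameters:\n  " + "\n  ".join(errors))

    # -- config file IO -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        """Load a nested key-value config file.  Unknown keys are errors."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParams":
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for section, content in data.items():
            if section not in _SECTIONS:
                raise ValueError(f"unknown config section: {section!r}")
            if content is None:
                continue
            for key, value in content.items():
                if key not in _SECTIONS[section] or key not in known:
                    raise ValueError(
                        f"unknown config key: {section}.{key!r}")
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out: dict = {}
        for section, names in _SECTIONS.items():
            out[section] = {n: getattr(self, n) for n in names}
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_updates(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)

    # -- packing for compiled kernels ----------------------------------------

    def pack(self) -> np.ndarray:
        """Flatten the mechanical/physiological constants into a float64
        vector consumed by the compiled engine kernels (indices ``PV_*``)."""
        v = np.zeros(32)
        v[PV_W0] = self.w0
        v[PV_LDIV] = self.division_length()
        v[PV_L0] = self.l0
        v[PV_SIGMA] = self.sigma
        v[PV_KN] = self.k_n
        v[PV_GAMMA_N] = self.gamma_n
        v[PV_GAMMA_T] = self.gamma_cc_t
        v[PV_MU_CC] = self.mu_cc
        v[PV_MU_CA] = self.mu_ca
        v[PV_HRAN] = self.h_ran
        v[PV_GSURF] = self.gamma_surf
        v[PV_DELTA_H] = self.delta_h
        v[PV_ETA] = self.eta_drag
        v[PV_ETA_ROT] = self.eta_rot if self.rot_drag_on else 0.0
        v[PV_MASS] = self.mass
        v[PV_INERTIA] = self.inertia
        v[PV_DT] = self.dt
        v[PV_DIV_NOISE] = self.div_noise
        v[PV_ANG_NOISE] = math.tan(math.radians(self.div_angle_noise_deg))
        v[PV_OMEGA_KICK] = self.omega_kick
        v[PV_HF_BIN] = self.hf_bin
        v[PV_HF_EVERY] = float(self.hf_every)
        v[PV_MAX_DISP] = self.max_disp_frac * self.w0
        v[PV_LAMBDA_S] = self.lambda_S
        v[PV_KS_MASS] = self.K_S_mass
        v[PV_AGAR_NDISS] = 1.0 if self.agar_normal_dissipation else 0.0
        v[PV_LAM_INNER] = 1.0 if self.lambda_readout == "inner" else 0.0
        return v

    def division_length(self, lambda_S: Optional[float] = None) -> float:
        """Division cylinder length; see :func:`physiology.division_length`."""
        from . import physiology  # local import to avoid a cycle
        lam = self.lambda_S if lambda_S is None else lambda_S
        return physiology.division_length(lam, self)


# packed-vector index constants (keep in sync with pack())
(PV_W0, PV_LDIV, PV_L0, PV_SIGMA, PV_KN, PV_GAMMA_N, PV_GAMMA_T, PV_MU_CC,
 PV_MU_CA, PV_HRAN, PV_GSURF, PV_DELTA_H, PV_ETA, PV_ETA_ROT, PV_MASS,
 PV_INERTIA, PV_DT, PV_DIV_NOISE, PV_ANG_NOISE, PV_OMEGA_KICK, PV_HF_BIN,
 PV_HF_EVERY, PV_MAX_DISP, PV_LAMBDA_S, PV_KS_MASS, PV_AGAR_NDISS,
 PV_LAM_INNER) = range(27)


# ---------------------------------------------------------------------------
# Cells and contacts
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """A spherocylinder agent: cylinder of length ``l`` capped by hemispheres
    of diameter ``w0``, with center ``r`` and unit director ``n``."""

    id: int
    r: np.ndarray                  # center (um)
    n: np.ndarray                  # unit director
    l: float                       # cylinder length (um)
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))
    M: float = 0.05
    I: float = 0.0375
    t_birth: float = 0.0
    lambda_local: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        norm = float(np.linalg.norm(self.n))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("director must be non-zero")
            self.n = self.n / norm
        self.v = np.asarray(self.v, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)

    @property
    def p(self) -> np.ndarray:
        """Cap center r + (l/2) n."""
        return self.r + 0.5 * self.l * self.n

    @property
    def q(self) -> np.ndarray:
        """Cap center r - (l/2) n."""
        return self.r - 0.5 * self.l * self.n

    def volume(self, w0: float = 1.0) -> float:
        return spherocylinder_volume(self.l, w0)

    def footprint_length(self, w0: float = 1.0) -> float:
        return self.l + w0


@dataclass
class Contact:
    """A resolved contact between two bodies (cell-cell or cell-agar)."""

    id_a: int
    id_b: int                      # -1 for the agar substrate
    a: np.ndarray                  # closest point on body A's segment
    a_prime: np.ndarray            # closest point on body B's segment
    delta: float                   # overlap (um), >= 0
    normal: np.ndarray             # unit normal along a - a_prime
    center: np.ndarray             # contact center, midpoint of [a, a_prime]

    @classmethod
    def between_cells(cls, cell_a: Cell, cell_b: Cell, w0: float) -> "Contact":
        d, pa, pb = segment_min_distance(cell_a.p, cell_a.q, cell_b.p, cell_b.q)
        delta = max(0.0, w0 - d)
        if d > 1e-12:
            normal = (pa - pb) / d
        else:
            normal = np.array([0.0, 0.0, 1.0])
        return cls(cell_a.id, cell_b.id, pa, pb, delta, normal,
                   0.5 * (pa + pb))


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


@njit(cache=True)
def spherocylinder_volume(l, w0):
    """Volume (pi w0^2/4) l + (pi/6) w0^3."""
    return math.pi * w0 * w0 * l / 4.0 + math.pi * w0 ** 3 / 6.0


@njit(cache=True)
def _seg_seg(p1x, p1y, p1z, d1x, d1y, d1z, p2x, p2y, p2z, d2x, d2y, d2z):
    """Closest parameters (s, t) in [0,1]^2 between segments P1+s*D1, P2+t*D2.

    Robust clamped quadratic minimization (Eberly's algorithm); handles
    degenerate (zero-length) and parallel segments.
    """
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        return 0.0, 0.0
    if a <= EPS:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
        return s, t
    c = d1x * rx + d1y * ry + d1z * rz
    if e <= EPS:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
        return s, t
    b = d1x * d2x + d1y * d2y + d1z * d2z
    denom = a * e - b * b
    if denom > EPS * a * e:
        s = min(1.0, max(0.0, (b * f - c * e) / denom))
    else:
        s = 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = min(1.0, max(0.0, -c / a))
    elif t > 1.0:
        t = 1.0
        s = min(1.0, max(0.0, (b - c) / a))
    return s, t


@njit(cache=True)
def seg_min_dist_nb(pA, qA, pB, qB):
    """Minimal distance between closed segments [pA,qA], [pB,qB] plus an
    achieving point pair.  Total function; works for degenerate segments."""
    s, t = _seg_seg(pA[0], pA[1], pA[2],
                    qA[0] - pA[0], qA[1] - pA[1], qA[2] - pA[2],
                    pB[0], pB[1], pB[2],
                    qB[0] - pB[0], qB[1] - pB[1], qB[2] - pB[2])
    ax = pA[0] + s * (qA[0] - pA[0])
    ay = pA[1] + s * (qA[1] - pA[1])
    az = pA[2] + s * (qA[2] - pA[2])
    bx = pB[0] + t * (qB[0] - pB[0])
    by = pB[1] + t * (qB[1] - pB[1])
    bz = pB[2] + t * (qB[2] - pB[2])
    d = math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)
    return d, ax, ay, az, bx, by, bz


def segment_min_distance(pA, qA, pB, qB):
    """Minimal Euclidean distance between two closed 3D segments.

    Returns ``(distance, a, a_prime)`` with ``a`` on [pA, qA] and ``a_prime``
    on [pB, qB] an achieving pair.  Symmetric under argument swap and total
    (degenerate, i.e. zero-length, segments are allowed).
    """
    pA = np.asarray(pA, dtype=float)
    qA = np.asarray(qA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    qB = np.asarray(qB, dtype=float)
    d, ax, ay, az, bx, by, bz = seg_min_dist_nb(pA, qA, pB, qB)
    return d, np.array([ax, ay, az]), np.array([bx, by, bz])


def cell_geometry(cell: Cell, w0: float = 1.0):
    """Cap centers, volume and footprint length of a cell.

    Returns ``(p, q, volume, footprint_length)`` with
    ``p = r + (l/2) n``, ``q = r - (l/2) n``,
    ``volume = (pi w0^2/4) l + (pi/6) w0^3`` and footprint ``l + w0``.
    """
    return cell.p, cell.q, spherocylinder_volume(cell.l, w0), cell.l + w0


def cell_volume(l: float, w0: float) -> float:
    """Spherocylinder volume for cylinder length ``l``, diameter ``w0``."""
    return spherocylinder_volume(l, w0)
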