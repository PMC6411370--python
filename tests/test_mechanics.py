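"""Cell-cell, cell-agar, drag, and surface-tension forces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from agarcolony import (
    AgarSurface, Cell, Contact, SimulationParams,
    cell_agar_force, cell_cell_force, colony_height_field,
    surface_tension_force, viscous_drag,
)
from agarcolony.mechanics import surface_tension_magnitude


@pytest.fixture
def params():
    return SimulationParams(seed=3)


def _pair(z_off=0.0, gap=0.9, vA=(0, 0, 0), vB=(0, 0, 0)):
    a = Cell(id=0, r=[0.0, 0.0, 0.5], n=[1, 0, 0], l=2.0, v=np.array(vA, float))
    b = Cell(id=1, r=[0.0, gap, 0.5 + z_off], n=[1, 0, 0], l=2.0,
             v=np.array(vB, float))
    return a, b


class TestCellCellForce:
    def test_no_contact_zero(self, params):
        a, b = _pair(gap=1.5)
        contact = Contact.between_cells(a, b, params.w0)
        assert contact.delta == 0.0
        (Fa, Ta), (Fb, Tb) = cell_cell_force(contact, a, b, params)
        assert np.all(Fa == 0) and np.all(Fb == 0)
        assert np.all(Ta == 0) and np.all(Tb == 0)

    def test_newtons_third_law(self, params):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = Cell(id=0, r=rng.uniform(-1, 1, 3), n=rng.normal(size=3),
                     l=rng.uniform(0.5, 3), v=rng.normal(size=3),
                     omega=rng.normal(size=3))
            b = Cell(id=1, r=a.r + rng.uniform(-0.8, 0.8, 3),
                     n=rng.normal(size=3), l=rng.uniform(0.5, 3),
                     v=rng.normal(size=3), omega=rng.normal(size=3))
            contact = Contact.between_cells(a, b, params.w0)
            (Fa, _), (Fb, _) = cell_cell_force(contact, a, b, params)
            np.testing.assert_array_equal(Fa, -Fb)

    def test_elastic_magnitude_is_hertzian(self, params):
        a, b = _pair(gap=0.9)
        contact = Contact.between_cells(a, b, params.w0)
        (Fa, _), _ = cell_cell_force(contact, a, b, params)
        delta = params.w0 - 0.9
        assert np.linalg.norm(Fa) == pytest.approx(
            params.k_n * delta ** 1.5)
        # repulsive along -y for A (B sits at +y)
        assert Fa[1] < 0

    def test_dynamic_friction_cap_two_branch_oracle(self, params):
        delta = 0.05
        a, b = _pair(gap=params.w0 - delta, vA=(8.0, 0, 0))
        contact = Contact.between_cells(a, b, params.w0)
        (Fa, _), _ = cell_cell_force(contact, a, b, params)
        F_elas = params.k_n * delta ** 1.5
        vt = 8.0
        # independent scalar evaluation of both branches
        static_branch = min(params.gamma_cc_t * delta,
                            0.5 * (params.mass / 2) / params.dt) * vt
        expected = min(static_branch, params.mu_cc * F_elas)
        assert static_branch > params.mu_cc * F_elas  # the cap is active
        F_t = Fa - np.array([0, Fa[1], 0])  # tangential = x component here
        assert abs(F_t[0]) == pytest.approx(expected, rel=1e-12)
        assert F_t[0] < 0  # opposes sliding

    def test_zero_tangential_velocity_zero_friction(self, params):
        a, b = _pair(gap=0.9)
        contact = Contact.between_cells(a, b, params.w0)
        (Fa, _), _ = cell_cell_force(contact, a, b, params)
        # purely normal force: no x or z component
        assert Fa[0] == 0.0 and Fa[2] == 0.0

    def test_friction_never_exceeds_cap(self, params):
        rng = np.random.default_rng(5)
        for _ in range(100):
            delta = rng.uniform(0.001, 0.3)
            a, b = _pair(gap=params.w0 - delta,
                         vA=rng.normal(scale=5, size=3),
                         vB=rng.normal(scale=5, size=3))
            contact = Contact.between_cells(a, b, params.w0)
            (Fa, _), _ = cell_cell_force(contact, a, b, params)
            nhat = contact.normal
            Fn = np.dot(Fa, nhat)
            Ft = np.linalg.norm(Fa - Fn * nhat)
            F_elas = params.k_n * contact.delta ** 1.5
            assert Ft <= params.mu_cc * F_elas + 1e-12


class TestCellAgarForce:
    def test_tangency_zero(self, params):
        flat = SimulationParams(h_ran=0.0, seed=3)
        c = Cell(id=0, r=[0, 0, 0.5], n=[1, 0, 0], l=2.0)
        F, T, entries = cell_agar_force(c, AgarSurface(flat), flat)
        assert np.all(F == 0) and len(entries) == 0

    def test_fully_above_surface_zero(self, params):
        c = Cell(id=0, r=[0, 0, 5.0], n=[1, 0, 0], l=2.0)
        F, _, entries = cell_agar_force(c, AgarSurface(params), params)
        assert np.all(F == 0) and len(entries) == 0

    def test_equilibrium_overlap_root_find_oracle(self):
        """A cell pressed down by a constant load F settles where
        F_elastic(delta) = F; verify against a 1D root find."""
        flat = SimulationParams(h_ran=0.0, seed=3)
        load = 2.5
        delta_star = brentq(lambda d: flat.k_n * d ** 1.5 - load, 1e-9, 0.5)
        c = Cell(id=0, r=[0, 0, 0.5 * flat.w0 - delta_star], n=[1, 0, 0],
                 l=2.0)
        F, _, entries = cell_agar_force(c, AgarSurface(flat), flat)
        # two caps share the load: each cap pushes up with F_elastic(delta*)
        assert len(entries) == 2
        assert F[2] == pytest.approx(2 * load, rel=1e-9)

    def test_dynamic_cap_speed_independent(self):
        flat = SimulationParams(h_ran=0.0, seed=3)
        delta = 0.05
        mags = []
        for speed in (50.0, 100.0, 400.0):
            c = Cell(id=0, r=[0, 0, 0.5 - delta], n=[1, 0, 0], l=2.0,
                     v=[speed, 0, 0])
            F, _, _ = cell_agar_force(c, AgarSurface(flat), flat)
            mags.append(math.hypot(F[0], F[1]))
        F_elas = flat.k_n * delta ** 1.5
        for m in mags:
            assert m == pytest.approx(2 * flat.mu_ca * F_elas, rel=1e-9)

    def test_roughness_field_static_and_bounded(self, params):
        agar = AgarSurface(params)
        h1 = [agar.height_at(x, y) for x, y in [(0, 0), (5.3, -2.1), (100, 7)]]
        h2 = [agar.height_at(x, y) for x, y in [(0, 0), (5.3, -2.1), (100, 7)]]
        assert h1 == h2
        samples = [agar.height_at(i * 1.0 + 0.5, j * 1.0 + 0.5)
                   for i in range(-20, 20) for j in range(-20, 20)]
        assert max(np.abs(samples)) <= params.h_ran
        assert np.std(samples) > 0.01  # actually rough


class TestViscousDrag:
    def test_zero_velocity(self, params):
        c = Cell(id=0, r=[0, 0, 1], n=[1, 0, 0], l=2.0)
        F, T = viscous_drag(c, params)
        assert np.all(F == 0) and np.all(T == 0)

    def test_linearity_and_proportionality(self, params):
        c1 = Cell(id=0, r=[0, 0, 1], n=[1, 0, 0], l=2.0, v=[1, 0, 0])
        c2 = Cell(id=0, r=[0, 0, 1], n=[1, 0, 0], l=2.0, v=[2, 0, 0])
        F1, _ = viscous_drag(c1, params)
        F2, _ = viscous_drag(c2, params)
        np.testing.assert_allclose(F1, [-params.eta_drag, 0, 0])
        np.testing.assert_allclose(F2, 2 * F1)


class TestSurfaceTension:
    def test_piecewise_values(self, params):
        w0, g = params.w0, params.gamma_surf
        F0 = math.pi * g * w0
        assert surface_tension_magnitude(-0.2, params) == 0.0
        assert surface_tension_magnitude(w0 / 20, params) == pytest.approx(F0 / 2)
        assert surface_tension_magnitude(w0 / 10, params) == pytest.approx(F0)
        assert surface_tension_magnitude(5.0, params) == pytest.approx(F0)

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_ramp_continuity(self, dz):
        params = SimulationParams(seed=3)
        eps = 1e-9
        f0 = surface_tension_magnitude(dz, params)
        f1 = surface_tension_magnitude(dz + eps, params)
        # piecewise-linear continuous: max slope pi*gamma*w0 / (w0/10)
        max_slope = math.pi * params.gamma_surf * params.w0 / (0.1 * params.w0)
        assert abs(f1 - f0) <= max_slope * eps * 1.01

    def test_submerged_cell_feels_nothing(self, params):
        snap_cells = [Cell(id=i, r=[x, y, 0.5], n=[1, 0, 0], l=2.0)
                      for i, (x, y) in enumerate(
                          (x, y) for x in range(-3, 4) for y in range(-3, 4))]
        hf = colony_height_field(snap_cells, 1.0, params)
        F, T, _ = surface_tension_force(snap_cells[24], hf, params)
        # flat monolayer: everyone level with the film, no restoring force
        assert np.linalg.norm(F) == 0.0

    def test_protruding_cell_pushed_down(self, params):
        cells = [Cell(id=i, r=[x, y, 0.5], n=[1, 0, 0], l=2.0)
                 for i, (x, y) in enumerate(
                     (x, y) for x in range(-4, 5) for y in range(-4, 5))]
        riser = Cell(id=99, r=[0.0, 0.0, 1.5], n=[1, 0, 0], l=2.0)
        hf = colony_height_field(cells + [riser], 1.0, params)
        F, _, _ = surface_tension_force(riser, hf, params)
        assert F[2] < 0
        assert np.linalg.norm(F) <= params.F_surf0 + 1e-12


class TestHeightField:
    def test_single_sphere_cell(self, params):
        c = Cell(id=0, r=[0.5, 0.5, 0.5], n=[1, 0, 0], l=0.0)
        hf = colony_height_field([c], 1.0, params)
        assert hf.h_raw.max() == pytest.approx(1.0)

    def test_flat_monolayer_height_w0(self, params):
        cells = [Cell(id=0, r=[x, y, 0.5], n=[1, 0, 0], l=2.0)
                 for x in range(-5, 6) for y in range(-5, 6)]
        hf = colony_height_field(cells, 1.0, params)
        inside = hf.h[3:-3, 3:-3]
        occupied = inside[inside > 0]
        np.testing.assert_allclose(occupied, params.w0, rtol=1e-9)
        assert hf.hw.max() == pytest.approx(hf.h.max() + params.delta_h)

    def test_zero_outside_footprint(self, params):
        c = Cell(id=0, r=[0.5, 0.5, 0.5], n=[1, 0, 0], l=0.0)
        hf = colony_height_field([c], 1.0, params)
        assert hf.h[0, 0] == 0.0  # padded corner bin, no cells

    def test_cone_monotone_after_smoothing(self, params):
        # densely covered synthetic cone: one sphere-cell per 1 um column,
        # top surface at H (1 - r/R)
        R, H = 30.0, 15.0
        cells = []
        k = 0
        for x in np.arange(-R, R + 0.5, 1.0):
            for y in np.arange(-R, R + 0.5, 1.0):
                rad = math.hypot(x, y)
                if rad > R:
                    continue
                top = max(1.0, H * (1.0 - rad / R))
                cells.append(Cell(id=k, r=[x + 0.5, y + 0.5, top - 0.5],
                                  n=[1, 0, 0], l=0.0))
                k += 1
        hf = colony_height_field(cells, 1.0, params)
        nx, ny = hf.h.shape
        row = hf.h[:, ny // 2]
        occ = np.where(row > 0)[0]
        prof = row[occ[0]: nx // 2]
        # heights increase monotonically toward the center, up to the
        # one-bin discretization of the cone slope
        assert np.all(np.diff(prof) >= -H / R - 1e-9)
        assert prof[-1] > prof[0] + 0.5 * H
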