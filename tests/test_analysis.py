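"""Pressure, coarse-grained fields, edge profiles, and observables."""

import math

import numpy as np
import pytest

from agarcolony import Cell, SimulationParams, engine
from agarcolony.analysis import (
    azimuthal_profiles, cell_pressure, coarse_grain, colony_observables,
    growth_zone_and_verticalization, plot_edge_profiles, plot_growth_curves,
    plot_vertical_fraction,
)
from agarcolony.engine import Snapshot, compute_forces
from agarcolony.fixtures import (
    make_cone_colony, make_linear_trajectory, make_monolayer_disk,
    make_vertical_rod_lattice,
)
from agarcolony.model_core import spherocylinder_volume
from agarcolony.nutrient_solver import AGAR, NutrientField, NutrientGrid


@pytest.fixture
def params():
    return SimulationParams(seed=0)


class TestCellPressure:
    def test_force_free_cell(self, params):
        c = Cell(id=0, r=[0, 0, 0.5], n=[1, 0, 0], l=2.0)
        assert cell_pressure(c, [], params.w0) == 0.0

    def test_axial_compression_positive(self, params):
        """Two cells pressed axially both read a positive pressure."""
        a = Cell(id=0, r=[-1.0, 0, 0.5], n=[1, 0, 0], l=1.0)
        b = Cell(id=1, r=[0.9, 0, 0.5], n=[1, 0, 0], l=1.0)
        acc = compute_forces([a, b], params, with_agar=False,
                             with_surface=False, with_drag=False)
        Pa = cell_pressure(a, acc.ledger[0], params.w0)
        Pb = cell_pressure(b, acc.ledger[1], params.w0)
        assert Pa > 0 and Pb > 0
        assert Pa == pytest.approx(Pb, rel=1e-9)

    def test_duplicate_virial_oracle(self, params):
        """cell_pressure matches an independently coded virial sum."""
        rng = np.random.default_rng(7)
        c = Cell(id=0, r=[0, 0, 1.0], n=[0, 1, 0], l=2.0)
        ledger = [(rng.normal(size=3), rng.normal(size=3))
                  for _ in range(20)]
        expected = sum(F @ off for F, off in ledger) / spherocylinder_volume(
            c.l, params.w0)
        assert cell_pressure(c, ledger, params.w0) == pytest.approx(
            expected, rel=1e-12)

    def test_kernel_virial_matches_ledger_path(self):
        """The engine kernel's accumulated virial equals the ledger-based
        pressure computed through the Python force path."""
        p = SimulationParams(L=24, a=16, b=16, uniform_spacing=8.0, seed=5,
                             h_ran=0.0)
        cells = [
            Cell(id=0, r=[-1.0, 0.0, 0.5], n=[1, 0, 0], l=1.2),
            Cell(id=1, r=[0.9, 0.05, 0.5], n=[1, 0, 0], l=1.2),
            Cell(id=2, r=[0.0, 0.9, 0.5], n=[0, 1, 0], l=1.2),
        ]
        st = engine.SimulationState(params=p)
        st._alloc(16)
        for i, c in enumerate(cells):
            st.r[i] = c.r
            st.n[i] = c.n
            st.l[i] = c.l
            st.ids[i] = i
        st.count = 3
        st.next_id = 3
        # one tiny step evaluates forces; growth frozen (lam = 0)
        engine.step_inner(st, 1)
        snap = st.snapshot()
        hf = st.height_field()
        acc = compute_forces(cells, p, height_field=hf)
        for i, c in enumerate(cells):
            P_ledger = cell_pressure(c, acc.ledger[i], p.w0)
            assert snap.pressure[i] == pytest.approx(P_ledger, abs=1e-9)


class TestCoarseGrain:
    def test_vertical_lattice_director(self, params):
        snap, _ = make_vertical_rod_lattice()
        cf = coarse_grain(snap, box=4.0, rho_cell=params.rho_cell)
        occ = cf.mask
        dirs = cf.director[occ]
        assert np.allclose(np.abs(dirs[:, 2]), 1.0, atol=1e-9)
        assert np.allclose(cf.order[occ], 1.0, atol=1e-9)

    def test_nematic_sign_invariance(self, params):
        """An equal mix of +x and -x cells still reads director x, order 1."""
        r = np.array([[i + 0.5, 0.5, 0.5] for i in range(4)])
        n = np.array([[1, 0, 0], [-1, 0, 0], [1, 0, 0], [-1, 0, 0]],
                     dtype=float)
        snap = Snapshot(t=0, ids=np.arange(4), r=r, n=n,
                        l=np.full(4, 2.0), v=np.zeros((4, 3)),
                        omega=np.zeros((4, 3)), t_birth=np.zeros(4),
                        lambda_local=np.zeros(4), pressure=np.zeros(4))
        cf = coarse_grain(snap, box=8.0, rho_cell=params.rho_cell)
        d = cf.director[cf.mask][0]
        assert abs(d[0]) == pytest.approx(1.0)
        assert cf.order[cf.mask][0] == pytest.approx(1.0)

    def test_lattice_density_exact(self, params):
        snap, truth = make_vertical_rod_lattice(nx=4, ny=4, spacing=2.0,
                                                l=2.0)
        cf = coarse_grain(snap, box=4.0, rho_cell=params.rho_cell)
        # 2x2 cells of known volume per fully covered 4 um box
        vol = spherocylinder_volume(2.0, 1.0)
        expected = 4 * vol * params.rho_cell / 4.0 ** 3
        inner = cf.density[cf.mask]
        assert np.allclose(inner, expected, rtol=1e-12)

    def test_empty_boxes_masked(self, params):
        # two distant cells: the boxes between them are empty
        r = np.array([[0.5, 0.5, 0.5], [9.5, 9.5, 0.5]])
        n = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        snap = Snapshot(t=0, ids=np.arange(2), r=r, n=n, l=np.full(2, 2.0),
                        v=np.zeros((2, 3)), omega=np.zeros((2, 3)),
                        t_birth=np.zeros(2), lambda_local=np.zeros(2),
                        pressure=np.zeros(2))
        cf = coarse_grain(snap, box=2.0, rho_cell=params.rho_cell)
        assert (~cf.mask).any()
        assert np.isnan(cf.pressure[~cf.mask]).all()
        assert (cf.density[~cf.mask] == 0).all()


class TestAzimuthalProfiles:
    def test_rigid_radial_expansion(self):
        """v = V r_hat in the bottom layer: Vr(dr) = V in every bin."""
        traj, truth = make_linear_trajectory(VR=12.0, t_max=0.0)
        snap = traj.snapshots[0]
        prof = azimuthal_profiles(snap, bottom_layer_only=True)
        good = prof[prof["n_cells"] >= 3]
        assert np.allclose(good["Vr"], 12.0, atol=1e-9)

    def test_linear_profile_slope_recovery(self):
        """Vr = VR + lambda_S dr: the recovered slope matches lambda_S
        within 2%."""
        lam = 1.0
        VR = 8.0
        snap, _ = make_monolayer_disk(R=40.0, seed=1)
        center = snap.r[:, :2].mean(axis=0)
        rad = np.hypot(snap.r[:, 0] - center[0], snap.r[:, 1] - center[1])
        R_edge = 40.0   # ring construction radius = sector edge radius
        vr = VR + lam * (rad - R_edge)
        with np.errstate(invalid="ignore"):
            rhat = (snap.r[:, :2] - center) / rad[:, None]
        rhat[rad < 1e-9] = 0.0
        snap.v[:, :2] = vr[:, None] * rhat
        prof = azimuthal_profiles(snap, dr_bin=2.0)
        good = prof[(prof["n_cells"] >= 5) & (prof["dr"] < -2)]
        slope = np.polyfit(good["dr"], good["Vr"], 1)[0]
        assert slope == pytest.approx(lam, rel=0.02)

    def test_rotation_invariance(self):
        snap, _ = make_monolayer_disk(R=30.0, seed=2)
        th = math.radians(30)
        Rm = np.array([[math.cos(th), -math.sin(th), 0],
                       [math.sin(th), math.cos(th), 0],
                       [0, 0, 1]])
        center = snap.r[:, :2].mean(axis=0)
        rad = np.hypot(snap.r[:, 0] - center[0], snap.r[:, 1] - center[1])
        with np.errstate(invalid="ignore"):
            rhat = (snap.r[:, :2] - center) / np.maximum(rad[:, None], 1e-9)
        snap.v[:, :2] = (3.0 + 0.5 * rad)[:, None] * rhat
        prof1 = azimuthal_profiles(snap)
        rot = Snapshot(t=0, ids=snap.ids, r=snap.r @ Rm.T, n=snap.n @ Rm.T,
                       l=snap.l, v=snap.v @ Rm.T, omega=snap.omega,
                       t_birth=snap.t_birth, lambda_local=snap.lambda_local,
                       pressure=snap.pressure, w0=snap.w0)
        prof2 = azimuthal_profiles(rot)
        m = min(len(prof1), len(prof2))
        np.testing.assert_allclose(prof1["Vr"][:m], prof2["Vr"][:m],
                                   atol=0.15)


class TestColonyObservables:
    def test_linear_trajectory_exact_recovery(self):
        traj, truth = make_linear_trajectory(VR=18.0, VH=6.0, Wb=8.0)
        obs = colony_observables(traj)
        assert obs.VR == pytest.approx(truth["VR"], abs=1e-6)
        assert obs.VH == pytest.approx(truth["VH"], abs=1e-6)
        assert obs.Wb == pytest.approx(truth["Wb"], abs=1e-6)

    def test_explicit_fit_window(self):
        traj, _ = make_linear_trajectory(VR=10.0, VH=2.0, t_max=2.0)
        obs = colony_observables(traj, fit_window=(1.0, 2.0))
        assert obs.VR == pytest.approx(10.0, abs=1e-6)
        with pytest.raises(ValueError):
            colony_observables(traj, fit_window=(1.0, 99.0))

    def test_monolayer_only_no_buckling(self):
        snap, _ = make_monolayer_disk(R=20.0)
        traj = engine.Trajectory(SimulationParams(seed=0))
        for t in (0.0, 0.5, 1.0):
            s = Snapshot(t=t, ids=snap.ids, r=snap.r, n=snap.n, l=snap.l,
                         v=snap.v, omega=snap.omega, t_birth=snap.t_birth,
                         lambda_local=snap.lambda_local,
                         pressure=snap.pressure, w0=snap.w0)
            traj.snapshots.append(s)
        obs = colony_observables(traj)
        assert obs.t_buckle is None
        assert math.isnan(obs.Wb)

    def test_cone_layer_radii_exact(self):
        snap, truth = make_cone_colony(R=60.0, H=20.0)
        traj = engine.Trajectory(SimulationParams(seed=0))
        traj.snapshots = [snap]
        obs = colony_observables(traj, fit_window=(0.0, 0.0))
        assert obs.r1[0] == pytest.approx(truth["r1"], abs=1e-9)
        assert obs.r2[0] == pytest.approx(truth["r2"], abs=1e-9)


class TestGrowthZoneAndVerticalization:
    def _field_with_linear_profile(self, params, z_cross):
        """Synthetic solved field: C = K_S exactly at z = z_cross."""
        grid = NutrientGrid(40.0, 16.0, 32.0, 4.0)
        Ks = params.K_S_mass
        C0 = 10 * Ks
        slope = (C0 - Ks) / z_cross
        C = np.broadcast_to(np.maximum(C0 - slope * grid.z, 0.0),
                            grid.shape).copy()
        labels = np.full(grid.shape, AGAR, dtype=np.int8)
        return NutrientField(grid, C, labels, params)

    def test_hs_interpolated_crossing(self, params):
        snap, _ = make_cone_colony(R=30.0, H=16.0)
        field = self._field_with_linear_profile(params, z_cross=10.0)
        HS, prof, limited = growth_zone_and_verticalization(snap, field)
        assert limited
        assert HS == pytest.approx(10.0, abs=0.05)

    def test_all_horizontal_zero_fraction(self, params):
        snap, _ = make_monolayer_disk(R=20.0)
        field = self._field_with_linear_profile(params, z_cross=10.0)
        _, prof, _ = growth_zone_and_verticalization(snap, field)
        assert (prof["vertical_fraction"] == 0).all()

    def test_45_degree_inclusive(self, params):
        ang = math.radians(44.0)
        n = np.array([[math.sin(ang), 0.0, math.cos(ang)]] * 5)
        r = np.array([[i * 3.0, 0.0, 0.5] for i in range(5)])
        snap = Snapshot(t=0, ids=np.arange(5), r=r, n=n, l=np.full(5, 2.0),
                        v=np.zeros((5, 3)), omega=np.zeros((5, 3)),
                        t_birth=np.zeros(5), lambda_local=np.zeros(5),
                        pressure=np.zeros(5))
        field = self._field_with_linear_profile(params, z_cross=10.0)
        _, prof, _ = growth_zone_and_verticalization(snap, field)
        assert (prof["vertical_fraction"] == 1).all()

    def test_not_nutrient_limited_flagged(self, params):
        snap, _ = make_monolayer_disk(R=20.0)
        field = self._field_with_linear_profile(params, z_cross=1e6)
        HS, _, limited = growth_zone_and_verticalization(snap, field)
        assert not limited


class TestSimulationSnapshotStructure:
    """Structure of the real simulated colony around buckling."""

    def test_pressure_low_at_edge_high_inside(self, standard_runs):
        traj = standard_runs[1]
        snap = traj.snapshots[-1]
        prof = azimuthal_profiles(snap, bottom_layer_only=True)
        good = prof[prof["n_cells"] >= 10]
        edge = good[good["dr"] >= -2.0]["P"].mean()
        inner = good[good["dr"] <= -10.0]["P"].max()
        assert inner > 2 * max(edge, 0.0)

    def test_radial_velocity_rises_toward_edge(self, standard_runs):
        snap = standard_runs[1].snapshots[-1]
        prof = azimuthal_profiles(snap, bottom_layer_only=True)
        good = prof[prof["n_cells"] >= 10].reset_index(drop=True)
        inner = good[good["dr"] <= -10.0]["Vr"].mean()
        outer = good[good["dr"] >= -4.0]["Vr"].mean()
        assert outer > inner + 1.0

    def test_monolayer_height_about_one_cell_width(self, standard_runs):
        snap = standard_runs[1].snapshots[-1]
        prof = azimuthal_profiles(snap, bottom_layer_only=True)
        edge_bins = prof[(prof["dr"] >= -6) & (prof["n_cells"] >= 5)]
        assert 0.8 <= edge_bins["H"].mean() <= 1.6


class TestPlotting:
    def test_plot_helpers_run(self):
        traj, _ = make_linear_trajectory(t_max=1.0)
        obs = colony_observables(traj)
        ax = plot_growth_curves(obs)
        assert ax is not None
        snap = traj.snapshots[0]
        prof = azimuthal_profiles(snap)
        assert plot_edge_profiles(prof) is not None
        import pandas as pd
        vf = pd.DataFrame({"radius": [2, 6], "vertical_fraction": [0, 1]})
        assert plot_vertical_fraction(vf) is not None
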