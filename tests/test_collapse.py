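"""Meshing and transient Kelvin–Voigt collapse: analytic oracles and
strategy comparison."""

import numpy as np
import pytest

from gelprint.collapse import (
    analytic_kv_creep,
    compare_strategies,
    oedometric_modulus,
    solve_collapse,
)
from gelprint.mesh import (
    GEL,
    SUPPORT,
    ScaffoldUnitCell,
    build_unit_cell_mesh,
    rectangle_mesh,
)
from gelprint.rheology import KelvinVoigtMaterial

RHO = 1000.0
G = 9.81


@pytest.fixture(scope="module")
def cell(fixtures):
    return fixtures.cell


class TestMesh:
    def test_gel_only_mesh_scale_and_labels(self, cell):
        mesh = build_unit_cell_mesh(cell, with_support=False)
        assert 500 <= mesh.n_elements <= 750
        assert np.all(mesh.labels == GEL)
        assert np.all(mesh.element_areas() > 0)

    def test_support_mesh_fills_voids(self, cell):
        mesh = build_unit_cell_mesh(cell, with_support=True)
        assert 450 <= mesh.n_elements <= 700
        assert np.any(mesh.labels == SUPPORT)
        # support fills the voids exactly: total area = bounding box
        assert mesh.element_areas().sum() == pytest.approx(
            cell.width * cell.height, rel=1e-9
        )

    def test_single_layer_is_solid_slab(self):
        cell1 = ScaffoldUnitCell(
            strand_width=0.77e-3, layer_height=0.55e-3,
            inter_fiber_distance=2.57e-3, n_layers=1,
        )
        mesh = build_unit_cell_mesh(cell1)
        assert np.all(mesh.labels == GEL)
        assert mesh.element_areas().sum() == pytest.approx(
            cell1.width * cell1.layer_height, rel=1e-9
        )

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            cell_bad = ScaffoldUnitCell(
                strand_width=3.0e-3, layer_height=0.55e-3,
                inter_fiber_distance=2.57e-3,
            )
            build_unit_cell_mesh(cell_bad)

    def test_overlap_invariant(self):
        with pytest.raises(ValueError):
            ScaffoldUnitCell(
                strand_width=0.4e-3, layer_height=0.55e-3,
                inter_fiber_distance=2.57e-3,
            )

    def test_gmsh_export(self, tmp_path, cell):
        mesh = build_unit_cell_mesh(cell)
        path = tmp_path / "cell.msh"
        mesh.write_gmsh(path)
        text = path.read_text()
        assert "$Nodes" in text and f"{mesh.n_elements}" in text


class TestAnalyticCreep:
    def test_asymptote_is_elastic_strain(self):
        assert analytic_kv_creep(30.0, 231.4, 10.0, 1e9) == pytest.approx(10 / 30)

    def test_zero_time_zero_strain(self):
        assert analytic_kv_creep(30.0, 231.4, 10.0, 0.0) == 0.0

    def test_softest_gel_time_constant(self):
        # tau = eta/E = 7.71 s: equilibrium is reached well within 200 s
        tau = 231.4 / 30.0
        assert tau == pytest.approx(7.71, abs=0.01)
        eps200 = analytic_kv_creep(30.0, 231.4, 1.0, 200.0)
        assert eps200 == pytest.approx(1.0 / 30.0, rel=1e-9)

    def test_zero_viscosity_is_instantaneous(self):
        assert analytic_kv_creep(30.0, 0.0, 10.0, 0.0) == pytest.approx(10 / 30)


class TestColumnOracle:
    """FE self-weight compression of a laterally confined column."""

    H = 3.3e-3

    def _top_displacement(self, nu):
        mat = KelvinVoigtMaterial(E=30.0, eta0=231.4, nu=nu, rho=RHO)
        mesh = rectangle_mesh(2.57e-3, self.H, nx=6, ny=30)
        sol = solve_collapse(mesh, mat, t_end=200.0, dt=0.5)
        return np.abs(sol.displacements[-1][mesh.top_nodes(), 1]).max()

    def test_matches_rho_g_h2_over_2E_at_nu_zero(self):
        # for E = 30 Pa and H = 3.3 mm the analytic value is 1.78 mm
        exact = RHO * G * self.H**2 / (2 * 30.0)
        assert exact == pytest.approx(1.78e-3, abs=5e-6)
        assert self._top_displacement(0.0) == pytest.approx(exact, rel=0.02)

    def test_near_incompressible_column_against_confined_modulus(self):
        """At nu = 0.49 the confined column compresses with the oedometric
        modulus; the mesh must not lock volumetrically."""
        M = oedometric_modulus(30.0, 0.49)
        exact = RHO * G * self.H**2 / (2 * M)
        assert self._top_displacement(0.49) == pytest.approx(exact, rel=0.02)


class TestSingleElementCreep:
    def test_fe_matches_1d_kelvin_voigt_creep(self):
        """One-square mesh under constant top traction follows
        (sigma/E)(1 - exp(-E t/eta)) at every output time."""
        E, eta, sigma = 30.0, 231.4, 10.0
        mat = KelvinVoigtMaterial(E=E, eta0=eta, nu=0.0, rho=RHO)
        mesh = rectangle_mesh(1e-3, 1e-3, nx=1, ny=1)
        sol = solve_collapse(mesh, mat, gravity=0.0, t_end=40.0, dt=0.02,
                             top_traction=-sigma)
        eps_fe = np.abs(sol.displacements[:, mesh.top_nodes(), 1]).max(axis=1) / 1e-3
        eps_exact = analytic_kv_creep(E, eta, sigma, sol.times)
        mask = sol.times > 0
        np.testing.assert_allclose(eps_fe[mask], eps_exact[mask], rtol=0.01)


class TestSolveCollapse:
    def test_zero_gravity_zero_displacement(self, cell, fixtures):
        mesh = build_unit_cell_mesh(cell)
        sol = solve_collapse(mesh, fixtures.kv_gels["C20_pH3.7"], gravity=0.0,
                             t_end=10.0, dt=0.5)
        assert np.abs(sol.displacements).max() == 0.0

    def test_displacement_starts_at_zero_and_is_monotone(self, cell, fixtures):
        mesh = build_unit_cell_mesh(cell)
        sol = solve_collapse(mesh, fixtures.kv_gels["C20_pH3.7"], t_end=200.0, dt=0.5)
        series = sol.point_a_series
        assert series[0] == 0.0
        assert np.all(np.diff(series) >= -1e-15)

    def test_equilibrium_reached_by_200s_for_all_gels(self, cell, fixtures):
        """Point A asymptotes: < 0.1% relative change over the last 10%."""
        mesh = build_unit_cell_mesh(cell)
        for label, gel in fixtures.kv_gels.items():
            sol = solve_collapse(mesh, gel, t_end=200.0, dt=0.5)
            series = sol.point_a_series
            tail = series[int(0.9 * len(series)):]
            assert (tail[-1] - tail[0]) / tail[-1] < 1e-3, label

    def test_strain_decreases_monotonically_with_stiffness(self, cell, fixtures):
        mesh = build_unit_cell_mesh(cell)
        by_E = sorted(fixtures.kv_gels.values(), key=lambda m: m.E)
        strains = [
            solve_collapse(mesh, gel, t_end=200.0, dt=0.5).final_strain
            for gel in by_E
        ]
        assert np.all(np.diff(strains) < 0)
        # stiffest gel more than an order of magnitude below the softest
        assert strains[-1] < strains[0] / 10

    def test_doubling_gravity_doubles_displacement(self, cell, fixtures):
        mesh = build_unit_cell_mesh(cell)
        gel = fixtures.kv_gels["C20_pH4.9"]
        d1 = solve_collapse(mesh, gel, gravity=G, t_end=200.0, dt=0.5).final_displacement
        d2 = solve_collapse(mesh, gel, gravity=2 * G, t_end=200.0, dt=0.5).final_displacement
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_time_step_convergence(self, cell, fixtures):
        """Halving dt changes the final point-A displacement by < 1%."""
        mesh = build_unit_cell_mesh(cell)
        gel = fixtures.kv_gels["C20_pH3.7"]
        d_coarse = solve_collapse(mesh, gel, t_end=200.0, dt=0.5).final_displacement
        d_fine = solve_collapse(mesh, gel, t_end=200.0, dt=0.25).final_displacement
        assert abs(d_fine - d_coarse) / d_fine < 0.01

    def test_support_material_consistency_checks(self, cell, fixtures):
        mesh_plain = build_unit_cell_mesh(cell, with_support=False)
        mesh_bath = build_unit_cell_mesh(cell, with_support=True)
        with pytest.raises(ValueError):
            solve_collapse(mesh_bath, fixtures.kv_gels["C20_pH3.7"])  # missing support
        with pytest.raises(ValueError):
            solve_collapse(
                mesh_plain, fixtures.kv_gels["C20_pH3.7"], fixtures.support
            )  # spurious support

    def test_series_export(self, tmp_path, cell, fixtures):
        mesh = build_unit_cell_mesh(cell)
        sol = solve_collapse(mesh, fixtures.kv_gels["C30_pH4.9"], t_end=20.0, dt=0.5)
        sol.series_to_csv(tmp_path / "a.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "a.csv")
        assert list(df.columns) == ["time", "point_a_displacement"]
        assert len(df) == len(sol.times)


class TestCompareStrategies:
    def test_support_bath_reduces_softest_gel_collapse_tenfold(self, cell, fixtures):
        cmp = compare_strategies(cell, fixtures.kv_gels["C20_pH3.7"], fixtures.support)
        assert cmp.strain_without > 0.05  # would collapse visibly
        assert cmp.improvement_ratio >= 10.0

    def test_filling_voids_with_same_material_cannot_soften(self, cell, fixtures):
        """With gel == support, the only difference is the filled voids;
        added material can only stiffen the cell."""
        gel = fixtures.kv_gels["C20_pH4.9"]
        cmp = compare_strategies(cell, gel, gel)
        assert cmp.strain_with < cmp.strain_without

    def test_summary_fields(self, cell, fixtures):
        cmp = compare_strategies(cell, fixtures.kv_gels["C30_pH4.9"], fixtures.support)
        s = cmp.summary()
        assert s["final_strain_without_support"] == pytest.approx(cmp.strain_without)
        assert s["improvement_ratio"] > 1.0
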