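import numpy as np
import pytest

from plaqueifem.errors import ConfigurationError, FESolverError
from plaqueifem.fem import (InflationProtocol, SolverOptions,
                            axial_displacement_field, solve_inflation)
from plaqueifem.materials import neo_hookean, yeoh
from plaqueifem.phantom import annular_mesh
from plaqueifem.tube import TubeSpec, inner_displacement
from plaqueifem.units import mmhg_to_kpa


def inner_radial_displacement(mesh, sol, pressure_kpa, n_theta):
    u = sol.displacement(pressure_kpa)
    ring = np.arange(n_theta)
    return np.linalg.norm(mesh.nodes[ring] + u[ring], axis=1) - np.linalg.norm(
        mesh.nodes[ring], axis=1)


def test_zero_pressure_gives_zero_displacement():
    mesh = annular_mesh(1.0, 2.0, 4, 24)
    sol = solve_inflation(mesh, {"wall": neo_hookean(5.0)},
                          InflationProtocol((0.0,)))
    assert np.allclose(sol.displacement(0.0), 0.0)


def test_equilibrium_is_homogeneous_in_constants_and_pressure():
    """Scaling all material constants and all pressures by k leaves the
    displacement field unchanged (W is linear in the constants)."""
    mesh = annular_mesh(1.5, 3.0, 6, 36)
    k = 7.3
    p = InflationProtocol.from_mmhg((80.0,))
    sol1 = solve_inflation(mesh, {"wall": yeoh(10.0, 1.0, 40.0)}, p)
    sol2 = solve_inflation(mesh, {"wall": yeoh(10.0 * k, 1.0 * k, 40.0 * k)},
                           InflationProtocol((k * p.pressures_kpa[0],)))
    u1 = sol1.displacement(p.pressures_kpa[0])
    u2 = sol2.displacement(k * p.pressures_kpa[0])
    assert np.max(np.abs(u1 - u2)) < 1e-8


@pytest.mark.parametrize("material", [neo_hookean(30.0), yeoh(10.0, 0.0, 100.0)])
def test_fe_matches_tube_oracle_within_one_percent(material):
    mesh = annular_mesh(1.5, 3.0, 12, 64)
    sol = solve_inflation(mesh, {"wall": material},
                          InflationProtocol.from_mmhg((80.0, 120.0)))
    spec = TubeSpec(1.5, 3.0, material)
    for p_mmhg in (80.0, 120.0):
        pk = mmhg_to_kpa(p_mmhg)
        ur = inner_radial_displacement(mesh, sol, pk, 64).mean()
        assert ur == pytest.approx(inner_displacement(spec, pk), rel=0.01)


def test_symmetry_of_concentric_inflation():
    mesh = annular_mesh(1.5, 3.0, 8, 48)
    sol = solve_inflation(mesh, {"wall": neo_hookean(30.0)},
                          InflationProtocol.from_mmhg((120.0,)))
    ur = inner_radial_displacement(mesh, sol, mmhg_to_kpa(120.0), 48)
    assert ur.std() / ur.mean() < 0.005


def test_incompressibility_of_the_solved_field():
    mesh = annular_mesh(1.5, 3.0, 8, 48)
    sol = solve_inflation(mesh, {"wall": neo_hookean(30.0)},
                          InflationProtocol.from_mmhg((120.0,)))
    pk = mmhg_to_kpa(120.0)
    assert sol.max_volumetric_strain(pk) < 1e-3
    # total tissue area change < 0.2 %
    x = mesh.nodes + sol.displacement(pk)
    xq = x[mesh.quads]
    x2 = np.roll(xq, -1, axis=1)
    area = 0.5 * np.abs(np.sum(xq[..., 0] * x2[..., 1]
                               - x2[..., 0] * xq[..., 1], axis=1)).sum()
    area0 = mesh.element_areas().sum()
    assert abs(area - area0) / area0 < 0.002


def test_mesh_refinement_convergence():
    mat = neo_hookean(30.0)
    pk = mmhg_to_kpa(120.0)
    results = []
    for nr, nt in ((8, 48), (16, 96)):
        mesh = annular_mesh(1.5, 3.0, nr, nt)
        sol = solve_inflation(mesh, {"wall": mat}, InflationProtocol((pk,)))
        results.append(inner_radial_displacement(mesh, sol, pk, nt).mean())
    assert abs(results[1] - results[0]) / abs(results[1]) < 0.01


def test_axial_projection_and_symmetry(annulus_solution):
    mesh, _, sol = annulus_solution
    pk = mmhg_to_kpa(80.0)
    uy = axial_displacement_field(sol, (0.0, 1.0), pk)
    u = sol.displacement(pk)
    assert np.allclose(uy, u[:, 1])
    # beam (1, 0) on a radially symmetric solution: antisymmetric about x=0
    ux = axial_displacement_field(sol, (1.0, 0.0), pk)
    theta = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    r = np.linalg.norm(mesh.nodes, axis=1)
    # mirror node: same radius, pi - theta
    from scipy.spatial import cKDTree
    mirror = np.column_stack([r * np.cos(np.pi - theta), r * np.sin(np.pi - theta)])
    _, idx = cKDTree(mesh.nodes).query(mirror)
    assert np.allclose(ux, -ux[idx], atol=1e-8 + 0.01 * np.abs(ux).max())


def test_unknown_pressure_lookup_raises(annulus_solution):
    _, _, sol = annulus_solution
    with pytest.raises(KeyError):
        sol.displacement(3.21)


def test_missing_material_is_a_configuration_error():
    mesh = annular_mesh(1.0, 2.0, 3, 16)
    with pytest.raises(ConfigurationError):
        solve_inflation(mesh, {}, InflationProtocol((1.0,)))


def test_unstable_yeoh_warns_but_attempts():
    mesh = annular_mesh(1.0, 2.0, 3, 16)
    with pytest.warns(UserWarning, match="stability"):
        solve_inflation(mesh, {"wall": yeoh(5.0, -1.0, 0.05)},
                        InflationProtocol((0.5,)))


def test_divergence_reports_last_converged_pressure():
    """A Neo-Hookean tube loaded beyond its limit pressure must fail with a
    penalizable error, not hang or return garbage."""
    mesh = annular_mesh(1.5, 3.0, 6, 36)
    with pytest.raises(FESolverError) as err:
        solve_inflation(mesh, {"wall": neo_hookean(10.0)},
                        InflationProtocol.from_mmhg((120.0,)))
    assert err.value.last_converged_pressure_kpa is not None


def test_protocol_validation():
    with pytest.raises(ConfigurationError):
        InflationProtocol((2.0, 1.0))
    with pytest.raises(ConfigurationError):
        InflationProtocol((-1.0, 1.0))
    with pytest.raises(ConfigurationError):
        SolverOptions(formulation="penalty")


def test_solution_export_table(annulus_solution):
    mesh, _, sol = annulus_solution
    df = sol.to_dataframe()
    assert len(df) == 3 * mesh.n_nodes
    assert set(df.columns) == {"pressure_kpa", "node", "x_mm", "y_mm",
                               "ux_mm", "uy_mm"}
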