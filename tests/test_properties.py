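"""MLP projection, electrostatic potential and sign splitting."""

import numpy as np
import pytest
from scipy import constants

from curvmap.errors import ParameterError
from curvmap.properties import (
    ElectrostaticModel,
    SurfaceProperty,
    electrostatic_potential,
    fermi_weight,
    mlp_project,
    read_opendx,
    sign_split,
)
from curvmap.surfaces import build_surface

from conftest import atom_cluster, single_atom


def _unit_mesh_at(points):
    """Minimal mesh stub: positions only (normals/triangles unused here)."""
    from curvmap.surfaces import SurfaceMesh

    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return SurfaceMesh(
        positions=points,
        normals=normals,
        triangles=np.empty((0, 3), dtype=int),
        nearest_atom=np.zeros(n, dtype=int),
        area_weights=np.ones(n),
    )


class TestMlp:
    def test_kernel_midpoint(self):
        assert fermi_weight(4.0) == pytest.approx(0.5, abs=1e-15)

    def test_kernel_monotone_and_short_ranged(self):
        d = np.linspace(0, 12, 200)
        g = fermi_weight(d)
        assert (np.diff(g) < 0).all()
        assert fermi_weight(7.2) < 0.01

    def test_single_atom_returns_f_exactly(self):
        s = single_atom(f=0.7)
        mesh = build_surface(s, grid_spacing=0.5)
        prop = mlp_project(s, mesh)
        np.testing.assert_allclose(prop.values, 0.7, atol=1e-12)

    def test_symmetric_pair_cancels(self):
        s = atom_cluster([[-2, 0, 0], [2, 0, 0]], hydros=[1.0, -1.0])
        mesh = _unit_mesh_at([[0, 0, 1.0], [0, 0, -3.0], [0, 5, 0]])
        prop = mlp_project(s, mesh)
        np.testing.assert_allclose(prop.values, 0.0, atol=1e-12)

    def test_weights_sum_to_one(self):
        # projecting f ≡ 1 must return exactly 1 everywhere
        rng = np.random.default_rng(0)
        s = atom_cluster(rng.uniform(-4, 4, (12, 3)), hydros=np.ones(12))
        mesh = _unit_mesh_at(rng.uniform(-6, 6, (40, 3)))
        prop = mlp_project(s, mesh)
        np.testing.assert_allclose(prop.values, 1.0, atol=1e-12)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(-1, 1, 15)
        s = atom_cluster(rng.uniform(-4, 4, (15, 3)), hydros=f)
        mesh = _unit_mesh_at(rng.uniform(-8, 8, (60, 3)))
        prop = mlp_project(s, mesh)
        assert prop.values.min() >= f.min() - 1e-12
        assert prop.values.max() <= f.max() + 1e-12


class TestElectrostatics:
    def test_coulomb_closed_form(self):
        s = single_atom(q=1.0)
        mesh = _unit_mesh_at([[7.0, 0.0, 0.0]])
        model = ElectrostaticModel(ionic_strength=0.0, temperature=298.0)
        prop = electrostatic_potential(s, mesh, model)
        # independent closed form: e²/(4π ε₀ ε_s k_B T d) in kT/e
        d_m = 7.0e-10
        expected = constants.e**2 / (
            4 * np.pi * constants.epsilon_0 * 80.0 * constants.k * 298.0 * d_m
        )
        assert prop.values[0] == pytest.approx(expected, rel=1e-12)

    def test_dipole_bisector_zero(self):
        s = atom_cluster([[-1.5, 0, 0], [1.5, 0, 0]], charges=[1.0, -1.0])
        mesh = _unit_mesh_at([[0, 3, 0], [0, 0, -5], [0, 2, 2]])
        prop = electrostatic_potential(s, mesh, ElectrostaticModel())
        np.testing.assert_allclose(prop.values, 0.0, atol=1e-12)

    def test_linearity_in_charges(self):
        rng = np.random.default_rng(2)
        q = rng.uniform(-1, 1, 6)
        coords = rng.uniform(-3, 3, (6, 3))
        mesh = _unit_mesh_at(rng.uniform(5, 8, (10, 3)))
        p1 = electrostatic_potential(atom_cluster(coords, charges=q), mesh)
        p2 = electrostatic_potential(atom_cluster(coords, charges=2 * q), mesh)
        np.testing.assert_allclose(p2.values, 2 * p1.values, rtol=1e-12)

    def test_screening_reduces_to_coulomb(self):
        s = single_atom(q=1.0)
        mesh = _unit_mesh_at([[6.0, 0.0, 0.0]])
        coulomb = electrostatic_potential(
            s, mesh, ElectrostaticModel(ionic_strength=0.0)
        ).values[0]
        screened_prev = None
        for ionic in (0.15, 0.015, 0.0015, 1.5e-5):
            v = electrostatic_potential(
                s, mesh, ElectrostaticModel(ionic_strength=ionic)
            ).values[0]
            assert v < coulomb
            if screened_prev is not None:
                assert v > screened_prev
            screened_prev = v
        assert screened_prev == pytest.approx(coulomb, rel=0.01)

    def test_debye_length_physically_sensible(self):
        model = ElectrostaticModel(ionic_strength=0.15)
        assert 1.0 / model.inverse_debye_length == pytest.approx(7.9, abs=0.3)

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ParameterError):
            ElectrostaticModel(ionic_strength=-0.1)


class TestSignSplit:
    def test_definition(self):
        prop = SurfaceProperty("ECM", np.array([1.0, -2.0, 0.0]))
        sign_split(prop)
        np.testing.assert_array_equal(prop.phi_plus, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(prop.phi_minus, [0.0, -2.0, 0.0])

    def test_all_positive_field(self):
        prop = sign_split(SurfaceProperty("ECM", np.array([0.5, 2.0])))
        assert (prop.phi_minus == 0).all()

    def test_reconstruction_bit_for_bit(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=100)
        prop = sign_split(SurfaceProperty("ECM", v))
        assert (prop.phi_plus + prop.phi_minus == v).all()


class TestOpenDx:
    def test_linear_field_interpolated_exactly(self, tmp_path):
        nx = ny = nz = 5
        origin = np.array([-2.0, -2.0, -2.0])
        h = 1.0
        xs = origin[0] + h * np.arange(nx)
        grid = (
            xs[:, None, None] + 2.0 * xs[None, :, None] + 3.0 * xs[None, None, :]
        )
        dx = tmp_path / "pot.dx"
        flat = grid.ravel(order="C")
        body = "\n".join(
            " ".join(f"{v:.6e}" for v in flat[i : i + 3]) for i in range(0, len(flat), 3)
        )
        dx.write_text(
            f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
            f"origin {origin[0]} {origin[1]} {origin[2]}\n"
            f"delta {h} 0.0 0.0\ndelta 0.0 {h} 0.0\ndelta 0.0 0.0 {h}\n"
            f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
            f"{body}\n"
            'attribute "dep" string "positions"\n'
        )
        o, step, counts, data = read_opendx(dx)
        np.testing.assert_array_equal(counts, [5, 5, 5])
        s = single_atom(q=0.0)
        mesh = _unit_mesh_at([[0.5, -0.5, 1.0], [0.0, 0.0, 0.0]])
        model = ElectrostaticModel(mode="grid_import", grid_path=dx)
        prop = electrostatic_potential(s, mesh, model)
        expected = mesh.positions @ np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(prop.values, expected, atol=1e-9)
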