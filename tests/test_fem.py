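"""Elasticity solver: element stiffness, patch tests, energy identities."""

import numpy as np
import pytest

from osteoadapt.fem import (
    LoadCase,
    assemble,
    assemble_and_solve,
    element_stiffness,
    fixed_dof_indices,
    nodal_forces,
    solve,
    strain_energy_density,
)
from osteoadapt.geometry import rectangular_mesh

UNIT_SQUARE = [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]


class TestElementStiffness:
    def test_rigid_body_modes(self):
        """Three zero-energy modes (two translations, one rotation)."""
        ke = element_stiffness(UNIT_SQUARE, 1000.0, 0.0)
        ev = np.linalg.eigvalsh(ke)
        assert np.sum(np.abs(ev) < 1e-9 * ev.max()) == 3
        # x-translation is exactly force-free
        tx = np.zeros(8)
        tx[0::2] = 1.0
        assert np.allclose(ke @ tx, 0.0, atol=1e-12 * ke.max())

    def test_symmetry_and_linearity_in_E(self):
        ke = element_stiffness(UNIT_SQUARE, 1000.0, 0.3)
        assert np.allclose(ke, ke.T)
        ke10 = element_stiffness(UNIT_SQUARE, 10000.0, 0.3)
        assert np.allclose(ke10, 10 * ke)

    def test_inverted_element_rejected(self):
        cw = [UNIT_SQUARE[0], UNIT_SQUARE[3], UNIT_SQUARE[2], UNIT_SQUARE[1]]
        with pytest.raises(ValueError, match="element 0"):
            element_stiffness(cw, 1000.0, 0.3)


def _uniaxial_patch(sigma=10.0, E=1000.0, width=10.0, height=20.0, h=1.0):
    """Bar under uniform vertical traction; returns (mesh, solution, sigma)."""
    mesh = rectangular_mesh(width, height, h)
    Ea = np.full(mesh.n_elements, E)
    nua = np.zeros(mesh.n_elements)
    load = LoadCase(vertical=-sigma * width, lateral=0.0, bc_mode="free",
                    thickness=1.0, force_distribution="edge_length")
    f = nodal_forces(mesh, load)
    fixed = fixed_dof_indices(mesh, "free")
    return mesh, solve(mesh, Ea, nua, f, fixed, thickness=1.0), sigma


class TestPatch:
    def test_uniform_energy_density_matches_closed_form(self):
        """Uniaxial patch: U = sigma^2 / (2E) in every element to 1e-6."""
        mesh, sol, sigma = _uniaxial_patch()
        expected = sigma**2 / (2 * 1000.0)
        assert np.allclose(sol.energy_density, expected, rtol=1e-6)
        assert np.ptp(sol.energy_density) / expected < 1e-6

    def test_energy_balance(self):
        """Work-energy identity sum(U V) = f.u / 2 to 1e-8 relative."""
        mesh, sol, _ = _uniaxial_patch()
        load = LoadCase(vertical=-100.0, lateral=0.0, bc_mode="free",
                        thickness=1.0, force_distribution="edge_length")
        f = nodal_forces(mesh, load)
        total = (sol.energy_density * sol.element_volume).sum()
        work = 0.5 * f @ sol.displacements.ravel()
        assert total == pytest.approx(work, rel=1e-8)

    def test_linear_field_reproduced_exactly(self):
        """A linear displacement field is in the bilinear span: imposing its
        boundary values reproduces it at interior nodes to round-off."""
        mesh = rectangular_mesh(4.0, 4.0, 1.0)
        a, b, c, d = 1e-3, -2e-3, 5e-4, 1.5e-3
        exact = np.column_stack([
            a * mesh.nodes[:, 0] + b * mesh.nodes[:, 1],
            c * mesh.nodes[:, 0] + d * mesh.nodes[:, 1],
        ]).ravel()
        E = np.full(mesh.n_elements, 500.0)
        nu = np.full(mesh.n_elements, 0.3)
        K = assemble(mesh, E, nu)
        x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
        boundary = np.nonzero(
            np.isclose(x, 0) | np.isclose(x, 4) | np.isclose(y, 0) | np.isclose(y, 4)
        )[0]
        fixed = np.concatenate([2 * boundary, 2 * boundary + 1])
        free = np.setdiff1d(np.arange(2 * mesh.n_nodes), fixed)
        rhs = -K[free][:, fixed] @ exact[fixed]
        import scipy.sparse.linalg as spla

        u = exact.copy()
        u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
        assert np.allclose(u, exact, atol=1e-12)

    def test_refinement_consistency(self):
        """Total strain energy of the homogeneous patch is mesh-independent
        (constant-stress state): < 0.1% change between refinements."""
        totals = []
        for h in (2.0, 1.0):
            _, sol, _ = _uniaxial_patch(h=h)
            totals.append((sol.energy_density * sol.element_volume).sum())
        assert abs(totals[1] - totals[0]) / totals[0] < 1e-3


class TestToothLoadCase:
    def test_zero_load_zero_solution(self, reduced_mesh, materials):
        load = LoadCase(vertical=0.0, lateral=0.0)
        rho = np.full(int(reduced_mesh.trabecular_mask.sum()), 0.8)
        sol = assemble_and_solve(reduced_mesh, materials, rho, load)
        assert np.allclose(sol.displacements, 0.0)
        assert np.allclose(sol.energy_density, 0.0)

    def test_energy_quadratic_in_load(self, reduced_mesh, materials):
        rho = np.full(int(reduced_mesh.trabecular_mask.sum()), 0.8)
        sol1 = assemble_and_solve(reduced_mesh, materials, rho, LoadCase())
        sol2 = assemble_and_solve(
            reduced_mesh, materials, rho,
            LoadCase(vertical=-200.0, lateral=20.0))
        e1 = (sol1.energy_density * sol1.element_volume).sum()
        e2 = (sol2.energy_density * sol2.element_volume).sum()
        assert e2 == pytest.approx(4 * e1, rel=1e-9)

    def test_energy_balance_on_tooth_mesh(self, reduced_mesh, materials):
        rho = np.full(int(reduced_mesh.trabecular_mask.sum()), 0.8)
        load = LoadCase()
        sol = assemble_and_solve(reduced_mesh, materials, rho, load)
        f = nodal_forces(reduced_mesh, load)
        total = (sol.energy_density * sol.element_volume).sum()
        work = 0.5 * f @ sol.displacements.ravel()
        assert total == pytest.approx(work, rel=1e-8)
        assert sol.reaction_residual < 1e-8
        assert np.all(sol.energy_density >= 0)

    def test_nonnegative_energy_and_strain_energy_density_accessor(self):
        mesh, sol, _ = _uniaxial_patch()
        assert np.array_equal(strain_energy_density(sol, mesh), sol.energy_density)

    def test_free_mode_leaves_edges_loose(self, reduced_mesh, materials):
        """Constrained mode suppresses lateral edge motion; free mode allows it."""
        rho = np.full(int(reduced_mesh.trabecular_mask.sum()), 0.8)
        ux_edge = {}
        for mode in ("constrained", "free"):
            sol = assemble_and_solve(
                reduced_mesh, materials, rho, LoadCase(bc_mode=mode))
            edge = reduced_mesh.node_sets["left_edge"]
            ux_edge[mode] = np.abs(sol.displacements[edge, 0]).max()
        assert ux_edge["constrained"] < 1e-14
        assert ux_edge["free"] > 1e-6
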