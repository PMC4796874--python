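"""Linearized PB solver: analytic oracles, focusing, and invariants."""

import numpy as np
import pytest

import focuswalk as fw
from focuswalk.errors import ConvergenceError, FocusingError, OutOfGridError


def _uniform_problem(structure, edge, resolution, eps, ionic_strength=0.0,
                     boundary="coulombic_debye", stern=0.0):
    physics = fw.PBPhysics(eps_in=eps, eps_out=eps, ionic_strength=ionic_strength,
                           stern=stern)
    grid = fw.make_grid(structure, resolution, edge=edge)
    return fw.build_problem(structure, grid, physics, boundary=boundary,
                            uniform_eps=eps), physics


class TestSolveLinearPB:
    def test_no_charge_zero_boundary_gives_zero_potential(self, born_ion):
        neutral = fw.make_born_ion(0.0, 2.0)
        problem, _ = _uniform_problem(neutral, 16.0, 1.0, 80.0, boundary="zero")
        field = fw.solve_linear_pb(problem)
        assert np.all(field.values == 0.0)

    def test_single_charge_follows_coulomb_1_over_r(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 24.0, 1.0, 80.0)
        field = fw.solve_linear_pb(problem)
        p5, p10 = fw.site_potentials(field, [[5, 0, 0], [10, 0, 0]])
        assert p5 / p10 == pytest.approx(2.0, rel=0.05)

    def test_screened_charge_matches_debye_hueckel(self):
        # point-like source so the grid is effectively uniform everywhere
        ion = fw.make_born_ion(1.0, 0.1)
        problem, physics = _uniform_problem(ion, 24.0, 2.0, 80.0, ionic_strength=0.15)
        field = fw.solve_linear_pb(problem)
        kappa = fw.debye_kappa(0.15, physics.temperature, 80.0)
        amp = fw.coulomb_kt(physics.temperature) / 80.0
        for r in (5.0, 8.0):
            phi = fw.site_potentials(field, [[r, 0, 0]])[0]
            assert phi == pytest.approx(amp * np.exp(-kappa * r) / r, rel=0.05)

    def test_agrees_with_independent_sparse_direct_solve(self, rng):
        """Oracle: assemble the 7-point system explicitly and solve it exactly."""
        from scipy.sparse import lil_matrix
        from scipy.sparse.linalg import spsolve

        n = 9
        s = fw.from_arrays(rng.uniform(-1.5, 1.5, size=(4, 3)),
                           charges=rng.uniform(-1, 1, size=4),
                           radii=np.full(4, 1.2))
        grid = fw.GridSpec(origin=(-4, -4, -4), spacing=1.0, dims=(n, n, n))
        physics = fw.PBPhysics(eps_in=2.0, eps_out=80.0, ionic_strength=0.1, stern=1.0)
        problem = fw.build_problem(s, grid, physics, boundary="coulombic_debye")
        field = fw.solve_linear_pb(problem, tol=1e-10, max_iter=50000)

        # independent assembly from the problem definition
        import math
        from focuswalk import constants

        c = constants.coulomb_kt(physics.temperature)
        k2 = (8 * math.pi * c * physics.ionic_strength * constants.MOLAR_TO_PER_A3
              * problem.ion_mask.values)
        ex, ey, ez = (f.values for f in problem.dielectric)
        h = grid.spacing
        interior = [(i, j, k) for i in range(1, n - 1) for j in range(1, n - 1)
                    for k in range(1, n - 1)]
        pos = {ijk: m for m, ijk in enumerate(interior)}
        A = lil_matrix((len(interior), len(interior)))
        b = np.zeros(len(interior))
        phi_b = field.values.copy()  # boundary values only are used below
        for (i, j, k), m in pos.items():
            eps_nb = [
                (ex[i, j, k], (i + 1, j, k)), (ex[i - 1, j, k], (i - 1, j, k)),
                (ey[i, j, k], (i, j + 1, k)), (ey[i, j - 1, k], (i, j - 1, k)),
                (ez[i, j, k], (i, j, k + 1)), (ez[i, j, k - 1], (i, j, k - 1)),
            ]
            diag = sum(e for e, _ in eps_nb) + k2[i, j, k] * h * h
            A[m, m] = diag
            b[m] += 4 * math.pi * c * problem.charge.values[i, j, k] / h
            for e, nb in eps_nb:
                if nb in pos:
                    A[m, pos[nb]] -= e
                else:
                    b[m] += e * phi_b[nb]
        exact = spsolve(A.tocsr(), b)
        ours = np.array([field.values[ijk] for ijk in interior])
        np.testing.assert_allclose(ours, exact, rtol=1e-6, atol=1e-9)

    def test_superposition_linearity(self, rng):
        a = fw.from_arrays([[-3, 0, 0]], charges=[1.0], radii=[0.5])
        b = fw.from_arrays([[3, 0, 0]], charges=[-0.5], radii=[0.5])
        both = fw.from_arrays([[-3, 0, 0], [3, 0, 0]], charges=[1.0, -0.5],
                              radii=[0.5, 0.5])
        fields = []
        for s in (a, b, both):
            grid = fw.GridSpec(origin=(-12, -12, -12), spacing=1.0, dims=(25, 25, 25))
            problem = fw.build_problem(
                s, grid, fw.PBPhysics(eps_in=80, eps_out=80, ionic_strength=0.0),
                uniform_eps=80.0)
            fields.append(fw.solve_linear_pb(problem, tol=1e-8).values)
        np.testing.assert_allclose(fields[0] + fields[1], fields[2], atol=1e-4)

    def test_centered_charge_field_has_octahedral_symmetry(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        v = fw.solve_linear_pb(problem, tol=1e-8).values
        for sym in (v[::-1, :, :], v.transpose(1, 0, 2), v.transpose(2, 1, 0)):
            np.testing.assert_allclose(v, sym, atol=1e-10)

    def test_salt_never_increases_potential_magnitude(self, born_ion):
        values = []
        for ionic in (0.0, 0.05, 0.3):
            problem, _ = _uniform_problem(born_ion, 24.0, 1.0, 80.0,
                                          ionic_strength=ionic)
            values.append(fw.solve_linear_pb(problem).values)
        assert np.all(values[1] <= values[0] + 1e-12)
        assert np.all(values[2] <= values[1] + 1e-12)

    def test_nonconvergence_raises_with_residual_history(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        with pytest.raises(ConvergenceError) as err:
            fw.solve_linear_pb(problem, tol=1e-14, max_iter=6)
        assert len(err.value.residual_history) > 0


class TestSitePotentials:
    def test_point_on_node_returns_node_value(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        f = fw.solve_linear_pb(problem)
        assert fw.site_potentials(f, [[4.0, 0.0, 0.0]])[0] == pytest.approx(
            f.values[12, 8, 8], abs=1e-12
        )

    def test_constant_field_interpolates_to_the_constant(self):
        grid = fw.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(6, 6, 6))
        field = fw.PotentialField(
            field=fw.ScalarField(grid, np.full((6, 6, 6), 3.25), "potential"),
            residual=0.0)
        pts = [[0.3, 2.7, 4.9], [1, 1, 1]]
        np.testing.assert_allclose(fw.site_potentials(field, pts), 3.25, atol=1e-12)

    def test_out_of_grid_point_error_names_the_index(self):
        grid = fw.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(6, 6, 6))
        field = fw.PotentialField(
            field=fw.ScalarField(grid, np.zeros((6, 6, 6)), "potential"),
            residual=0.0)
        with pytest.raises(OutOfGridError, match="index 1"):
            fw.site_potentials(field, [[1, 1, 1], [99, 0, 0]])


class TestFocusing:
    def test_identity_focusing_reproduces_parent_interior(self, born_ion):
        problem, physics = _uniform_problem(born_ion, 32.0, 1.0, 80.0)
        parent = fw.solve_linear_pb(problem, tol=1e-8)
        child = fw.focus(parent, born_ion, physics, (0, 0, 0), 30.0, 1.0,
                         tol=1e-8, uniform_eps=80.0)
        pts = child.grid.grid_to_world(
            np.argwhere(np.ones(child.grid.dims, bool)))
        parent_vals = fw.site_potentials(parent, pts).reshape(child.grid.dims)
        np.testing.assert_allclose(child.values, parent_vals, atol=2e-4)

    def test_child_matches_global_fine_solve(self, born_ion):
        """Focused child vs direct fine-grid brute force, away from the charge."""
        physics = fw.PBPhysics(eps_in=80, eps_out=80, ionic_strength=0.0, stern=0.0)
        coarse = fw.build_problem(
            born_ion, fw.make_grid(born_ion, 1.0, edge=48.0), physics,
            uniform_eps=80.0)
        parent = fw.solve_linear_pb(coarse)
        child = fw.focus(parent, born_ion, physics, (0, 0, 0), 24.0, 2.0,
                         uniform_eps=80.0)
        fine = fw.solve_linear_pb(fw.build_problem(
            born_ion, fw.make_grid(born_ion, 2.0, edge=48.0, dims_cap=129),
            physics, uniform_eps=80.0))
        idx = np.argwhere(np.ones(child.grid.dims, bool))
        pts = child.grid.grid_to_world(idx)
        r = np.linalg.norm(pts, axis=1)
        interior = np.all((idx > 0) & (idx < np.array(child.grid.dims) - 1), axis=1)
        sel = interior & (r > 4.0)
        ours = child.values.ravel()[np.flatnonzero(sel)]
        ref = fw.site_potentials(fine, pts[sel])
        assert np.max(np.abs(ours - ref) / np.abs(ref)) < 0.03

    def test_child_level_increments_and_nesting_works(self, born_ion):
        problem, physics = _uniform_problem(born_ion, 32.0, 1.0, 80.0)
        parent = fw.solve_linear_pb(problem)
        child = fw.focus(parent, born_ion, physics, (0, 0, 0), 20.0, 1.0,
                         uniform_eps=80.0)
        grandchild = fw.focus(child, born_ion, physics, (0, 0, 0), 10.0, 2.0,
                              uniform_eps=80.0)
        assert (parent.level, child.level, grandchild.level) == (0, 1, 2)

    def test_child_outside_parent_raises_containment_error(self, born_ion):
        problem, physics = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        parent = fw.solve_linear_pb(problem)
        with pytest.raises(FocusingError):
            fw.focus(parent, born_ion, physics, (10, 0, 0), 16.0, 2.0,
                     uniform_eps=80.0)

    def test_coarser_child_resolution_is_rejected(self, born_ion):
        problem, physics = _uniform_problem(born_ion, 16.0, 2.0, 80.0)
        parent = fw.solve_linear_pb(problem)
        with pytest.raises(FocusingError):
            fw.focus(parent, born_ion, physics, (0, 0, 0), 8.0, 1.0,
                     uniform_eps=80.0)


class TestEnergies:
    def test_zero_charges_give_exactly_zero_solvation(self):
        neutral = fw.make_born_ion(0.0, 2.0)
        dg = fw.reaction_field_energy(
            neutral, fw.PBPhysics(eps_in=1.0, eps_out=80.0, ionic_strength=0.0),
            resolution=1.0, edge=16.0)
        assert dg == 0.0

    def test_born_ion_solvation_matches_analytic_formula(self, born_ion):
        physics = fw.PBPhysics(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
        dg = fw.reaction_field_energy(born_ion, physics, resolution=2.0, edge=24.0)
        analytic = -(332.0637 / (2 * 2.0)) * (1 / 1.0 - 1 / 80.0)
        assert dg == pytest.approx(analytic, rel=0.10)

    def test_born_energy_scales_as_charge_squared(self):
        physics = fw.PBPhysics(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
        dg1 = fw.reaction_field_energy(fw.make_born_ion(1.0, 2.0), physics,
                                       resolution=2.0, edge=16.0)
        dg2 = fw.reaction_field_energy(fw.make_born_ion(2.0, 2.0), physics,
                                       resolution=2.0, edge=16.0)
        assert dg2 / dg1 == pytest.approx(4.0, rel=0.02)

    def test_distant_identical_ions_are_energy_additive(self):
        # 40 Å separation; 1 grid/Å keeps both solves small and the grid
        # self-energy cancels within each solvated/reference pair anyway
        physics = fw.PBPhysics(eps_in=1.0, eps_out=80.0, ionic_strength=0.0)
        one = fw.reaction_field_energy(fw.make_born_ion(1.0, 2.0), physics,
                                       resolution=1.0, edge=24.0)
        pair = fw.from_arrays([[-20, 0, 0], [20, 0, 0]], charges=[1.0, 1.0],
                              radii=[2.0, 2.0])
        two = fw.reaction_field_energy(pair, physics, resolution=1.0, edge=64.0,
                                       dims_cap=193)
        assert two == pytest.approx(2 * one, rel=0.10)

    def test_interaction_energy_matches_coulomb_closed_form(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 32.0, 2.0, 80.0)
        field = fw.solve_linear_pb(problem)
        e = fw.interaction_energy_from_field(field, [[10, 0, 0]], [1.0])
        assert e == pytest.approx(332.0637 / (80 * 10), rel=0.05)

    def test_interaction_energy_is_linear_in_ligand_charges(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        field = fw.solve_linear_pb(problem)
        pts = [[4, 0, 0], [0, 5, 0]]
        e_pos = fw.interaction_energy_from_field(field, pts, [0.5, -0.3])
        e_neg = fw.interaction_energy_from_field(field, pts, [-0.5, 0.3])
        assert e_neg == -e_pos

    def test_neutral_ligand_has_zero_interaction(self, born_ion):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        field = fw.solve_linear_pb(problem)
        assert fw.interaction_energy_from_field(field, [[4, 0, 0]], [0.0]) == 0.0


class TestMapsIO:
    def test_npz_container_roundtrip_is_bit_exact(self, born_ion, tmp_path):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        field = fw.solve_linear_pb(problem)
        path = tmp_path / "map.npz"
        fw.save_field(field, path)
        back = fw.load_field(path)
        assert np.array_equal(back.values, field.values)  # bit-exact
        assert back.grid == field.grid
        assert back.level == field.level

    def test_dx_roundtrip_preserves_grid_and_values(self, born_ion, tmp_path):
        problem, _ = _uniform_problem(born_ion, 16.0, 1.0, 80.0)
        field = fw.solve_linear_pb(problem)
        path = tmp_path / "map.dx"
        fw.write_dx(field, path)
        back = fw.read_dx(path)
        assert back.grid.dims == field.grid.dims
        np.testing.assert_allclose(back.values, field.values, rtol=1e-8)
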