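"""Assembly, Newton solve, and schedule-driver checks."""

import numpy as np
import pytest

from atrophyfem.mechanics import MaterialParams
from atrophyfem.mesh import structured_rectangle_mesh
from atrophyfem.scenarios import AtrophySchedule, generalized_schedule
from atrophyfem.solver import (DirichletBC, FEModel, SingularSystemError,
                               SolverSettings, assemble, brainstem_fixation,
                               patch_test, run_schedule, solve_increment)
from atrophyfem.verification import (_rigid_mode_bcs, consistency_check,
                                     free_shrink_check, newton_rate_check)


@pytest.fixture(scope="module")
def square(material):
    mesh = structured_rectangle_mesh(50.0, 50.0, 6, 6)
    return mesh, FEModel(mesh, material)


class TestAssemble:
    def test_unloaded_reference_residual_is_zero(self, square):
        mesh, model = square
        R, K = model.assemble(np.zeros((mesh.n_nodes, 2)),
                              np.ones(mesh.n_elements))
        assert np.all(R == 0.0)
        assert K.shape == (2 * mesh.n_nodes, 2 * mesh.n_nodes)

    def test_residual_is_energy_gradient(self, material):
        report = consistency_check(material)
        assert report["residual_vs_energy_grad_rel"] <= 1e-6

    def test_tangent_is_residual_jacobian(self, material):
        report = consistency_check(material)
        assert report["tangent_vs_fd_rel"] <= 1e-5

    def test_module_level_wrapper(self, square, material):
        mesh, model = square
        R, _ = assemble(mesh, np.zeros((mesh.n_nodes, 2)),
                        np.full(mesh.n_elements, 0.9), material)
        assert R.shape == (2 * mesh.n_nodes,)


class TestSolveIncrement:
    def test_no_atrophy_converges_immediately(self, square):
        mesh, model = square
        state = solve_increment(model, np.zeros((mesh.n_nodes, 2)),
                                np.ones(mesh.n_elements),
                                _rigid_mode_bcs(mesh), SolverSettings())
        assert state.converged
        assert state.newton_iters == 0
        assert np.allclose(state.u, 0.0)

    def test_free_shrink_analytic(self, material):
        report = free_shrink_check(material, upsilon=0.9)
        assert report["passed"], report

    def test_quadratic_convergence(self, material):
        report = newton_rate_check(material)
        assert report["passed"], report["observed_orders"]

    def test_missing_constraints_raise(self, square):
        mesh, model = square
        with pytest.raises((SingularSystemError, ValueError)):
            solve_increment(model, np.zeros((mesh.n_nodes, 2)),
                            np.full(mesh.n_elements, 0.9), [],
                            SolverSettings())

    def test_dirichlet_values_enforced(self, square):
        mesh, model = square
        bnodes = np.unique(np.vstack(list(mesh.boundary_edges.values())))
        shift = (0.5, -0.25)
        bcs = [DirichletBC(bnodes, value=shift)]
        state = solve_increment(model, np.zeros((mesh.n_nodes, 2)),
                                np.ones(mesh.n_elements), bcs, SolverSettings())
        assert np.allclose(state.u[bnodes], shift, atol=1e-12)
        # rigid translation: stress-free interior
        assert state.von_mises.max() <= 1e-10

    def test_equilibrium_reactions_balance(self, square, material):
        mesh, model = square
        edges = mesh.boundary_edges["brainstem"]
        bcs = [DirichletBC(np.unique(edges))]
        state = solve_increment(model, np.zeros((mesh.n_nodes, 2)),
                                np.full(mesh.n_elements, 0.8), bcs,
                                SolverSettings())
        R = model.residual(state.u, np.full(mesh.n_elements, 0.8))
        scale = np.abs(R).max()
        # with no external loads the total internal force (free residual ≈ 0
        # plus Dirichlet reactions) must vanish componentwise
        net = R.reshape(-1, 2).sum(axis=0)
        assert np.all(np.abs(net) <= 1e-8 * max(scale, 1.0))


class TestPatchTest:
    def test_affine_map_constant_stress(self, material):
        report = patch_test(material)
        assert report["passed"]
        assert report["max_stress_deviation_kpa"] <= 1e-8

    def test_identity_map_zero_stress(self, material):
        report = patch_test(material, strain=0.0)
        assert report["passed"]

    def test_broken_gradients_fail(self, material):
        report = patch_test(material, _distort_gradients=0.05)
        assert not report["passed"]


class TestRunSchedule:
    def test_endpoint_upsilon_values(self, square, material):
        mesh, _ = square
        sched = generalized_schedule(n_increments=4)
        states, _ = run_schedule(mesh, sched, material,
                                 bcs=_rigid_mode_bcs(mesh))
        assert len(states) == 4
        assert np.allclose(
            states[-1].upsilon[mesh.element_region == "gray"], 0.80)
        assert states[-1].time == pytest.approx(48.0)

    def test_deterministic(self, square, material):
        mesh, _ = square
        sched = generalized_schedule(n_increments=3)
        s1, _ = run_schedule(mesh, sched, material, bcs=_rigid_mode_bcs(mesh))
        s2, _ = run_schedule(mesh, sched, material, bcs=_rigid_mode_bcs(mesh))
        assert np.array_equal(s1[-1].u, s2[-1].u)

    def test_path_independence_of_endpoint(self, square, material):
        # elastostatics: the endpoint state is increment-count independent
        mesh, _ = square
        bcs = _rigid_mode_bcs(mesh)
        one, _ = run_schedule(mesh, generalized_schedule(n_increments=1),
                              material, bcs=bcs)
        many, _ = run_schedule(mesh, generalized_schedule(n_increments=8),
                               material, bcs=bcs)
        u1 = np.linalg.norm(one[-1].u, axis=1).max()
        u8 = np.linalg.norm(many[-1].u, axis=1).max()
        assert u1 == pytest.approx(u8, rel=0.01)

    def test_trivial_schedule_keeps_initial_state(self, square, material):
        mesh, _ = square
        sched = AtrophySchedule("generalized", "endpoint", duration=12.0,
                                n_increments=1, entries=())
        states, _ = run_schedule(mesh, sched, material,
                                 bcs=_rigid_mode_bcs(mesh))
        assert np.allclose(states[-1].u, 0.0)

    def test_brainstem_fixation_on_slice(self, coronal_coarse, material):
        bcs = brainstem_fixation(coronal_coarse)
        sched = generalized_schedule(n_increments=2)
        states, _ = run_schedule(coronal_coarse, sched, material, bcs=bcs)
        fixed = np.unique(coronal_coarse.boundary_edges["brainstem"])
        assert np.allclose(states[-1].u[fixed], 0.0)
        assert (states[-1].J > 0).all()
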