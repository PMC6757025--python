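"""Solver verification suite: analytic and discrete consistency oracles.

Each check builds its own small problem and returns a dict with a
``passed`` flag and the measured quantities, so the suite can run from the
command line (``atrophyfem verify``) or from tests:

* free-shrink — a homogeneous square under uniform υ with only rigid modes
  constrained must scale by exactly υ^{1/3} and stay stress-free;
* patch test — constant-stress reproduction under affine boundary data
  (delegated to :func:`atrophyfem.solver.patch_test`);
* finite-difference consistency — the residual is the gradient of the
  stored energy and the tangent its Jacobian;
* Newton rate — residual norms contract superlinearly near the solution;
* annulus oracle — an atrophying core inside a passive ring: in the
  incompressible limit the radial motion is kinematically determined,
  r(R)² = υc^{2/3}A² + R² − A² outside the core and r = υc^{1/3}R inside,
  independent of the stress response. Run at κ/μ = 1000 on a crossed
  (union-jack) polar mesh, which does not volumetrically lock;
* mesh convergence — the annulus displacement error decreases
  monotonically under refinement.
"""

from __future__ import annotations

import numpy as np

from .mechanics import MaterialParams
from .mesh import crossed_disc_mesh, structured_rectangle_mesh
from .solver import (DirichletBC, FEModel, SolverSettings, patch_test,
                     solve_increment)

__all__ = [
    "free_shrink_check",
    "consistency_check",
    "newton_rate_check",
    "annulus_check",
    "mesh_convergence_check",
    "run_verification",
]


def _rigid_mode_bcs(mesh):
    """Pin one node fully and the y-component of a node on the same y-line."""
    coords = mesh.node_coords
    i0 = int(np.argmin(np.hypot(coords[:, 0] - coords[:, 0].min(),
                                coords[:, 1] - coords[:, 1].min())))
    same_row = np.nonzero(np.isclose(coords[:, 1], coords[i0, 1]))[0]
    i1 = same_row[int(np.argmax(coords[same_row, 0]))]
    return [DirichletBC(np.array([i0])),
            DirichletBC(np.array([i1]), components=(False, True))]


def free_shrink_check(params: MaterialParams | None = None,
                      upsilon: float = 0.5, size: float = 100.0,
                      n: int = 10) -> dict:
    """Uniform atrophy of a free homogeneous square: exact υ^{1/3} scaling."""
    params = params or MaterialParams()
    mesh = structured_rectangle_mesh(size, size, n, n)
    model = FEModel(mesh, params)
    ups = np.full(mesh.n_elements, upsilon)
    state = solve_increment(model, np.zeros((mesh.n_nodes, 2)), ups,
                            _rigid_mode_bcs(mesh), SolverSettings())
    x = mesh.node_coords + state.u
    ratio = (x[:, 0].max() - x[:, 0].min()) / size
    expected = upsilon ** (1.0 / 3.0)
    vm_max = float(state.von_mises.max())
    mu = min(params.mu_gray, params.mu_white)
    return {
        "name": "free-shrink",
        "passed": bool(abs(ratio - expected) <= 1e-4 and vm_max <= 1e-6 * mu),
        "side_ratio": float(ratio),
        "expected_ratio": float(expected),
        "max_von_mises_kpa": vm_max,
    }


def consistency_check(params: MaterialParams | None = None,
                      upsilon: float = 0.9, seed: int = 0) -> dict:
    """Residual = FD gradient of energy; tangent = FD Jacobian of residual."""
    params = params or MaterialParams()
    mesh = structured_rectangle_mesh(2.0, 2.0, 2, 2)
    model = FEModel(mesh, params)
    rng = np.random.default_rng(seed)
    u = rng.normal(scale=0.02, size=(mesh.n_nodes, 2))
    ups = np.full(mesh.n_elements, upsilon)
    R, K = model.assemble(u, ups)
    h = 1e-6
    ndof = model.ndof
    grad = np.empty(ndof)
    Kfd = np.empty((ndof, ndof))
    for i in range(ndof):
        up, um = u.reshape(-1).copy(), u.reshape(-1).copy()
        up[i] += h
        um[i] -= h
        grad[i] = (model.energy(up.reshape(-1, 2), ups)
                   - model.energy(um.reshape(-1, 2), ups)) / (2 * h)
        Kfd[:, i] = (model.residual(up.reshape(-1, 2), ups)
                     - model.residual(um.reshape(-1, 2), ups)) / (2 * h)
    res_err = float(np.linalg.norm(R - grad) / np.linalg.norm(grad))
    tan_err = float(np.linalg.norm(K.toarray() - Kfd) / np.linalg.norm(Kfd))
    return {
        "name": "fd-consistency",
        "passed": bool(res_err <= 1e-6 and tan_err <= 1e-5),
        "residual_vs_energy_grad_rel": res_err,
        "tangent_vs_fd_rel": tan_err,
    }


def newton_rate_check(params: MaterialParams | None = None,
                      upsilon: float = 0.7) -> dict:
    """Superlinear contraction of Newton residual norms near the solution."""
    params = params or MaterialParams()
    mesh = structured_rectangle_mesh(50.0, 50.0, 8, 8)
    model = FEModel(mesh, params)
    ups = np.full(mesh.n_elements, upsilon)
    settings = SolverSettings(newton_rel_tol=1e-12, newton_abs_tol=1e-12,
                              max_newton_iters=40)
    try:
        state = solve_increment(model, np.zeros((mesh.n_nodes, 2)), ups,
                                _rigid_mode_bcs(mesh), settings)
        hist = np.array(state.residual_history)
    except Exception:  # still inspect whatever history exists
        raise
    hist = hist[hist > 0]
    # quadratic convergence: ||r_{k+1}|| ≈ C ||r_k||²; check the observed
    # order over the final contractions exceeds 1.5
    orders = []
    floor = 1e-10 * hist[0]  # below this the norms sit on round-off
    for k in range(len(hist) - 2):
        r0, r1, r2 = hist[k], hist[k + 1], hist[k + 2]
        if r1 < r0 and floor < r2 < r1:
            orders.append(np.log(r2 / r1) / np.log(r1 / r0))
    tail = [o for o in orders[-2:]]
    return {
        "name": "newton-rate",
        "passed": bool(tail and min(tail) > 1.5),
        "residual_history": hist.tolist(),
        "observed_orders": orders,
    }


def annulus_analytic_radius(R: np.ndarray, core_radius: float,
                            upsilon_core: float) -> np.ndarray:
    """Incompressible-limit deformed radius of the core/ring problem."""
    lam = upsilon_core ** (1.0 / 3.0)
    inside = R <= core_radius
    r = np.empty_like(R)
    r[inside] = lam * R[inside]
    r[~inside] = np.sqrt(lam**2 * core_radius**2 + R[~inside] ** 2
                         - core_radius**2)
    return r


def annulus_check(upsilon_core: float = 0.7, core_radius: float = 20.0,
                  outer_radius: float = 40.0, n_r: int = 24,
                  n_theta: int = 64, kappa_ratio: float = 1000.0,
                  mu: float = 2.07, n_steps: int = 3, tol: float = 0.02) -> dict:
    """Atrophying core in a passive ring vs the incompressible-limit solution.

    The FE radial displacement is compared with the semi-analytic area
    bookkeeping r(R)² = υc^{2/3}A² + R² − A²; the relative error is
    normalized by the maximum analytic displacement.
    """
    params = MaterialParams(mu_gray=mu, mu_white=mu, kappa_ratio=kappa_ratio)
    mesh = crossed_disc_mesh(outer_radius, core_radius, n_r=n_r,
                             n_theta=n_theta)
    model = FEModel(mesh, params)
    core = mesh.element_region == "gray"
    # rigid modes: center node fixed, θ=0 node on the first ring held on the axis
    coords = mesh.node_coords
    on_axis = np.nonzero(np.isclose(coords[:, 1], 0.0) & (coords[:, 0] > 0))[0]
    bcs = [DirichletBC(np.array([0])),
           DirichletBC(on_axis, components=(False, True))]
    u = np.zeros((mesh.n_nodes, 2))
    settings = SolverSettings()
    for k in range(1, n_steps + 1):
        ups = np.ones(mesh.n_elements)
        ups[core] = upsilon_core ** (k / n_steps)
        state = solve_increment(model, u, ups, bcs, settings)
        u = state.u
    R = np.hypot(coords[:, 0], coords[:, 1])
    r_fe = np.hypot(*(coords + u).T)
    r_an = annulus_analytic_radius(R, core_radius, upsilon_core)
    u_an = r_an - R
    err = float(np.max(np.abs((r_fe - R) - u_an)) / np.max(np.abs(u_an)))
    return {
        "name": "annulus",
        "passed": bool(err <= tol),
        "max_rel_error": err,
        "tolerance": tol,
        "kappa_ratio": kappa_ratio,
        "n_elements": mesh.n_elements,
    }


def mesh_convergence_check(levels: tuple = ((8, 24), (16, 48), (32, 96))) -> dict:
    """Annulus displacement error decreases monotonically under refinement."""
    errs = []
    for n_r, n_theta in levels:
        errs.append(annulus_check(n_r=n_r, n_theta=n_theta)["max_rel_error"])
    return {
        "name": "mesh-convergence",
        "passed": bool(all(b < a for a, b in zip(errs, errs[1:]))),
        "errors": errs,
    }


def run_verification(params: MaterialParams | None = None) -> list[dict]:
    """Run the full verification battery; returns one report dict per check."""
    params = params or MaterialParams()
    checks = [
        free_shrink_check(params),
        dict(patch_test(params), name="patch-test"),
        consistency_check(params),
        newton_rate_check(params),
        annulus_check(),
        mesh_convergence_check(),
    ]
    return checks
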