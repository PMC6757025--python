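"""Incremental quasi-static equilibrium of the atrophying slice.

The displacement field is the discrete unknown: linear (constant-strain)
triangles with one-point quadrature, for which the centroid rule is exact.
Each pseudo-time increment prescribes a per-element retention factor υ and
solves div(σ) = 0 by Newton's method with a consistent tangent, sparse
direct linear solves, optional backtracking line search, and increment
bisection on non-convergence. The brainstem boundary is fixed in space
(homogeneous Dirichlet); all other nodes move freely.

Dirichlet constraints are eliminated by row/column reduction, so the
unconstrained problem size equals ``mesh.dof_count`` (2 per node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import mechanics
from .mechanics import InvertedElementError, MaterialParams
from .mesh import TriMesh, element_areas
from .scenarios import AtrophySchedule, upsilon_field

__all__ = [
    "DirichletBC",
    "SolverSettings",
    "SystemState",
    "FEModel",
    "assemble",
    "solve_increment",
    "run_schedule",
    "brainstem_fixation",
    "patch_test",
    "NonConvergenceError",
    "SingularSystemError",
]


class NonConvergenceError(RuntimeError):
    def __init__(self, message, increment=None, residual_norm=None,
                 worst_element=None):
        super().__init__(message)
        self.increment = increment
        self.residual_norm = residual_norm
        self.worst_element = worst_element


class SingularSystemError(RuntimeError):
    """Singular tangent; usually missing Dirichlet constraints."""


@dataclass(frozen=True)
class DirichletBC:
    """Prescribed displacement on a node set (optionally per component)."""

    nodes: np.ndarray
    value: tuple = (0.0, 0.0)  # mm
    components: tuple = (True, True)

    def __post_init__(self):
        object.__setattr__(self, "nodes",
                           np.unique(np.asarray(self.nodes, dtype=np.int64)))
        if self.nodes.size == 0:
            raise ValueError("DirichletBC node set is empty")


def brainstem_fixation(mesh: TriMesh) -> list[DirichletBC]:
    """Zero-displacement constraint on all brainstem boundary nodes."""
    edges = mesh.boundary_edges.get("brainstem")
    if edges is None or edges.size == 0:
        raise ValueError("mesh has no brainstem boundary marker to fix")
    return [DirichletBC(nodes=np.unique(edges))]


@dataclass(frozen=True)
class SolverSettings:
    newton_rel_tol: float = 1e-8
    newton_abs_tol: float = 1e-10
    max_newton_iters: int = 25
    max_increment_bisections: int = 3
    max_line_search: int = 8
    linear_solver: str = "sparse-direct"

    def __post_init__(self):
        if self.newton_rel_tol <= 0 or self.newton_abs_tol <= 0:
            raise ValueError("Newton tolerances must be positive")


@dataclass
class SystemState:
    """Converged nodal displacements plus derived element fields."""

    u: np.ndarray                  # (n, 2) mm
    upsilon: np.ndarray            # (m,) retention factor used
    F: np.ndarray                  # (m, 2, 2)
    J: np.ndarray                  # (m,)
    Je: np.ndarray                 # (m,)
    sigma: np.ndarray              # (m, 2, 2) kPa
    von_mises: np.ndarray          # (m,) kPa
    converged: bool = False
    increment: int = 0
    time: float = 0.0              # months
    newton_iters: int = 0
    residual_history: list = field(default_factory=list)


class FEModel:
    """Precomputed element data and assembly kernels for one mesh."""

    def __init__(self, mesh: TriMesh, params: MaterialParams):
        self.mesh = mesh
        self.params = params
        coords = mesh.node_coords
        cells = mesh.elements
        self.area0 = element_areas(cells, coords)
        if np.any(self.area0 <= 0):
            bad = int(np.argmin(self.area0))
            raise ValueError(f"element {bad} has non-positive area")
        p = coords[cells]  # (m, 3, 2)
        # gradients of linear shape functions: grad N_a, constant per element
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        inv_det = 1.0 / (2.0 * self.area0)
        g1 = np.stack([e2[:, 1], -e2[:, 0]], axis=1) * inv_det[:, None]
        g2 = np.stack([-e1[:, 1], e1[:, 0]], axis=1) * inv_det[:, None]
        self.grads = np.stack([-(g1 + g2), g1, g2], axis=1)  # (m, 3, 2)
        self.mu = np.where(mesh.element_region == "gray",
                           params.mu_gray, params.mu_white)
        self.kappa = params.kappa_ratio * self.mu
        # global dof indices of each element's 6 local dofs
        dofs = np.empty((len(cells), 6), dtype=np.int64)
        dofs[:, 0::2] = 2 * cells
        dofs[:, 1::2] = 2 * cells + 1
        self.dofs = dofs
        self.ndof = 2 * mesh.n_nodes

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F = I + Σ_a u_a ⊗ ∇N_a per element; u is (n, 2)."""
        ue = u[self.mesh.elements]  # (m, 3, 2)
        F = np.einsum("nai,naj->nij", ue, self.grads)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        return F

    def lambda_a(self, upsilon: np.ndarray) -> np.ndarray:
        return np.asarray(upsilon, dtype=float) ** (1.0 / 3.0)

    def energy(self, u: np.ndarray, upsilon: np.ndarray) -> float:
        F = self.deformation_gradients(u)
        psi = mechanics.batch_energy(F, self.lambda_a(upsilon), self.mu, self.kappa)
        return float(np.sum(self.area0 * psi))

    def residual(self, u: np.ndarray, upsilon: np.ndarray) -> np.ndarray:
        """Internal-force vector (gradient of the total stored energy)."""
        F = self.deformation_gradients(u)
        P, _, _ = mechanics.batch_pk1_and_tangent(
            F, self.lambda_a(upsilon), self.mu, self.kappa, want_tangent=False)
        fe = np.einsum("n,nij,naj->nai", self.area0, P, self.grads)
        R = np.zeros(self.ndof)
        np.add.at(R, self.dofs, fe.reshape(-1, 6))
        return R

    def assemble(self, u: np.ndarray, upsilon: np.ndarray):
        """Residual vector and consistent sparse tangent matrix."""
        F = self.deformation_gradients(u)
        lam = self.lambda_a(upsilon)
        P, A, _ = mechanics.batch_pk1_and_tangent(F, lam, self.mu, self.kappa)
        fe = np.einsum("n,nij,naj->nai", self.area0, P, self.grads)
        R = np.zeros(self.ndof)
        np.add.at(R, self.dofs, fe.reshape(-1, 6))
        Ke = np.einsum("n,naj,nijkl,nbl->naibk", self.area0, self.grads, A,
                       self.grads).reshape(-1, 6, 6)
        rows = np.repeat(self.dofs, 6, axis=1).ravel()
        cols = np.tile(self.dofs, (1, 6)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(self.ndof, self.ndof)).tocsc()
        return R, K

    def element_state(self, u: np.ndarray, upsilon: np.ndarray,
                      increment: int = 0, time: float = 0.0,
                      converged: bool = True) -> SystemState:
        """Derived per-element fields at the element centroids.

        The reported Cauchy stress keeps the element-wise deviator but
        replaces the in-plane pressure by its area-weighted nodal L2
        projection re-interpolated to the centroid. Low-order displacement
        elements near incompressibility carry a non-physical checkerboard
        pressure mode; the projection removes it without touching the
        equilibrium solution (for a spatially constant stress field the
        recovery is exact).
        """
        F = self.deformation_gradients(u)
        lam = self.lambda_a(upsilon)
        sigma, _ = mechanics.batch_cauchy(F, lam, self.mu, self.kappa)
        p_elem = 0.5 * (sigma[:, 0, 0] + sigma[:, 1, 1])
        p_rec = self._recover_nodal(p_elem)
        shift = p_rec - p_elem
        sigma[:, 0, 0] += shift
        sigma[:, 1, 1] += shift
        s11, s22, s12 = sigma[:, 0, 0], sigma[:, 1, 1], sigma[:, 0, 1]
        pm = (s11 + s22) / 3.0
        vm = np.sqrt(1.5 * ((s11 - pm) ** 2 + (s22 - pm) ** 2 + pm**2
                            + 2 * s12**2))
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        return SystemState(u=u.copy(), upsilon=np.asarray(upsilon, float).copy(),
                           F=F, J=J, Je=J / lam**2, sigma=sigma, von_mises=vm,
                           converged=converged, increment=increment, time=time)

    def _recover_nodal(self, field: np.ndarray) -> np.ndarray:
        """Area-weighted nodal average of an element field, back to centroids."""
        acc = np.zeros(self.mesh.n_nodes)
        wsum = np.zeros(self.mesh.n_nodes)
        for a in range(3):
            np.add.at(acc, self.mesh.elements[:, a], self.area0 * field)
            np.add.at(wsum, self.mesh.elements[:, a], self.area0)
        nodal = acc / np.maximum(wsum, 1e-300)
        return nodal[self.mesh.elements].mean(axis=1)


def assemble(mesh: TriMesh, u: np.ndarray, atrophy, params: MaterialParams):
    """One-shot assembly: (residual, tangent) at displacement u.

    ``atrophy`` is a per-element υ array or an
    :class:`~atrophyfem.mechanics.AtrophyField`.
    """
    ups = getattr(atrophy, "upsilon", atrophy)
    return FEModel(mesh, params).assemble(np.asarray(u, float).reshape(-1, 2), ups)


def _constraint_arrays(ndof: int, bcs: list[DirichletBC]):
    fixed = np.zeros(ndof, dtype=bool)
    values = np.zeros(ndof)
    for bc in bcs:
        for comp in (0, 1):
            if bc.components[comp]:
                idx = 2 * bc.nodes + comp
                fixed[idx] = True
                values[idx] = bc.value[comp]
    return fixed, values


def solve_increment(model: FEModel, u0: np.ndarray, upsilon: np.ndarray,
                    bcs: list[DirichletBC], settings: SolverSettings,
                    increment: int = 0, time: float = 0.0) -> SystemState:
    """Newton solve of one increment, starting from displacement u0."""
    ndof = model.ndof
    fixed, values = _constraint_arrays(ndof, bcs)
    if not fixed.any():
        raise SingularSystemError(
            "no Dirichlet constraints: the tangent is singular (rigid modes); "
            "fix the brainstem or another node set")
    free = ~fixed
    u = np.asarray(u0, float).reshape(-1, 2).copy()
    uf = u.reshape(-1)
    uf[fixed] = values[fixed]
    u = uf.reshape(-1, 2)

    history: list[float] = []
    ref_norm = None
    for it in range(settings.max_newton_iters + 1):
        R, K = model.assemble(u, upsilon)
        rnorm = float(np.linalg.norm(R[free]))
        history.append(rnorm)
        if ref_norm is None:
            ref_norm = rnorm
        if rnorm <= max(settings.newton_abs_tol,
                        settings.newton_rel_tol * ref_norm):
            state = model.element_state(u, upsilon, increment, time, True)
            state.newton_iters = it
            state.residual_history = history
            return state
        if it == settings.max_newton_iters:
            break
        Kff = K[free][:, free]
        try:
            lu = spla.splu(Kff.tocsc())
            du = -lu.solve(R[free])
        except RuntimeError as e:
            raise SingularSystemError(
                f"linear solve failed ({e}); missing Dirichlet constraints "
                "or degenerate tangent") from e
        if not np.all(np.isfinite(du)):
            raise SingularSystemError(
                "linear solve produced non-finite correction; the tangent is "
                "singular — are Dirichlet constraints missing?")
        # backtracking line search: accept the first step that reduces ||R||
        alpha = 1.0
        for ls in range(settings.max_line_search + 1):
            u_try = u.copy()
            u_try.reshape(-1)[free] += alpha * du
            try:
                r_try = float(np.linalg.norm(
                    model.residual(u_try, upsilon)[free]))
            except InvertedElementError:
                r_try = np.inf
            if r_try < rnorm or ls == settings.max_line_search:
                break
            alpha *= 0.5
        if not np.isfinite(r_try):
            break
        u = u_try

    worst = None
    try:
        F = model.deformation_gradients(u)
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        worst = int(np.argmin(J))
    except Exception:
        pass
    raise NonConvergenceError(
        f"Newton did not converge in {settings.max_newton_iters} iterations "
        f"(last residual {history[-1]:.3e})",
        increment=increment, residual_norm=history[-1], worst_element=worst)


def run_schedule(mesh: TriMesh, schedule: AtrophySchedule,
                 params: MaterialParams, bcs: list[DirichletBC] | None = None,
                 settings: SolverSettings | None = None,
                 report_fn=None, store_states: bool = True):
    """Run all increments of an atrophy schedule.

    Returns ``(states, reports)``: one converged :class:`SystemState` per
    scheduled increment (plus reports from ``report_fn(mesh, state)`` if
    given). On non-convergence an increment is bisected recursively up to
    ``settings.max_increment_bisections`` times; only scheduled increments
    are recorded. Deterministic for fixed inputs.
    """
    bcs = brainstem_fixation(mesh) if bcs is None else bcs
    settings = settings or SolverSettings()
    model = FEModel(mesh, params)
    u = np.zeros((mesh.n_nodes, 2))
    states: list[SystemState] = []
    reports = []
    state = None
    t_prev = 0.0
    for k, t in enumerate(schedule.times, start=1):
        u, state = _advance(model, u, schedule, t_prev, t, bcs, settings,
                            increment=k, depth=0)
        state.increment = k
        state.time = t
        if store_states:
            states.append(state)
        if report_fn is not None:
            reports.append(report_fn(mesh, state))
        t_prev = t
    if not store_states and state is not None:
        states.append(state)  # keep at least the final state
    return states, reports


def _advance(model, u, schedule, t0, t1, bcs, settings, increment, depth):
    ups = upsilon_field(schedule, model.mesh, t1)
    try:
        state = solve_increment(model, u, ups, bcs, settings,
                                increment=increment, time=t1)
        return state.u, state
    except NonConvergenceError as e:
        if depth >= settings.max_increment_bisections:
            raise NonConvergenceError(
                f"increment {increment} (t = {t1:.3f} months) failed after "
                f"{depth} bisections: {e}", increment=increment,
                residual_norm=e.residual_norm,
                worst_element=e.worst_element) from e
        tm = 0.5 * (t0 + t1)
        u, _ = _advance(model, u, schedule, t0, tm, bcs, settings,
                        increment, depth + 1)
        return _advance(model, u, schedule, tm, t1, bcs, settings,
                        increment, depth + 1)


# ---------------------------------------------------------------------------
# Patch test
# ---------------------------------------------------------------------------

def patch_test(params: MaterialParams | None = None,
               strain: float = 0.02, _distort_gradients: float = 0.0) -> dict:
    """Constant-stress patch test on a small structured mesh.

    An affine displacement is imposed on every boundary node with υ ≡ 1;
    a correct constant-strain element reproduces a spatially constant
    interior stress field. Returns a dict with ``passed`` and the maximum
    deviation of element stresses from their mean (kPa). The
    ``_distort_gradients`` knob deliberately corrupts the discrete
    gradient operator and exists for testing the test.
    """
    from .mesh import structured_rectangle_mesh

    params = params or MaterialParams()
    mesh = structured_rectangle_mesh(10.0, 10.0, 4, 4)
    A = np.array([[strain, 0.25 * strain], [0.15 * strain, -0.5 * strain]])
    model = FEModel(mesh, params)
    if _distort_gradients:
        model.grads = model.grads * (1.0 + _distort_gradients)
        model.grads[0] += _distort_gradients
    # boundary nodes: those on any boundary edge
    bnodes = np.unique(np.vstack(list(mesh.boundary_edges.values())))
    coords = mesh.node_coords
    ubc = coords[bnodes] @ A.T
    bcs = [DirichletBC(nodes=bnodes[i:i + 1], value=tuple(ubc[i]))
           for i in range(len(bnodes))]
    ups = np.ones(mesh.n_elements)
    state = solve_increment(model, np.zeros_like(coords), ups, bcs,
                            SolverSettings())
    dev = state.sigma - state.sigma.mean(axis=0)
    max_dev = float(np.abs(dev).max())
    return {"passed": bool(max_dev <= 1e-8), "max_stress_deviation_kpa": max_dev,
            "newton_iters": state.newton_iters}
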