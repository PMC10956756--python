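"""Quasi-static incremental Newton solver and tie-link application.

Loads are ramped in ``n_load_steps`` increments; each increment is solved
by damped Newton iteration on the reduced (tie-merged, support-eliminated)
system.  A diverging increment is bisected up to five times before the
solve is reported as a structured failure (``converged=False`` with the
full residual history preserved).
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .assembly import System, _DEGENERATE_DETC
from .errors import ModelError
from .model import FEModel, SimulationResult

__all__ = ["solve_quasi_static", "apply_tie_links"]

_MAX_BISECTIONS = 5
_MAX_LINE_SEARCH = 8
_MINIMIZE_MAXITER = 1200


def _minimize_phase(system: System, u, scale, tol):
    """Energy-minimisation pre-phase (L-BFGS) that carries the very soft
    transverse membrane modes close to equilibrium before Newton polishes
    the residual to tolerance."""

    def fun(ur):
        uu = system.expand(ur)
        e = system.potential_energy(uu, scale)
        r, _ = system.residual_reduced(uu, scale)
        if not np.isfinite(e):
            return 1e30, np.zeros_like(ur)
        return e, r

    u0 = system.P.T @ u.reshape(-1) / np.maximum(
        np.asarray(system.P.sum(axis=0)).ravel(), 1.0
    )
    res = minimize(
        fun,
        u0,
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=_MINIMIZE_MAXITER, ftol=0.0, gtol=100.0 * tol,
                     maxcor=30),
    )
    return system.expand(res.x)


def apply_tie_links(model: FEModel, pairs) -> FEModel:
    """Return a model whose listed node pairs share displacement dofs.

    A pair ``(i, i)`` is a no-op.  Tying two fully fixed nodes separated by
    a nonzero gap raises ``ConstraintConflictError`` (at system build)."""
    out = model.copy()
    n = out.mesh.n_nodes
    for a, b in pairs:
        if not (0 <= a < n and 0 <= b < n):
            raise ModelError(f"tie link ({a}, {b}) references a missing node")
        if a != b:
            out.load_case.tie_links.append((int(a), int(b)))
    # validate eagerly so conflicts surface at application time
    System(out)
    return out


def _solve_linear(K, rhs):
    try:
        du = spla.spsolve(K, rhs)
    except RuntimeError:
        du = np.full(rhs.shape, np.nan)
    if not np.all(np.isfinite(du)):
        # regularise a (near-)singular tangent and retry
        diag = np.abs(K.diagonal())
        mu = 1e-8 * (diag.max() if diag.size else 1.0) + 1e-12
        for _ in range(3):
            du = spla.spsolve(K + mu * sp.identity(K.shape[0], format="csc"), rhs)
            if np.all(np.isfinite(du)):
                break
            mu *= 100.0
    return du


def _newton(system: System, u0, scale, tol, max_iter):
    """Damped Newton at a fixed load scale.  Returns (ok, u, history).

    Steps are accepted by Armijo decrease of the total potential energy
    (the residual is its exact gradient); an indefinite or overly soft
    tangent is Levenberg-regularised until the Newton direction becomes a
    usable descent direction.  Convergence is judged on the residual norm."""
    u = u0.copy()
    history = []
    r_red, min_det = system.residual_reduced(u, scale)
    norm = float(np.linalg.norm(r_red))
    history.append(norm)
    if min_det <= _DEGENERATE_DETC or not np.isfinite(norm):
        return False, u0, history
    energy = system.potential_energy(u, scale)
    mu = 0.0
    for _ in range(max_iter):
        if norm <= tol:
            return True, u, history
        K = system.tangent_reduced(u)
        diag_ref = float(np.abs(K.diagonal()).max()) or 1.0
        accepted = False
        for _try in range(8):
            Kmu = K if mu == 0.0 else (
                K + mu * sp.identity(K.shape[0], format="csc")
            )
            du_red = _solve_linear(Kmu, -r_red)
            slope = float(np.dot(du_red, r_red))
            if not np.all(np.isfinite(du_red)) or slope >= 0.0:
                mu = max(mu * 10.0, 1e-8 * diag_ref)
                continue
            du = system.expand(du_red)
            alpha = 1.0
            for _ls in range(_MAX_LINE_SEARCH):
                u_try = u + alpha * du
                e_try = system.potential_energy(u_try, scale)
                r_try, det_try = system.residual_reduced(u_try, scale)
                norm_try = float(np.linalg.norm(r_try))
                armijo = e_try <= energy + 1e-4 * alpha * slope
                if (
                    np.isfinite(e_try)
                    and np.isfinite(norm_try)
                    and det_try > _DEGENERATE_DETC
                    and (armijo or norm_try <= tol)
                ):
                    u, r_red, norm, energy = u_try, r_try, norm_try, e_try
                    history.append(norm)
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                if alpha == 1.0:
                    mu /= 4.0
                    if mu < 1e-14 * diag_ref:
                        mu = 0.0
                break
            mu = max(mu * 10.0, 1e-8 * diag_ref)
        if not accepted:
            return False, u, history
    return norm <= tol, u, history


def solve_quasi_static(
    model: FEModel,
    initial_displacement: np.ndarray | None = None,
) -> SimulationResult:
    """Solve the model's load case quasi-statically.

    The external loads are applied in ``load_case.n_load_steps`` equal
    increments (warm starts may set ``n_load_steps=1``).  The converged
    flag is honest: it is set only when the final residual norm is at or
    below ``newton_tolerance``.  Displacements of fixed nodes are exactly
    zero by construction of the reduced system."""
    system = System(model)
    lc = model.load_case
    n = model.mesh.n_nodes
    if initial_displacement is not None:
        u = np.array(initial_displacement, dtype=float).reshape(n, 3)
        u = u.copy()
        u[system.fixed_mask] = 0.0
        # project onto the tie-reduced space so shared dofs agree
        u = system.expand(system.P.T @ u.reshape(-1) / np.maximum(
            np.asarray(system.P.sum(axis=0)).ravel(), 1.0))
    else:
        u = np.zeros((n, 3))
    targets = list(np.linspace(0.0, 1.0, lc.n_load_steps + 1)[1:])
    converged_scale = 0.0
    residual_history: list[list[float]] = []
    total_iters = 0
    steps_done = 0
    bisections = 0
    k_target = lc.stabilization
    f_red_norm = float(np.linalg.norm(system.P.T @ system.f_ext.reshape(-1)))
    while targets:
        s = targets[0]
        r0, _ = system.residual_reduced(u, s)
        norm0 = float(np.linalg.norm(r0))
        # "cold" = the state is far from equilibrium relative to the load
        # scale; a warm re-solve (small load change) goes straight to Newton
        cold = norm0 > max(1e3 * lc.newton_tolerance, 0.2 * s * f_red_norm)
        if cold and k_target > 0.0:
            # conditioning continuation: solve with stiffer grounding
            # springs first, then relax them back to the model's value
            stage_tol = max(lc.newton_tolerance, 1e-5)
            for k_level in (100.0 * k_target, 10.0 * k_target):
                system.stabilization = k_level
                _, u, _ = _newton(
                    system, u, s, stage_tol, lc.max_newton_iterations
                )
            system.stabilization = k_target
        ok, u_new, hist = _newton(
            system, u, s, lc.newton_tolerance, lc.max_newton_iterations
        )
        if not ok and cold:
            u_min = _minimize_phase(system, u_new, s, lc.newton_tolerance)
            ok, u_new, hist2 = _newton(
                system, u_min, s, lc.newton_tolerance, lc.max_newton_iterations
            )
            hist = hist + hist2
        total_iters += max(len(hist) - 1, 1)
        if ok:
            u = u_new
            converged_scale = s
            targets.pop(0)
            steps_done += 1
            residual_history.append(hist)
        else:
            residual_history.append(hist)
            if bisections >= _MAX_BISECTIONS:
                return SimulationResult(
                    displacement=u,
                    converged=False,
                    residual_history=residual_history,
                    reactions={},
                    n_steps_completed=steps_done,
                    n_newton_iterations=total_iters,
                    message=(
                        f"no convergence at load scale {s:.4g} after "
                        f"{_MAX_BISECTIONS} bisections"
                    ),
                )
            bisections += 1
            targets.insert(0, 0.5 * (converged_scale + s))
    # reactions: residual of the unconstrained equations at the supports
    r_full, _ = system.residual_full(u, 1.0)
    reactions = {}
    for fs in lc.fixed:
        ids = model.mesh.node_sets[fs.node_set]
        mask = np.zeros((n, 3), dtype=bool)
        for c in fs.component_indices():
            mask[ids, c] = True
        reactions[fs.node_set] = reactions.get(fs.node_set, np.zeros(3)) + (
            np.where(mask, r_full, 0.0).sum(axis=0)
        )
    return SimulationResult(
        displacement=u,
        converged=True,
        residual_history=residual_history,
        reactions=reactions,
        n_steps_completed=steps_done,
        n_newton_iterations=total_iters,
        message="converged",
    )
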