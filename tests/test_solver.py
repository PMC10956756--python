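"""Quasi-static solver oracles: patch tests, tie links, equilibrium."""
import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.spatial.transform import Rotation

from pelvifem.constitutive import uniaxial_membrane_stress
from pelvifem.errors import ConstraintConflictError, ModelError
from pelvifem.materials import MaterialModel
from pelvifem.model import FixedSet, LoadCase, sum_applied_forces
from pelvifem.solver import apply_tie_links, solve_quasi_static

from conftest import make_mesh, make_model, random_patch_model

ORGANS = [
    MaterialModel.yeoh(0.111, 0.27),
    MaterialModel.yeoh(0.0375, 0.07),
    MaterialModel.yeoh(0.085, 0.056),
]


def square_membrane_model(material, thickness=1.0, L=10.0):
    """Unit square membrane (2 CSTs), left edge on rollers, pulled in +x."""
    nodes = [[0, 0, 0], [L, 0, 0], [L, L, 0], [0, L, 0]]
    mesh = make_mesh(
        nodes,
        tris=[(0, 1, 2), (0, 2, 3)],
        tri_labels=["membrane", "membrane"],
        tri_thickness=thickness,
        node_sets={
            "left": [0, 3],
            "right": [1, 2],
            "origin": [0],
            "plane": [0, 1, 2, 3],
        },
    )
    model = make_model(mesh, materials={"membrane": material})
    model.load_case.fixed = [
        FixedSet("left", "x"),
        FixedSet("origin", "y"),
        FixedSet("plane", "z"),
    ]
    return model


class TestUniaxialPatchTest:
    @pytest.mark.parametrize("mat", ORGANS)
    def test_matches_closed_form_inversion(self, mat):
        """A homogeneous uniaxial membrane state must invert the closed-form
        Yeoh stress law to 1e-4 relative."""
        L, t = 10.0, 1.0
        model = square_membrane_model(mat, thickness=t, L=L)
        F_total = 0.08 * L * t  # nominal traction 0.08 MPa
        forces = np.zeros((4, 3))
        forces[1] = forces[2] = (F_total / 2.0, 0.0, 0.0)
        model.load_case.nodal_forces = forces
        model.load_case.n_load_steps = 4
        res = solve_quasi_static(model)
        assert res.converged
        P_nominal = F_total / (L * t)
        lam_exact = brentq(
            lambda lam: uniaxial_membrane_stress(lam, mat) / lam - P_nominal,
            1.0 + 1e-9,
            3.0,
            xtol=1e-13,
        )
        lam_fe = 1.0 + res.displacement[[1, 2], 0].mean() / L
        assert lam_fe == pytest.approx(lam_exact, rel=1e-4)
        # free lateral contraction: lam2 = 1/sqrt(lam)
        lam2_fe = 1.0 + (res.displacement[2, 1] - res.displacement[1, 1]) / L
        assert lam2_fe == pytest.approx(lam_exact**-0.5, rel=1e-4)


class TestTrussSolve:
    def test_linear_truss_force_displacement(self):
        E, A, L, F = 200.0, 0.5, 20.0, 4.0
        mesh = make_mesh(
            [[0, 0, 0], [0, 0, L]],
            trusses=[(0, 1)],
            truss_area=A,
            tension_only=False,
            node_sets={"base": [0], "tip": [1]},
        )
        model = make_model(
            mesh, materials={"wire": MaterialModel.linear_elastic(E, 0.3)}
        )
        forces = np.zeros((2, 3))
        forces[1, 2] = F
        model.load_case.nodal_forces = forces
        model.load_case.fixed = [FixedSet("base")]
        # pin the transverse dofs of the tip (a single truss has none)
        model.load_case.fixed.append(FixedSet("tip", "xy"))
        res = solve_quasi_static(model)
        assert res.converged
        lam = 1.0 + res.displacement[1, 2] / L
        assert E * A * (lam - 1.0) == pytest.approx(F, rel=1e-6)


class TestSolverContracts:
    def test_zero_load_converges_immediately_with_zero_field(self):
        model = random_patch_model(0)
        model.load_case.nodal_forces[:] = 0.0
        model.load_case.fixed = [FixedSet("edge")]
        res = solve_quasi_static(model)
        assert res.converged
        assert res.n_newton_iterations == res.n_steps_completed  # one per step
        assert np.abs(res.displacement).max() == 0.0

    def test_fixed_nodes_have_exactly_zero_displacement(self):
        model = random_patch_model(1)
        model.load_case.fixed = [FixedSet("edge")]
        res = solve_quasi_static(model)
        assert res.converged
        edge = model.mesh.node_sets["edge"]
        assert np.all(res.displacement[edge] == 0.0)

    def test_converged_residual_below_tolerance(self):
        model = random_patch_model(2)
        model.load_case.fixed = [FixedSet("edge")]
        res = solve_quasi_static(model)
        assert res.converged
        assert res.residual_history[-1][-1] <= model.load_case.newton_tolerance

    def test_global_equilibrium_of_reactions(self):
        """Reaction resultant balances the applied loads at convergence."""
        model = random_patch_model(3)
        model.load_case.fixed = [FixedSet("edge")]
        res = solve_quasi_static(model)
        assert res.converged
        total_reaction = sum(res.reactions.values())
        applied = sum_applied_forces(model.mesh, model.load_case)
        assert np.allclose(total_reaction + applied, 0.0, atol=1e-6)

    def test_structured_failure_on_hopeless_load(self):
        model = random_patch_model(4)
        model.load_case.fixed = [FixedSet("edge")]
        model.load_case.nodal_forces *= 1e9
        model.load_case.max_newton_iterations = 5
        res = solve_quasi_static(model)
        assert not res.converged
        assert res.residual_history  # trace preserved
        assert "bisection" in res.message or "convergence" in res.message

    def test_solution_objectivity_under_rotation(self):
        """Rotating the reference mesh and the loads rotates the converged
        displacement field (1e-6 mm)."""
        model = random_patch_model(5)
        # fix the whole perimeter so the equilibrium is unique; load the
        # interior node against the membrane and the stay wire
        perim = np.array([0, 1, 2, 3, 5, 6, 7, 8, 9])
        model.mesh.node_sets["perimeter"] = perim
        model.load_case.fixed = [FixedSet("perimeter")]
        model.mesh.tri_pretension = np.full(len(model.mesh.tri_nodes), 0.02)
        model.load_case.nodal_forces[:] = 0.0
        model.load_case.nodal_forces[4] = (0.004, -0.003, 0.02)
        res = solve_quasi_static(model)
        R = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        rot = model.copy()
        rot.mesh.nodes = model.mesh.nodes @ R.T
        rot.load_case.nodal_forces = model.load_case.nodal_forces @ R.T
        res_rot = solve_quasi_static(rot)
        assert res.converged and res_rot.converged
        assert np.allclose(
            res_rot.displacement, res.displacement @ R.T, atol=1e-6
        )


class TestTieLinks:
    def spring_chain(self, tie=False):
        """1-D oracle: two colinear trusses; tying the middle pair merges
        them into a series chain solvable by hand."""
        nodes = [[0, 0, 0], [0, 0, 10], [0, 0, 10], [0, 0, 20]]
        mesh = make_mesh(
            nodes,
            trusses=[(0, 1), (2, 3)],
            truss_area=1.0,
            tension_only=False,
            node_sets={"base": [0], "top": [3], "all": [0, 1, 2, 3]},
        )
        model = make_model(
            mesh, materials={"wire": MaterialModel.linear_elastic(100.0, 0.3)}
        )
        forces = np.zeros((4, 3))
        forces[3, 2] = 2.0
        model.load_case.nodal_forces = forces
        model.load_case.fixed = [FixedSet("base"), FixedSet("all", "xy")]
        if tie:
            model = apply_tie_links(model, [(1, 2)])
        return model

    def test_tied_chain_matches_hand_solution(self):
        # series of two k = EA/L springs -> tip u = F*(1/k1 + 1/k2)
        model = self.spring_chain(tie=True)
        res = solve_quasi_static(model)
        assert res.converged
        k = 100.0 * 1.0 / 10.0
        assert res.displacement[3, 2] == pytest.approx(2.0 * 2.0 / k, rel=1e-9)
        # tied pair shares its displacement exactly
        gap = res.displacement[1] - res.displacement[2]
        assert np.linalg.norm(gap) <= 1e-9

    def test_tie_to_self_is_noop(self):
        model = self.spring_chain(tie=False)
        tied = apply_tie_links(model, [(1, 1)])
        assert tied.load_case.tie_links == []

    def test_tying_two_fixed_nodes_with_gap_conflicts(self):
        model = self.spring_chain(tie=False)
        model.load_case.fixed = [FixedSet("base"), FixedSet("top")]
        with pytest.raises(ConstraintConflictError):
            apply_tie_links(model, [(0, 3)])

    def test_missing_node_rejected(self):
        model = self.spring_chain(tie=False)
        with pytest.raises(ModelError):
            apply_tie_links(model, [(0, 99)])


class TestPressurisedCircularMembrane:
    def test_center_deflection_matches_axisymmetric_oracle(self):
        """Uniformly pressurised clamped circular membrane (the Hencky
        problem).  The oracle is an independent 1-D axisymmetric
        Foppl-membrane energy minimisation; agreement within 5%."""
        E, nu, t, a, q = 10.0, 0.3, 0.5, 20.0, 2e-3

        # --- 1-D oracle: minimise the axisymmetric membrane energy
        n = 400
        r = np.linspace(0.0, a, n + 1)
        dr = r[1] - r[0]
        rm = 0.5 * (r[1:] + r[:-1])
        C = E * t / (1.0 - nu * nu)

        A = 2 * np.pi * rm * dr

        def split(x):
            u = np.concatenate(([0.0], x[: n - 1], [0.0]))
            w = np.concatenate((x[n - 1 :], [0.0]))
            return u, w

        def energy(x):
            u, w = split(x)
            du = np.diff(u) / dr
            dw = np.diff(w) / dr
            er = du + 0.5 * dw * dw
            et = 0.5 * (u[1:] + u[:-1]) / rm
            wm = 0.5 * (w[1:] + w[:-1])
            dens = 0.5 * C * (er * er + et * et + 2.0 * nu * er * et)
            val = float(np.sum(A * (dens - q * wm)))
            # analytic gradient
            Nr = C * (er + nu * et)
            Nt = C * (et + nu * er)
            gu = np.zeros(n + 1)
            gw = np.zeros(n + 1)
            np.add.at(gu, np.arange(1, n + 1), A * (Nr / dr + Nt / (2 * rm)))
            np.add.at(gu, np.arange(0, n), A * (-Nr / dr + Nt / (2 * rm)))
            np.add.at(gw, np.arange(1, n + 1), A * (Nr * dw / dr - 0.5 * q))
            np.add.at(gw, np.arange(0, n), A * (-Nr * dw / dr - 0.5 * q))
            grad = np.concatenate((gu[1:n], gw[:n]))
            return val, grad

        x0 = np.zeros(2 * n - 1)
        x0[n - 1 :] = 2.5 * (1 - (r[:-1] / a) ** 2)  # parabolic seed
        sol = minimize(energy, x0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=50000, maxfun=50000,
                                    ftol=1e-18, gtol=1e-12))
        w0_oracle = sol.x[n - 1]

        # --- 3-D membrane solve
        from pelvifem._primitives import basin_surface

        verts, faces, meta = basin_surface((0.0, 0.0), a, a, 0.0, 0.0, 2.0)
        mesh = make_mesh(
            verts,
            tris=faces,
            tri_thickness=t,
            node_sets={"rim": meta["border"], "center": [0]},
        )
        model = make_model(
            mesh, materials={"membrane": MaterialModel.linear_elastic(E, nu)}
        )
        area = mesh.nodal_membrane_area()
        forces = np.zeros((mesh.n_nodes, 3))
        forces[:, 2] = -q * area
        model.load_case.nodal_forces = forces
        model.load_case.fixed = [FixedSet("rim")]
        model.load_case.n_load_steps = 5
        model.load_case.max_newton_iterations = 80
        model.load_case.stabilization = 1e-8
        res = solve_quasi_static(model)
        assert res.converged
        w0_fe = -res.displacement[0, 2]
        assert w0_fe == pytest.approx(w0_oracle, rel=0.05)
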