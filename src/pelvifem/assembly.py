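"""Total-Lagrangian assembly of internal forces, energy, residual and tangent.

Membranes are constant-strain triangles with a plane-stress constitutive
update (incompressible Yeoh or St. Venant-Kirchhoff); trusses carry
``E*A*(lam-1)`` along the current axis, optionally tension-only.  The
residual is the analytic gradient of the total potential energy; the
tangent is assembled from central finite differences of the batched
element force vectors, which keeps the two consistent by construction.
"""
from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import ConstraintConflictError, ModelError
from .model import FEModel, FEMesh, LoadCase

__all__ = ["System", "assemble_residual", "total_potential_energy"]

_DEGENERATE_DETC = 1e-12
_FD_STEP = 1e-5  # mm, tangent finite-difference half-step
# C2 smoothing width (strain) of the tension-only kink; keeps the Newton
# tangent consistent where filaments flip between slack and taut
_SLACK_EPS = 1e-3


def _smooth_tension_strain(strain):
    """0.5*(e + sqrt(e^2 + eps^2)): ~e in tension, ~0 when slack, C2."""
    return 0.5 * (strain + np.sqrt(strain * strain + _SLACK_EPS**2))


def _smooth_tension_energy(strain):
    """Antiderivative pair of EA * smooth strain (per unit EA*L0)."""
    e = _SLACK_EPS
    rt = np.sqrt(strain * strain + e * e)
    return 0.25 * (strain * strain + strain * rt + e * e * np.arcsinh(strain / e))


def _unit_rows(v):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n, n[..., 0]


class System:
    """Precomputed arrays for one FEModel; all heavy math happens here."""

    def __init__(self, model: FEModel):
        self.model = model
        mesh = model.mesh
        mesh.validate()
        self.mesh = mesh
        self.n_nodes = mesh.n_nodes
        self.ndof = 3 * self.n_nodes
        # grounding-spring stiffness; the solver may raise it temporarily
        # as a conditioning continuation and relax it back to the model's
        self.stabilization = model.load_case.stabilization
        self._setup_membranes()
        self._setup_trusses()
        self._setup_constraints()
        self._setup_external()
        # stabilization weight: tributary membrane area, so the grounding
        # foundation is mesh-refinement invariant; area-less nodes (truss
        # chains, bone anchors) get the median weight
        w = mesh.nodal_membrane_area()
        if np.any(w > 0):
            w = np.where(w > 0, w, np.median(w[w > 0]))
        else:
            w = np.ones(self.n_nodes)
        self.stab_weight = w[:, None]

    # -- precomputation ---------------------------------------------------
    def _setup_membranes(self):
        mesh = self.mesh
        conn = mesh.tri_nodes
        self.tri_conn = conn
        m = conn.shape[0]
        if m == 0:
            self.tri_A0 = np.zeros(0)
            return
        P = mesh.nodes[conn]                       # (m, 3, 3)
        e1 = P[:, 1] - P[:, 0]
        e2 = P[:, 2] - P[:, 0]
        t1, l1 = _unit_rows(e1)
        nrm = np.cross(e1, e2)
        self.tri_A0 = 0.5 * np.linalg.norm(nrm, axis=1)
        n_hat, _ = _unit_rows(nrm)
        t2 = np.cross(n_hat, t1)
        # Reference in-plane edge matrix Dm (upper triangular) and inverse
        a = l1
        b = np.einsum("ij,ij->i", e2, t1)
        c = np.einsum("ij,ij->i", e2, t2)
        det = a * c
        Minv = np.empty((m, 2, 2))
        Minv[:, 0, 0] = c / det
        Minv[:, 0, 1] = -b / det
        Minv[:, 1, 0] = 0.0
        Minv[:, 1, 1] = a / det
        self.tri_Minv = Minv
        self.tri_thick = mesh.tri_thickness
        # material arrays
        from .materials import resolve_material

        kinds = np.empty(m, dtype=bool)  # True -> yeoh
        C0 = np.zeros(m); C1 = np.zeros(m); E = np.zeros(m); nu = np.zeros(m)
        for i, label in enumerate(mesh.tri_structure):
            mat = resolve_material(str(label), self.model.materials)
            if mat.kind == "yeoh":
                kinds[i] = True
                C0[i], C1[i] = mat.C0, mat.C1
            else:
                kinds[i] = False
                E[i], nu[i] = mat.E, mat.nu
        self.tri_is_yeoh = kinds
        self.tri_C0, self.tri_C1, self.tri_E, self.tri_nu = C0, C1, E, nu
        if mesh.tri_pretension is None:
            self.tri_pre = None
        else:
            pre = np.asarray(mesh.tri_pretension, dtype=float)
            self.tri_pre = pre if np.any(pre) else None

    def _setup_trusses(self):
        mesh = self.mesh
        self.truss_conn = mesh.truss_nodes
        k = self.truss_conn.shape[0]
        if k == 0:
            self.truss_EA = np.zeros(0)
            self.truss_L0 = np.zeros(0)
            self.truss_tension = np.zeros(0, dtype=bool)
            return
        from .materials import resolve_material

        E = np.zeros(k)
        for i, label in enumerate(mesh.truss_structure):
            mat = resolve_material(str(label), self.model.materials)
            E[i] = mat.E if mat.kind == "linear_elastic" else 3.0 * (mat.C0 + mat.C1)
        self.truss_EA = E * mesh.truss_area
        self.truss_L0 = mesh.truss_ref_length
        self.truss_tension = mesh.truss_tension_only

    def _setup_constraints(self):
        mesh, lc = self.mesh, self.model.load_case
        fixed = np.zeros((self.n_nodes, 3), dtype=bool)
        for fs in lc.fixed:
            if fs.node_set not in mesh.node_sets:
                raise ModelError(f"fixed set {fs.node_set!r} missing from mesh")
            ids = mesh.node_sets[fs.node_set]
            for c in fs.component_indices():
                fixed[ids, c] = True
        # union-find over tie pairs (displacement sharing)
        parent = np.arange(self.n_nodes)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in lc.tie_links:
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ModelError(f"tie link ({a}, {b}) references a missing node")
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        for a, b in lc.tie_links:
            both_fixed = fixed[a].all() and fixed[b].all()
            gap = np.linalg.norm(mesh.nodes[a] - mesh.nodes[b])
            if both_fixed and gap > 1e-9:
                raise ConstraintConflictError(
                    f"tie links fixed nodes {a} and {b} with gap {gap:.3g} mm"
                )
        rep = np.array([find(i) for i in range(self.n_nodes)])
        # a group is fixed in a component if any member is
        grp_fixed = np.zeros((self.n_nodes, 3), dtype=bool)
        np.logical_or.at(grp_fixed, rep, fixed)
        self.fixed_mask = grp_fixed[rep]          # per-node effective fixity
        # reduced dof numbering per (group representative, component)
        red_id = -np.ones((self.n_nodes, 3), dtype=np.int64)
        counter = 0
        reps = np.unique(rep)
        for r in reps:
            for c in range(3):
                if not grp_fixed[r, c]:
                    red_id[r, c] = counter
                    counter += 1
        self.n_red = counter
        rows, cols = [], []
        for c in range(3):
            cid = red_id[rep, c]
            keep = cid >= 0
            rows.append(np.nonzero(keep)[0] * 3 + c)
            cols.append(cid[keep])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        self.P = sp.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(self.ndof, self.n_red)
        )

    def _setup_external(self):
        mesh, lc = self.mesh, self.model.load_case
        area = mesh.nodal_membrane_area()
        f = np.zeros((self.n_nodes, 3))
        for t in lc.tractions:
            if t.node_set not in mesh.node_sets:
                raise ModelError(f"traction set {t.node_set!r} missing from mesh")
            ids = mesh.node_sets[t.node_set]
            f[ids] += t.magnitude * area[ids, None] * t.dir_array()[None, :]
        if lc.nodal_forces is not None:
            f = f + np.asarray(lc.nodal_forces, dtype=float)
        self.f_ext = f

    # -- element force kernels (batched over elements) --------------------
    def _tri_forces(self, P):
        """Nodal forces (m,3,3) and min det(C) for triangle positions P (m,3,3)."""
        m = P.shape[0]
        if m == 0:
            return np.zeros((0, 3, 3)), np.inf
        D = np.stack((P[:, 1] - P[:, 0], P[:, 2] - P[:, 0]), axis=2)  # (m,3,2)
        F = D @ self.tri_Minv                                         # (m,3,2)
        C = np.einsum("mki,mkj->mij", F, F)                           # (m,2,2)
        c00, c01, c11 = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
        detC = c00 * c11 - c01 * c01
        min_det = float(detC.min()) if m else np.inf
        detC_s = np.maximum(detC, _DEGENERATE_DETC)
        S = np.empty_like(C)
        y = self.tri_is_yeoh
        if y.any():
            trC = c00 + c11
            I1 = trC + 1.0 / detC_s
            dW = self.tri_C0 + 2.0 * self.tri_C1 * np.maximum(I1 - 3.0, 0.0)
            # Cinv/detC entries
            f = 1.0 / (detC_s * detC_s)
            S[:, 0, 0] = 2.0 * dW * (1.0 - c11 * f)
            S[:, 1, 1] = 2.0 * dW * (1.0 - c00 * f)
            S[:, 0, 1] = S[:, 1, 0] = 2.0 * dW * (c01 * f)
        if (~y).any():
            e00 = 0.5 * (c00 - 1.0)
            e11 = 0.5 * (c11 - 1.0)
            e01 = 0.5 * c01
            coef = self.tri_E / (1.0 - self.tri_nu**2)
            S_l00 = coef * ((1.0 - self.tri_nu) * e00 + self.tri_nu * (e00 + e11))
            S_l11 = coef * ((1.0 - self.tri_nu) * e11 + self.tri_nu * (e00 + e11))
            S_l01 = coef * (1.0 - self.tri_nu) * e01
            S[:, 0, 0] = np.where(y, S[:, 0, 0], S_l00)
            S[:, 1, 1] = np.where(y, S[:, 1, 1], S_l11)
            off = np.where(y, S[:, 0, 1], S_l01)
            S[:, 0, 1] = S[:, 1, 0] = off
        if self.tri_pre is not None:
            # surface tension T: S += (T/t) * sqrt(detC) * C^{-1}
            J = np.sqrt(detC_s)
            coef = self.tri_pre / self.tri_thick * J / detC_s
            S[:, 0, 0] += coef * c11
            S[:, 1, 1] += coef * c00
            S[:, 0, 1] -= coef * c01
            S[:, 1, 0] -= coef * c01
        scale = (self.tri_A0 * self.tri_thick)[:, None, None]
        G = scale * (F @ S @ np.swapaxes(self.tri_Minv, 1, 2))        # (m,3,2)
        out = np.empty((m, 3, 3))
        out[:, 1] = G[:, :, 0]
        out[:, 2] = G[:, :, 1]
        out[:, 0] = -G[:, :, 0] - G[:, :, 1]
        return out, min_det

    def _tri_energy(self, P):
        m = P.shape[0]
        if m == 0:
            return 0.0
        D = np.stack((P[:, 1] - P[:, 0], P[:, 2] - P[:, 0]), axis=2)
        F = D @ self.tri_Minv
        C = np.einsum("mki,mkj->mij", F, F)
        c00, c01, c11 = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
        detC = np.maximum(c00 * c11 - c01 * c01, _DEGENERATE_DETC)
        W = np.empty(m)
        y = self.tri_is_yeoh
        if y.any():
            x = np.maximum(c00 + c11 + 1.0 / detC - 3.0, 0.0)
            W_y = self.tri_C0 * x + self.tri_C1 * x * x
            W[y] = W_y[y]
        if (~y).any():
            e00 = 0.5 * (c00 - 1.0)
            e11 = 0.5 * (c11 - 1.0)
            e01 = 0.5 * c01
            tr = e00 + e11
            ee = e00 * e00 + e11 * e11 + 2.0 * e01 * e01
            W_l = self.tri_E / (2.0 * (1.0 - self.tri_nu**2)) * (
                (1.0 - self.tri_nu) * ee + self.tri_nu * tr * tr
            )
            W[~y] = W_l[~y]
        if self.tri_pre is not None:
            W = W + self.tri_pre / self.tri_thick * (np.sqrt(detC) - 1.0)
        return float(np.sum(self.tri_A0 * self.tri_thick * W))

    def _truss_forces(self, P):
        """Nodal forces (k,2,3) for truss end positions P (k,2,3)."""
        k = P.shape[0]
        if k == 0:
            return np.zeros((0, 2, 3))
        d = P[:, 1] - P[:, 0]
        u, l = _unit_rows(d)
        lam = l / self.truss_L0
        strain = lam - 1.0
        strain = np.where(
            self.truss_tension, _smooth_tension_strain(strain), strain
        )
        N = self.truss_EA * strain
        out = np.empty((k, 2, 3))
        out[:, 1] = N[:, None] * u
        out[:, 0] = -out[:, 1]
        return out

    def _truss_energy(self, P):
        if P.shape[0] == 0:
            return 0.0
        l = np.linalg.norm(P[:, 1] - P[:, 0], axis=1)
        lam = l / self.truss_L0
        strain = lam - 1.0
        psi = np.where(
            self.truss_tension,
            _smooth_tension_energy(strain),
            0.5 * strain * strain,
        )
        return float(np.sum(self.truss_EA * self.truss_L0 * psi))

    # -- global quantities -------------------------------------------------
    def internal_forces(self, x):
        """Global internal force vector (n,3) at node positions ``x`` plus the
        minimum membrane det(C) (non-positive means an inverted element)."""
        f = np.zeros((self.n_nodes, 3))
        ft, min_det = self._tri_forces(x[self.tri_conn])
        if ft.shape[0]:
            np.add.at(f, self.tri_conn.ravel(), ft.reshape(-1, 3))
        fk = self._truss_forces(x[self.truss_conn])
        if fk.shape[0]:
            np.add.at(f, self.truss_conn.ravel(), fk.reshape(-1, 3))
        return f, min_det

    def strain_energy(self, x):
        return self._tri_energy(x[self.tri_conn]) + self._truss_energy(
            x[self.truss_conn]
        )

    def residual_full(self, u, scale=1.0):
        """internal - scale*external, per node (n,3); fixed rows NOT zeroed
        (they carry the reaction forces)."""
        x = self.mesh.nodes + u
        f_int, min_det = self.internal_forces(x)
        k = self.stabilization
        if k:
            f_int = f_int + k * self.stab_weight * u
        return f_int - scale * self.f_ext, min_det

    def residual(self, u, scale=1.0):
        r, min_det = self.residual_full(u, scale)
        r = r.copy()
        r[self.fixed_mask] = 0.0
        return r.reshape(-1), min_det

    def residual_reduced(self, u, scale=1.0):
        r, min_det = self.residual_full(u, scale)
        return self.P.T @ r.reshape(-1), min_det

    def potential_energy(self, u, scale=1.0):
        x = self.mesh.nodes + u
        pi = self.strain_energy(x) - scale * float(np.sum(self.f_ext * u))
        k = self.stabilization
        if k:
            pi += 0.5 * k * float(np.sum(self.stab_weight * u * u))
        return pi

    def tangent(self, u):
        """Global stiffness (csr, ndof x ndof) by central differences of the
        batched element force kernels."""
        x = self.mesh.nodes + u
        blocks = []
        h = _FD_STEP
        if self.tri_conn.shape[0]:
            P0 = x[self.tri_conn]
            m = P0.shape[0]
            K = np.empty((m, 9, 9))
            for a in range(9):
                node, comp = divmod(a, 3)
                Pp = P0.copy(); Pp[:, node, comp] += h
                Pm = P0.copy(); Pm[:, node, comp] -= h
                fp, _ = self._tri_forces(Pp)
                fm, _ = self._tri_forces(Pm)
                K[:, :, a] = (fp - fm).reshape(m, 9) / (2.0 * h)
            K = 0.5 * (K + np.swapaxes(K, 1, 2))
            gdof = (self.tri_conn[:, :, None] * 3 + np.arange(3)).reshape(m, 9)
            blocks.append((K, gdof))
        if self.truss_conn.shape[0]:
            P0 = x[self.truss_conn]
            k = P0.shape[0]
            K = np.empty((k, 6, 6))
            for a in range(6):
                node, comp = divmod(a, 3)
                Pp = P0.copy(); Pp[:, node, comp] += h
                Pm = P0.copy(); Pm[:, node, comp] -= h
                K[:, :, a] = (
                    self._truss_forces(Pp) - self._truss_forces(Pm)
                ).reshape(k, 6) / (2.0 * h)
            K = 0.5 * (K + np.swapaxes(K, 1, 2))
            gdof = (self.truss_conn[:, :, None] * 3 + np.arange(3)).reshape(k, 6)
            blocks.append((K, gdof))
        rows, cols, data = [], [], []
        for K, gdof in blocks:
            nloc = gdof.shape[1]
            rows.append(np.repeat(gdof, nloc, axis=1).ravel())
            cols.append(np.tile(gdof, (1, nloc)).ravel())
            data.append(np.swapaxes(K, 1, 2).ravel())
        if not rows:
            k = self.stabilization
            if k:
                return sp.diags(np.repeat(k * self.stab_weight[:, 0], 3)).tocsr()
            return sp.csr_matrix((self.ndof, self.ndof))
        A = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        k = self.stabilization
        if k:
            A = A + sp.diags(np.repeat(k * self.stab_weight[:, 0], 3))
        return A

    def tangent_reduced(self, u):
        K = self.tangent(u)
        return (self.P.T @ K @ self.P).tocsc()

    def expand(self, u_red):
        return (self.P @ u_red).reshape(self.n_nodes, 3)


def assemble_residual(model: FEModel, displacement, scale: float = 1.0):
    """Global residual vector (N, length 3*n_nodes) at a displacement guess.

    Residual = internal forces - ``scale`` x external tractions, with
    fixed-set rows eliminated (zeroed).  Also returns the minimum membrane
    det(C) as an element-inversion indicator for load-step control.
    """
    u = np.asarray(displacement, dtype=float).reshape(model.mesh.n_nodes, 3)
    sys = System(model)
    return sys.residual(u, scale)


def total_potential_energy(model: FEModel, displacement, scale: float = 1.0) -> float:
    """Strain energy minus external work of the dead loads, in N*mm."""
    u = np.asarray(displacement, dtype=float).reshape(model.mesh.n_nodes, 3)
    return System(model).potential_energy(u, scale)
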