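import numpy as np
import pytest

from pelvifem.materials import MaterialModel
from pelvifem.model import FEMesh, FEModel, LoadCase


def make_mesh(
    nodes,
    tris=(),
    tri_labels=None,
    tri_thickness=1.0,
    trusses=(),
    truss_labels=None,
    truss_area=1.0,
    tension_only=False,
    node_sets=None,
    ref_lengths=None,
):
    """Hand-built FEMesh for small oracle problems."""
    nodes = np.asarray(nodes, dtype=float)
    tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
    trusses = np.asarray(trusses, dtype=np.int64).reshape(-1, 2)
    m, k = len(tris), len(trusses)
    if tri_labels is None:
        tri_labels = ["membrane"] * m
    if truss_labels is None:
        truss_labels = ["wire"] * k
    if ref_lengths is None and k:
        ref_lengths = np.linalg.norm(
            nodes[trusses[:, 1]] - nodes[trusses[:, 0]], axis=1
        )
    mesh = FEMesh(
        nodes=nodes,
        tri_nodes=tris,
        tri_structure=np.asarray(tri_labels, dtype=object),
        tri_thickness=np.full(m, tri_thickness, dtype=float)
        if np.isscalar(tri_thickness) else np.asarray(tri_thickness, float),
        truss_nodes=trusses,
        truss_structure=np.asarray(truss_labels, dtype=object),
        truss_area=np.full(k, truss_area, dtype=float)
        if np.isscalar(truss_area) else np.asarray(truss_area, float),
        truss_tension_only=np.full(k, tension_only, dtype=bool)
        if np.isscalar(tension_only) else np.asarray(tension_only, bool),
        truss_ref_length=np.asarray(ref_lengths, dtype=float)
        if ref_lengths is not None else np.zeros(0),
        node_sets={kk: np.asarray(v, dtype=np.int64)
                   for kk, v in (node_sets or {}).items()},
    )
    return mesh


def make_model(mesh, materials=None, **load_kw):
    if materials is None:
        materials = {
            "membrane": MaterialModel.yeoh(0.111, 0.27),
            "wire": MaterialModel.linear_elastic(100.0, 0.3),
        }
    return FEModel(mesh=mesh, materials=materials, load_case=LoadCase(**load_kw))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_patch_model(seed, with_truss=True):
    """Small random membrane patch (<= 20 nodes) with optional stay wires,
    for energy-gradient and objectivity checks."""
    rng = np.random.default_rng(seed)
    nx, ny = 3, 3
    xs, ys = np.meshgrid(np.arange(nx) * 4.0, np.arange(ny) * 4.0)
    nodes = np.column_stack(
        [xs.ravel(), ys.ravel(), rng.uniform(-0.5, 0.5, nx * ny)]
    )
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            tris += [(a, a + 1, a + nx + 1), (a, a + nx + 1, a + nx)]
    labels = ["soft" if (t[0] % 2) else "stiff" for t in tris]
    trusses, tlabels = [], []
    anchor = []
    if with_truss:
        base = len(nodes)
        trusses = [(4, base)]
        tlabels = ["wire"]
        nodes = np.vstack([nodes, [nodes[4] + np.array([1.5, 1.5, 6.0])]])
        anchor = [base]  # the wire's far end is a support point
    mesh = make_mesh(
        nodes,
        tris,
        tri_labels=labels,
        tri_thickness=2.0,
        trusses=trusses,
        truss_labels=tlabels,
        truss_area=0.5,
        tension_only=False,
        node_sets={
            "edge": np.concatenate([np.arange(nx), anchor]).astype(np.int64),
            "free": np.arange(nx, nx * ny),
        },
    )
    materials = {
        "soft": MaterialModel.yeoh(0.0375, 0.07),
        "stiff": MaterialModel.linear_elastic(0.18, 0.45),
        "wire": MaterialModel.linear_elastic(50.0, 0.3),
    }
    forces = np.zeros((len(nodes), 3))
    loaded = rng.choice(np.arange(nx, nx * ny), size=3, replace=False)
    forces[loaded] = rng.uniform(-0.05, 0.05, (3, 3))
    model = FEModel(
        mesh=mesh,
        materials=materials,
        load_case=LoadCase(nodal_forces=forces, newton_tolerance=1e-10),
    )
    return model
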