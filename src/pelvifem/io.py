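"""File I/O: STL surfaces, legacy-VTK results, JSON mesh dialect, INP deck."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .geometry import PelvicGeometry, TriSurface
from .model import FEMesh

__all__ = [
    "export_surfaces_stl",
    "load_surface_stl",
    "mesh_to_json",
    "mesh_from_json",
    "write_vtk",
    "write_inp",
]


def export_surfaces_stl(geometry: PelvicGeometry, directory) -> list[Path]:
    """Write every organ surface as a binary STL (units mm)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, surf in geometry.organ_surfaces.items():
        tm = trimesh.Trimesh(vertices=surf.vertices, faces=surf.faces, process=False)
        path = directory / f"{name}.stl"
        tm.export(path)
        out.append(path)
    return out


def load_surface_stl(path) -> TriSurface:
    tm = trimesh.load_mesh(str(path))
    return TriSurface(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
    )


def mesh_to_json(mesh: FEMesh) -> str:
    doc = {
        "nodes": mesh.nodes.tolist(),
        "tri_nodes": mesh.tri_nodes.tolist(),
        "tri_structure": [str(s) for s in mesh.tri_structure],
        "tri_thickness": mesh.tri_thickness.tolist(),
        "truss_nodes": mesh.truss_nodes.tolist(),
        "truss_structure": [str(s) for s in mesh.truss_structure],
        "truss_area": mesh.truss_area.tolist(),
        "truss_tension_only": mesh.truss_tension_only.tolist(),
        "truss_ref_length": mesh.truss_ref_length.tolist(),
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
        "element_sets": {
            k: [t, i.tolist()] for k, (t, i) in mesh.element_sets.items()
        },
        "ligament_chains": {
            k: [a.tolist(), b.tolist()] for k, (a, b) in mesh.ligament_chains.items()
        },
    }
    return json.dumps(doc, sort_keys=True)


def mesh_from_json(text: str) -> FEMesh:
    doc = json.loads(text)
    return FEMesh(
        nodes=np.asarray(doc["nodes"], dtype=float),
        tri_nodes=np.asarray(doc["tri_nodes"], dtype=np.int64).reshape(-1, 3),
        tri_structure=np.asarray(doc["tri_structure"], dtype=object),
        tri_thickness=np.asarray(doc["tri_thickness"], dtype=float),
        truss_nodes=np.asarray(doc["truss_nodes"], dtype=np.int64).reshape(-1, 2),
        truss_structure=np.asarray(doc["truss_structure"], dtype=object),
        truss_area=np.asarray(doc["truss_area"], dtype=float),
        truss_tension_only=np.asarray(doc["truss_tension_only"], dtype=bool),
        truss_ref_length=np.asarray(doc["truss_ref_length"], dtype=float),
        node_sets={k: np.asarray(v, dtype=np.int64)
                   for k, v in doc["node_sets"].items()},
        element_sets={k: (t, np.asarray(i, dtype=np.int64))
                      for k, (t, i) in doc["element_sets"].items()},
        ligament_chains={
            k: (np.asarray(a, dtype=np.int64), np.asarray(b, dtype=float))
            for k, (a, b) in doc["ligament_chains"].items()
        },
    )


def write_vtk(path, mesh: FEMesh, point_data: dict[str, np.ndarray] | None = None
              ) -> Path:
    """Legacy ASCII VTK unstructured grid: triangles + lines, with optional
    per-node vector fields (e.g. the displacement solution)."""
    path = Path(path)
    n = mesh.n_nodes
    tris = mesh.tri_nodes
    lines = mesh.truss_nodes
    ncells = len(tris) + len(lines)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\npelvifem result\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {ncells} {4 * len(tris) + 3 * len(lines)}\n")
        for t in tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        for s in lines:
            f.write(f"2 {s[0]} {s[1]}\n")
        f.write(f"CELL_TYPES {ncells}\n")
        f.write("".join("5\n" for _ in tris))
        f.write("".join("3\n" for _ in lines))
        if point_data:
            f.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float).reshape(n, 3)
                f.write(f"VECTORS {name} double\n")
                for v in arr:
                    f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    return path


def write_inp(path, mesh: FEMesh) -> Path:
    """Commented Abaqus-style keyword deck (*NODE/*ELEMENT/*NSET) for
    external cross-checking; write-only, bit-stable ordering."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("** pelvifem model export (mm, MPa, N)\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
        eid = 1
        for lab in sorted(dict.fromkeys(str(s) for s in mesh.tri_structure)):
            f.write(f"*ELEMENT, TYPE=S3, ELSET={lab}\n")
            for t, s in zip(mesh.tri_nodes, mesh.tri_structure):
                if str(s) == lab:
                    f.write(f"{eid}, {t[0]+1}, {t[1]+1}, {t[2]+1}\n")
                    eid += 1
        for lab in sorted(dict.fromkeys(str(s) for s in mesh.truss_structure)):
            f.write(f"*ELEMENT, TYPE=T3D2, ELSET={lab}\n")
            for t, s in zip(mesh.truss_nodes, mesh.truss_structure):
                if str(s) == lab:
                    f.write(f"{eid}, {t[0]+1}, {t[1]+1}\n")
                    eid += 1
        for name in sorted(mesh.node_sets):
            f.write(f"*NSET, NSET={name}\n")
            ids = [str(int(i) + 1) for i in mesh.node_sets[name]]
            for k in range(0, len(ids), 10):
                f.write(", ".join(ids[k:k + 10]) + "\n")
        f.write("** boundary: encastre sets\n")
        for name in ("pelvic_floor_border", "sacrum_coccyx_region",
                     "ischial_spine_region", "bone_anchors"):
            if name in mesh.node_sets:
                f.write(f"*BOUNDARY\n{name}, 1, 3\n")
    return path
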