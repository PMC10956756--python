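"""Assemble the pelvic geometry into a finite-element mesh.

Each organ surface becomes a membrane patch with its own thickness;
ligament polylines become chains of truss segments anchored at bony nodes;
fascia sheets and organ walls are coupled by short elastic link trusses
found by (tie-aware) nearest-node search, which stands in for the
fascia-mediated, no-direct-contact load path between the organs.

Emitted node sets:

``pelvic_floor_border``      basin rim (Encastre),
``sacrum_coccyx_region``     sacrum/coccyx bone nodes and sacral ligament ends,
``ischial_spine_region``     the two ischial-spine bone nodes,
``bone_anchors``             pubic and lateral-wall ligament anchors,
``vagina_upper_surface``     traction patch for the vaginal load,
``bladder_top_surface``      traction patch for the bladder load,
``rectum_lower_wall``        traction patch for the rectal load,
``point_Ba/point_C/point_Bp`` the PCL reference nodes,

plus one set per structure.  Element sets mirror the structure labels.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshError
from .geometry import PelvicGeometry, build_pelvic_geometry
from .materials import TrussSection, default_sections, resolve_section
from .model import FEMesh, FixedSet, LoadCase, Traction

__all__ = [
    "mesh_geometry",
    "default_load_case",
    "transfer_displacement",
    "DEFAULT_THICKNESS",
]

DEFAULT_THICKNESS = {
    "vagina": 3.0,
    "bladder": 3.0,
    "rectum": 3.0,
    "uterus": 3.0,
    "pelvic_floor": 2.0,
    "fascia_pubocervical": 1.0,
    "fascia_endopelvic": 1.0,
}

_LIG_SEG = 5.0  # mm target truss segment length along ligaments

# resting-tone surface tension (N/mm) per structure; the rectal wall is
# kept tauter (its contents keep it from going slack), which removes a
# posterior-compartment snap-through
DEFAULT_MEMBRANE_TONE = {"default": 2e-3, "rectum": 1e-2}

DEFAULT_FIXED_SETS = (
    "pelvic_floor_border",
    "sacrum_coccyx_region",
    "ischial_spine_region",
    "bone_anchors",
)


class _Builder:
    def __init__(self):
        self.nodes: list[np.ndarray] = []
        self.tri = []
        self.tri_label = []
        self.tri_thick = []
        self.truss = []
        self.truss_label = []
        self.truss_area = []
        self.truss_tension = []
        self.node_sets: dict[str, list[int]] = {}
        self.ligament_chains = {}

    def add_nodes(self, pts) -> np.ndarray:
        base = len(self.nodes)
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        self.nodes.extend(pts)
        return np.arange(base, base + len(pts))

    def add_to_set(self, name, ids):
        self.node_sets.setdefault(name, []).extend(int(i) for i in np.atleast_1d(ids))

    def add_tris(self, faces, label, thickness):
        for f in faces:
            self.tri.append(tuple(int(i) for i in f))
            self.tri_label.append(label)
            self.tri_thick.append(thickness)

    def _tone_array(self, tri_label, tone):
        if np.isscalar(tone):
            return np.full(len(tri_label), float(tone))
        default = float(tone.get("default", 0.0))
        out = np.full(len(tri_label), default)
        for lab, val in tone.items():
            if lab != "default":
                out[tri_label == lab] = float(val)
        return out

    def add_truss(self, a, b, label, section: TrussSection):
        self.truss.append((int(a), int(b)))
        self.truss_label.append(label)
        self.truss_area.append(section.area)
        self.truss_tension.append(section.tension_only)

    def finish(self, membrane_tone=0.0) -> FEMesh:
        nodes = np.asarray(self.nodes, dtype=float)
        tri = np.asarray(self.tri, dtype=np.int64).reshape(-1, 3)
        truss = np.asarray(self.truss, dtype=np.int64).reshape(-1, 2)
        if truss.shape[0]:
            ref = np.linalg.norm(nodes[truss[:, 1]] - nodes[truss[:, 0]], axis=1)
        else:
            ref = np.zeros(0)
        tri_label = np.asarray(self.tri_label, dtype=object)
        truss_label = np.asarray(self.truss_label, dtype=object)
        element_sets = {}
        for lab in dict.fromkeys(self.tri_label):
            element_sets[lab] = ("tri", np.nonzero(tri_label == lab)[0])
        for lab in dict.fromkeys(self.truss_label):
            element_sets[lab] = ("truss", np.nonzero(truss_label == lab)[0])
        mesh = FEMesh(
            nodes=nodes,
            tri_nodes=tri,
            tri_structure=tri_label,
            tri_thickness=np.asarray(self.tri_thick, dtype=float),
            truss_nodes=truss,
            truss_structure=truss_label,
            truss_area=np.asarray(self.truss_area, dtype=float),
            truss_tension_only=np.asarray(self.truss_tension, dtype=bool),
            truss_ref_length=ref,
            node_sets={
                k: np.unique(np.asarray(v, dtype=np.int64))
                for k, v in self.node_sets.items()
            },
            element_sets=element_sets,
            ligament_chains=self.ligament_chains,
            tri_pretension=self._tone_array(tri_label, membrane_tone),
        )
        return mesh


def _vertex_normals(surf) -> np.ndarray:
    """Area-weighted outward vertex normals of a TriSurface."""
    p = surf.vertices[surf.faces]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    out = np.zeros_like(surf.vertices)
    for c in range(3):
        np.add.at(out, surf.faces[:, c], fn)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.maximum(norm, 1e-12)


def _resample_polyline(points: np.ndarray, seg: float) -> np.ndarray:
    """Resample each polyline leg at ~seg spacing, keeping the original
    vertices (so attachment points stay exact)."""
    out = [points[0]]
    for i in range(len(points) - 1):
        a, b = points[i], points[i + 1]
        L = np.linalg.norm(b - a)
        n = max(1, int(round(L / seg)))
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.asarray(out)


def _tie_aware_links(builder, from_ids, to_ids, label, section, max_dist,
                     tie_tol=1e-9):
    """Link each source node to its nearest target node; exact distance ties
    (mirror pairs straddling the midsagittal plane) are all linked so the
    construction stays left/right symmetric."""
    nodes = np.asarray(builder.nodes)
    tree = cKDTree(nodes[to_ids])
    dists, idx = tree.query(nodes[from_ids], k=min(3, len(to_ids)))
    dists = np.atleast_2d(dists)
    idx = np.atleast_2d(idx)
    made = 0
    for r, src in enumerate(from_ids):
        if dists[r, 0] > max_dist:
            continue
        close = dists[r] <= dists[r, 0] + tie_tol
        for c in np.nonzero(close)[0]:
            builder.add_truss(src, to_ids[idx[r, c]], label, section)
            made += 1
    return made


def mesh_geometry(
    geometry: PelvicGeometry,
    target_edge_length: float | None = None,
    thickness_overrides: dict[str, float] | None = None,
    section_overrides: dict[str, TrussSection] | None = None,
    membrane_tone=None,
) -> FEMesh:
    """Mesh the geometry into membranes, ligament chains and link trusses.

    When ``target_edge_length`` differs from the geometry's own, the
    parametric surfaces are regenerated at the requested resolution (the
    generator is deterministic, so this is a pure refinement)."""
    p = geometry.params
    h = float(target_edge_length or p.target_edge_length)
    if h <= 0:
        raise MeshError("target_edge_length must be positive")
    if abs(h - p.target_edge_length) > 1e-12:
        geometry = build_pelvic_geometry(replace(p, target_edge_length=h))
    thick = dict(DEFAULT_THICKNESS)
    if thickness_overrides:
        thick.update(thickness_overrides)
    sections = default_sections(section_overrides)
    if membrane_tone is None:
        membrane_tone = dict(DEFAULT_MEMBRANE_TONE)

    b = _Builder()
    surf_base: dict[str, int] = {}
    for name, surf in geometry.organ_surfaces.items():
        if surf.areas().min() <= 1e-6:
            raise MeshError(f"surface {name!r} has a degenerate triangle")
        ids = b.add_nodes(surf.vertices)
        surf_base[name] = ids[0]
        b.add_to_set(name, ids)
        b.add_tris(surf.faces + ids[0], name, thick.get(name, 3.0))

    def gid(surface: str, vidx) -> np.ndarray:
        return surf_base[surface] + np.asarray(vidx, dtype=np.int64)

    # bone nodes at the landmarks (the PCL endpoints must be fixed nodes)
    lm = geometry.landmarks
    pubis = int(b.add_nodes(lm["pubic_symphysis_inferior"])[0])
    coccyx = int(b.add_nodes(lm["coccyx_last_joint"])[0])
    sacrum = int(b.add_nodes(lm["sacrum_center"])[0])
    spine = {
        side: int(b.add_nodes(lm[f"ischial_spine_{side}"])[0])
        for side in ("left", "right")
    }
    b.add_to_set("bone_anchors", [pubis])
    b.add_to_set("sacrum_coccyx_region", [sacrum, coccyx])
    b.add_to_set("ischial_spine_region", list(spine.values()))
    b.add_to_set("pcl_pubis", [pubis])
    b.add_to_set("pcl_coccyx", [coccyx])

    # reference points
    ref_ids = {}
    for name, (surf, vidx) in geometry.reference_points.items():
        ref_ids[name] = int(gid(surf, vidx))
        b.add_to_set(f"point_{name}", [ref_ids[name]])
    apex_node = ref_ids["C"]

    # ligament chains
    lig_sec = resolve_section("ligament", sections)
    # the sacrospinous ligament is a broad band embedded in its bed: its
    # substance transmits load toward both insertions, unlike the slender
    # suspension ligaments which act as tension-only stays
    ssl_sec = replace(lig_sec, tension_only=False)
    for name, poly in geometry.ligaments.items():
        if not geometry.ligament_active.get(name, True):
            continue
        pts = _resample_polyline(poly.points, _LIG_SEG)
        chain_ids = np.empty(len(pts), dtype=np.int64)
        arc = np.concatenate(
            ([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        )
        for i, pt in enumerate(pts):
            snapped = None
            if name.startswith("sacrospinous") and i == 0:
                snapped = spine[name.split("_")[1]]
            elif name == "ATFP":
                if i == 0:
                    snapped = spine["left"]
                elif i == len(pts) - 1:
                    snapped = spine["right"]
                elif np.linalg.norm(pt - lm["pubic_symphysis_inferior"]) < 1e-9:
                    snapped = pubis
            elif name in ("uterosacral", "cardinal", "broad", "round"):
                mid = geometry.ligaments[name].points[1]
                if np.linalg.norm(pt - mid) < 1e-9:
                    snapped = apex_node
            chain_ids[i] = snapped if snapped is not None else int(b.add_nodes(pt)[0])
        sec = ssl_sec if name.startswith("sacrospinous") else lig_sec
        for i in range(len(pts) - 1):
            b.add_truss(chain_ids[i], chain_ids[i + 1], name, sec)
        b.ligament_chains[name] = (chain_ids, arc)
        if name.startswith("sacrospinous"):
            # embed the ligament in its sidewall bed: each interior node is
            # elastically tied to a fixed anchor a few mm off the line, so
            # suture anchors have transverse support as well as the axial
            # chain path to the sacral insertion
            side_sign = -1.0 if name.endswith("left") else 1.0
            bed_sec = resolve_section("ligament_bed", sections)
            offsets = (
                np.array([2.0 * side_sign, -4.0, 0.0]),
                np.array([1.0 * side_sign, -1.5, -4.0]),
            )
            for i in range(1, len(pts) - 1):
                for off in offsets:
                    anchor = int(b.add_nodes(pts[i] + off)[0])
                    b.add_to_set("bone_anchors", [anchor])
                    b.add_truss(chain_ids[i], anchor, "ligament_bed", bed_sec)
        # anchor the far ends to bone sets
        if name.startswith("sacrospinous") or name == "uterosacral":
            ends = [chain_ids[-1]] if name.startswith("sacrospinous") else [
                chain_ids[0], chain_ids[-1]]
            b.add_to_set("sacrum_coccyx_region", ends)
        elif name in ("cardinal", "broad", "round"):
            b.add_to_set("bone_anchors", [chain_ids[0], chain_ids[-1]])

    # inter-organ links (fascia-mediated load path, no direct contact)
    link_sec = resolve_section("link", sections)
    strong = TrussSection(area=link_sec.area * 2.5, tension_only=False)
    vag = geometry.organ_surfaces["vagina"]
    rec = geometry.organ_surfaces["rectum"]
    vag_rings = vag.meta["rings"]
    rec_rings = rec.meta["rings"]
    floor_ids = gid("pelvic_floor", np.arange(geometry.organ_surfaces["pelvic_floor"].n_vertices))
    _tie_aware_links(b, gid("vagina", vag_rings[0]), floor_ids,
                     "link_vagina_floor", strong, max_dist=30.0)
    _tie_aware_links(b, gid("rectum", rec_rings[0]), floor_ids,
                     "link_rectum_floor", strong, max_dist=30.0)
    pc = geometry.organ_surfaces["fascia_pubocervical"]
    ep = geometry.organ_surfaces["fascia_endopelvic"]
    bla_ids = gid("bladder", np.arange(geometry.organ_surfaces["bladder"].n_vertices))
    vag_ids = gid("vagina", np.arange(vag.n_vertices))
    rec_ids = gid("rectum", np.arange(rec.n_vertices))
    _tie_aware_links(b, gid("fascia_pubocervical", pc.meta["row_a"]), bla_ids,
                     "link_pubocervical_bladder", link_sec, max_dist=30.0)
    _tie_aware_links(b, gid("fascia_pubocervical", pc.meta["row_b"]), vag_ids,
                     "link_pubocervical_vagina", link_sec, max_dist=30.0)
    _tie_aware_links(b, gid("fascia_endopelvic", ep.meta["row_a"]), vag_ids,
                     "link_endopelvic_vagina", link_sec, max_dist=30.0)
    _tie_aware_links(b, gid("fascia_endopelvic", ep.meta["row_b"]), rec_ids,
                     "link_endopelvic_rectum", link_sec, max_dist=30.0)
    # pubocervical "hammock": the bladder base rests on the anterior
    # vaginal wall through short connective links
    bl_surf = geometry.organ_surfaces["bladder"]
    zmin_b = bl_surf.vertices[:, 2].min()
    bottom = np.nonzero(bl_surf.vertices[:, 2] < zmin_b + 8.0)[0]
    _tie_aware_links(b, gid("bladder", bottom), vag_ids,
                     "link_hammock", link_sec, max_dist=30.0)
    # retropubic bladder attachment
    for side_x in (-10.0, 10.0):
        anchor = int(b.add_nodes(np.array([side_x, 55.0, -4.0]))[0])
        b.add_to_set("bone_anchors", [anchor])
        _tie_aware_links(b, np.array([anchor]), bla_ids,
                         "link_bladder_pubis", link_sec, max_dist=40.0)
    # mesorectal attachment of the upper rectum
    rec_top = gid("rectum", rec_rings[-1])
    for off in (np.array([-8.0, -48.0, 24.0]), np.array([8.0, -48.0, 24.0])):
        anchor = int(b.add_nodes(off)[0])
        b.add_to_set("sacrum_coccyx_region", [anchor])
        _tie_aware_links(b, np.array([anchor]), rec_top,
                         "link_rectum_sacrum", link_sec, max_dist=40.0)
    if "uterus" in geometry.organ_surfaces:
        ut = geometry.organ_surfaces["uterus"]
        ut_low = gid("uterus", [v for v in range(ut.n_vertices)
                                if ut.vertices[v, 2] < ut.vertices[:, 2].min() + 8.0])
        cap_ids = gid("vagina", vag_rings[-1] + [vag.meta["apex"]])
        _tie_aware_links(b, ut_low, cap_ids, "link_uterus_vagina", strong,
                         max_dist=40.0)

    # named regions
    floor_surf = geometry.organ_surfaces["pelvic_floor"]
    b.add_to_set("pelvic_floor_border", gid("pelvic_floor", floor_surf.meta["border"]))
    s_pos = np.asarray(vag.meta["arc_positions"])
    upper = [n for ring, s in zip(vag_rings, s_pos) if s >= 0.6 for n in ring]
    upper.append(vag.meta["apex"])
    b.add_to_set("vagina_upper_surface", gid("vagina", upper))
    bl = geometry.organ_surfaces["bladder"]
    zmin, zmax = bl.vertices[:, 2].min(), bl.vertices[:, 2].max()
    top = np.nonzero(bl.vertices[:, 2] > zmin + 0.72 * (zmax - zmin))[0]
    b.add_to_set("bladder_top_surface", gid("bladder", top))
    s_rec = np.asarray(rec.meta["arc_positions"])
    rec_top_nodes = [n for ring, s in zip(rec_rings, s_rec) if s >= 0.7 for n in ring]
    if rec.meta.get("apex") is not None:
        rec_top_nodes.append(rec.meta["apex"])
    b.add_to_set("rectum_top_surface", gid("rectum", rec_top_nodes))
    # distal rectal wall above the anorectal junction: the load patch that
    # drives the posterior compartment (Bp) downward during straining.
    # Only the inferior-facing wall is loaded - the straining pressure acts
    # outward on the wall that rests on the pelvic floor; pushing down on
    # the superior wall would squeeze the tube into a buckling mode.
    rec_low_nodes = np.asarray(
        [n for ring, s in zip(rec_rings, s_rec) if s <= 0.35 for n in ring]
    )
    normals = _vertex_normals(rec)
    down = normals[rec_low_nodes, 2] < -0.2
    b.add_to_set("rectum_lower_wall", gid("rectum", rec_low_nodes[down]))

    mesh = b.finish(membrane_tone=membrane_tone)
    mesh.validate()
    return mesh


def transfer_displacement(source_mesh: FEMesh, displacement: np.ndarray,
                          target_mesh: FEMesh) -> np.ndarray:
    """Nearest-node transfer of a displacement field between two meshes of
    the same geometry (e.g. as a warm start for a refined solve)."""
    tree = cKDTree(source_mesh.nodes)
    _, idx = tree.query(target_mesh.nodes)
    return np.asarray(displacement, dtype=float)[idx]


def default_load_case(
    mesh: FEMesh,
    vagina_traction: float = 8e-5,
    bladder_traction: float = 5e-5,
    rectum_traction: float = 7e-4,
    n_load_steps: int = 2,
    newton_tolerance: float = 1e-7,
    stabilization: float = 1e-6,
    max_newton_iterations: int = 150,
) -> LoadCase:
    """The study's straining load case: a downward traction on the upper
    vaginal surface, a traction at 45 degrees from the sagittal axis on the
    bladder dome, an optional rectal traction driving the posterior
    compartment, and Encastre supports at the floor border and bony sets.
    Magnitudes in MPa are the calibration unknowns."""
    s = np.sqrt(0.5)
    tractions = [
        Traction("vagina_traction", "vagina_upper_surface", (0.0, 0.0, -1.0),
                 vagina_traction),
        Traction("bladder_traction", "bladder_top_surface", (0.0, -s, -s),
                 bladder_traction),
        Traction("rectum_traction", "rectum_lower_wall", (0.0, 0.0, -1.0),
                 rectum_traction),
    ]
    fixed = [FixedSet(name) for name in DEFAULT_FIXED_SETS if name in mesh.node_sets]
    return LoadCase(
        tractions=tractions,
        fixed=fixed,
        n_load_steps=n_load_steps,
        newton_tolerance=newton_tolerance,
        stabilization=stabilization,
        max_newton_iterations=max_newton_iterations,
    )
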