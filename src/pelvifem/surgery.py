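"""Posterior sacrospinous ligament fixation (SSF) modelling.

The repair sutures the vaginal apex to the sacrospinous ligament at a
configurable arc-length distance from the ischial spine (clinically 1-3 cm;
2 cm is the default used in the absence of further precision).  Each
configured side receives two suture filaments running from two distinct
apex nodes to a single anchor node on the ligament chain; the filaments are
stiff tension-only trusses whose stress-free length is the gap-closed
(tied, tightened) length, optionally shortened by a pre-tension strain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ModelError, ParameterError
from .geometry import PelvicGeometry
from .materials import TrussSection
from .model import FEModel

__all__ = ["SSFConfig", "place_anchor", "apply_ssf"]


@dataclass(frozen=True)
class SSFConfig:
    """One surgical configuration of the study matrix.

    ``sides`` is a subset of {"left", "right"} (empty = no surgery);
    ``anchor_distance_mm`` is measured along the ligament from the ischial
    spine; ``apex_spread_mm`` separates the two apex attachment points;
    ``pretension`` is a stress-free-length shortening strain (0 = tied
    without tension)."""

    sides: frozenset = frozenset()
    anchor_distance_mm: float = 20.0
    sutures_per_side: int = 2
    suture_area_mm2: float = 0.2
    apex_spread_mm: float = 5.0
    pretension: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "sides", frozenset(self.sides))
        if not self.sides <= {"left", "right"}:
            raise ParameterError(f"sides must be within {{left,right}}: {self.sides}")
        if self.anchor_distance_mm < 0:
            raise ParameterError("anchor_distance_mm must be >= 0")
        if self.sutures_per_side < 1:
            raise ParameterError("sutures_per_side must be >= 1")
        if self.suture_area_mm2 <= 0:
            raise ParameterError("suture_area_mm2 must be > 0")
        if not 0 <= self.pretension < 1:
            raise ParameterError("pretension must be in [0, 1)")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.sides)) if self.sides else "none"


def place_anchor(geometry: PelvicGeometry, side: str, distance_mm: float):
    """Anchor point on the sacrospinous ligament at an arc-length distance
    from the ischial spine.

    Returns ``(point, vertex_index)`` where the point lies exactly on the
    polyline at the requested arc position and the index is the nearest
    polyline vertex.  Distances beyond the ligament's arc length are
    anatomically impossible and raise ``ParameterError``."""
    name = f"sacrospinous_{side}"
    if name not in geometry.ligaments:
        raise ParameterError(f"geometry has no ligament {name!r}")
    poly = geometry.ligaments[name]
    arc = poly.arc_length()
    if not 0.0 <= distance_mm <= arc + 1e-9:
        raise ParameterError(
            f"anchor distance {distance_mm} mm outside the ligament "
            f"(arc length {arc:.1f} mm)"
        )
    point = poly.point_at(min(distance_mm, arc))
    d = np.linalg.norm(poly.points - point[None, :], axis=1)
    return point, int(np.argmin(d))


def _anchor_chain_node(mesh, side: str, distance_mm: float) -> int:
    name = f"sacrospinous_{side}"
    if name not in mesh.ligament_chains:
        raise ModelError(f"mesh has no ligament chain {name!r}")
    ids, arc = mesh.ligament_chains[name]
    if distance_mm > arc[-1] + 1e-9:
        raise ParameterError(
            f"anchor distance {distance_mm} mm beyond ligament arc {arc[-1]:.1f} mm"
        )
    return int(ids[np.argmin(np.abs(arc - distance_mm))])


def _apex_attachment_nodes(model: FEModel, count: int, spread: float) -> list[int]:
    """The C apex node plus ``count-1`` midsagittal cap nodes ~spread mm
    away, so left and right fixations share identical attachment points."""
    mesh = model.mesh
    if "point_C" not in mesh.node_sets:
        raise ModelError("model lacks the vaginal apex node set 'point_C'")
    apex = int(mesh.node_sets["point_C"][0])
    if count == 1:
        return [apex]
    vag = mesh.node_sets.get("vagina")
    if vag is None:
        raise ModelError("model lacks the 'vagina' node set")
    pos = mesh.nodes[vag]
    apex_pos = mesh.nodes[apex]
    on_plane = np.abs(pos[:, 0]) < 1e-6
    cand = vag[on_plane]
    cand = cand[cand != apex]
    if len(cand) < count - 1:
        cand = vag[vag != apex]
    d = np.abs(np.linalg.norm(mesh.nodes[cand] - apex_pos, axis=1) - spread)
    order = np.argsort(d, kind="stable")
    return [apex] + [int(cand[i]) for i in order[: count - 1]]


def apply_ssf(model: FEModel, geometry: PelvicGeometry, config: SSFConfig) -> FEModel:
    """Add the SSF suture filaments for the configured sides.

    Each side contributes ``sutures_per_side`` trusses from distinct apex
    nodes to the ligament anchor node; attachment is by shared nodes, the
    discrete equivalent of a tie constraint at both ends.  The stress-free
    length is the as-built (gap-closed) length scaled by ``1 - pretension``.
    An empty ``sides`` returns the model unchanged."""
    if not config.sides:
        return model
    out = model.copy()
    mesh = out.mesh
    apex_nodes = _apex_attachment_nodes(out, config.sutures_per_side,
                                        config.apex_spread_mm)
    new_conn = []
    new_label = []
    for side in sorted(config.sides):
        # validates the arc-length bound on the geometry polyline too
        place_anchor(geometry, side, config.anchor_distance_mm)
        anchor = _anchor_chain_node(mesh, side, config.anchor_distance_mm)
        for a in apex_nodes:
            new_conn.append((a, anchor))
            new_label.append(f"suture_{side}")
    new_conn = np.asarray(new_conn, dtype=np.int64)
    ref = np.linalg.norm(
        mesh.nodes[new_conn[:, 1]] - mesh.nodes[new_conn[:, 0]], axis=1
    ) * (1.0 - config.pretension)
    k0 = mesh.truss_nodes.shape[0]
    mesh.truss_nodes = np.vstack([mesh.truss_nodes, new_conn])
    mesh.truss_structure = np.concatenate(
        [mesh.truss_structure, np.asarray(new_label, dtype=object)]
    )
    mesh.truss_area = np.concatenate(
        [mesh.truss_area, np.full(len(new_conn), config.suture_area_mm2)]
    )
    mesh.truss_tension_only = np.concatenate(
        [mesh.truss_tension_only, np.ones(len(new_conn), dtype=bool)]
    )
    mesh.truss_ref_length = np.concatenate([mesh.truss_ref_length, ref])
    for lab in dict.fromkeys(new_label):
        idx = k0 + np.nonzero(np.asarray(new_label, dtype=object) == lab)[0]
        prev = mesh.element_sets.get(lab)
        if prev is not None:
            idx = np.concatenate([prev[1], idx])
        mesh.element_sets[lab] = ("truss", idx)
    return out
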