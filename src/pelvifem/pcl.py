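"""Pubococcygeal-line (PCL) organ-descent measurement.

The PCL runs from the inferior border of the pubic symphysis to the last
coccygeal joint.  Both landmarks are projected onto the midsagittal plane
(x = 0); a reference point's mobility is the change, from rest to maximal
strain, of its perpendicular distance to that line, with the positive sign
on the inferior (caudal) side — positive descent is motion in the prolapse
direction.  The anterior point Ba is flagged not evaluable when its motion
is dominated by out-of-plane (lateral) displacement, mirroring the
asymmetric-bladder exclusion of the clinical measurement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, ReportError
from .model import FEMesh, SimulationResult

__all__ = [
    "PCLLine",
    "pcl_line",
    "perpendicular_distance",
    "descent",
    "DescentReport",
]

REFERENCE_POINTS = ("Ba", "C", "Bp")


@dataclass(frozen=True)
class PCLLine:
    """Directed line in the midsagittal plane, pubis -> coccyx."""

    origin: np.ndarray      # (3,), x = 0
    direction: np.ndarray   # (3,), unit, x = 0
    normal: np.ndarray      # (3,), unit, x = 0, points inferior (caudal)


def pcl_line(geometry_or_landmarks) -> PCLLine:
    """PCL through the midsagittal projections of the two bony landmarks."""
    lm = getattr(geometry_or_landmarks, "landmarks", geometry_or_landmarks)
    try:
        a = np.asarray(lm["pubic_symphysis_inferior"], dtype=float).copy()
        b = np.asarray(lm["coccyx_last_joint"], dtype=float).copy()
    except KeyError as e:
        raise GeometryError(f"missing PCL landmark: {e}") from None
    a[0] = 0.0
    b[0] = 0.0
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise GeometryError("PCL landmarks coincide")
    d /= n
    # in-plane perpendicular; choose the caudal side as positive
    cand = np.array([0.0, -d[2], d[1]])
    if cand[2] > 0 or (cand[2] == 0 and cand[1] > 0):
        cand = -cand
    return PCLLine(origin=a, direction=d, normal=cand)


def perpendicular_distance(point, line: PCLLine) -> float:
    """Signed midsagittal perpendicular distance (mm) of a point to the PCL.

    The point is projected to x = 0 first; positive values lie on the
    inferior side of the line."""
    p = np.asarray(point, dtype=float).copy()
    p[0] = 0.0
    return float(np.dot(p - line.origin, line.normal))


def descent(
    rest_result: SimulationResult,
    strain_result: SimulationResult,
    geometry: PelvicGeometry,
    mesh: FEMesh,
    ba_out_of_plane_fraction: float = 0.5,
) -> dict:
    """One descent-report row: PCL descent (mm) of Ba, C, Bp from the rest
    state to the maximal-strain state, plus the Euclidean ("total")
    displacement of each point and the Ba evaluability flag.

    ``rest_result`` is typically the zero-load state (zero displacement);
    both results must be converged.  Raises ``ReportError`` when a
    reference node set is missing."""
    if not (rest_result.converged and strain_result.converged):
        raise ReportError("descent requires converged rest and strain states")
    line = pcl_line(geometry)
    row: dict = {}
    for name in REFERENCE_POINTS:
        key = f"point_{name}"
        if key not in mesh.node_sets or len(mesh.node_sets[key]) == 0:
            raise ReportError(f"mesh lacks reference node set {key!r}")
        nid = int(mesh.node_sets[key][0])
        x0 = mesh.nodes[nid]
        rest = x0 + rest_result.displacement[nid]
        strain = x0 + strain_result.displacement[nid]
        d_rest = perpendicular_distance(rest, line)
        d_strain = perpendicular_distance(strain, line)
        disp = strain - rest
        row[f"{name}_mm"] = d_strain - d_rest
        row[f"{name}_total_mm"] = float(np.linalg.norm(disp))
        if name == "Ba":
            total = np.linalg.norm(disp)
            lateral = abs(disp[0])
            row["Ba_not_evaluable"] = bool(
                total > 1e-12 and lateral > ba_out_of_plane_fraction * total
            )
    return row


@dataclass
class DescentReport:
    """Per-configuration Ba/C/Bp PCL descents, keyed by
    (surgery sides, anchor distance, support condition)."""

    rows: list[dict] = field(default_factory=list)

    def add(self, sides, anchor_distance_mm, support_condition, row: dict,
            **extra) -> None:
        key = (tuple(sorted(sides)), float(anchor_distance_mm), support_condition)
        if any(r["_key"] == key for r in self.rows):
            raise ReportError(f"duplicate report row for {key}")
        entry = {
            "_key": key,
            "sides": "+".join(sorted(sides)) if sides else "none",
            "anchor_distance_mm": float(anchor_distance_mm),
            "support_condition": support_condition,
        }
        entry.update(row)
        entry.update(extra)
        self.rows.append(entry)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([{k: v for k, v in r.items() if k != "_key"}
                           for r in self.rows])
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def row_for(self, sides, anchor_distance_mm, support_condition) -> dict:
        key = (tuple(sorted(sides)), float(anchor_distance_mm), support_condition)
        for r in self.rows:
            if r["_key"] == key:
                return r
        raise ReportError(f"no report row for {key}")
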