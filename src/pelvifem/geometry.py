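"""Parametric synthetic pelvic geometry.

The MRI-derived anatomy behind the original study is not available, so the
pre-operative state is emulated by a procedural generator built from
ellipsoidal and tubular primitives that preserve the topology, attachment
pattern and landmark relations the mechanics depend on:

* a vaginal tube with a closed apex (the post-hysterectomy vault) whose
  apex carries the C reference point;
* a bladder shell (Ba on its postero-inferior base) and a curved rectal
  tube (Bp at the anterior anorectal junction);
* a basin-shaped pelvic-floor membrane spanning the bony attachments;
* pubocervical and endopelvic fascia sheets between the organ walls;
* ligament polylines (sacrospinous left/right, uterosacral, cardinal,
  broad, round, ATFP) anchored at bony landmarks.

Coordinates are millimetres: x lateral (patient-right positive), y
anterior, z superior; the midsagittal plane is x = 0.  The generic variant
(``asymmetry_amplitude = 0``) is strictly mirror-symmetric and keeps a
uterine body on the vaginal apex; a positive asymmetry amplitude produces
the patient-like post-hysterectomy variant with a laterally shifted
bladder and seeded smooth perturbations of the organ positions.  The
"pathological" support condition disables the broad and round ligaments,
which removes the apical suspension the prolapse model is built around.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import _primitives as prim
from .errors import GeometryError, ParameterError

__all__ = [
    "GeometryParams",
    "TriSurface",
    "Polyline",
    "PelvicGeometry",
    "build_pelvic_geometry",
    "apply_support_condition",
    "patient_like_params",
]

ORGAN_NAMES = (
    "vagina",
    "bladder",
    "rectum",
    "pelvic_floor",
    "fascia_pubocervical",
    "fascia_endopelvic",
)

LIGAMENT_NAMES = (
    "sacrospinous_left",
    "sacrospinous_right",
    "uterosacral",
    "cardinal",
    "broad",
    "round",
    "ATFP",
)

#: ligaments switched off by the pathological support condition
PATHOLOGICAL_DISABLED = ("broad", "round")

_MIN_SSL_ARC = 30.0  # mm, anchors up to 3 cm must be placeable


@dataclass(frozen=True)
class GeometryParams:
    """Generator parameters (all lengths in mm).

    ``organ_scales`` multiplies the linear dimensions of individual organs;
    ``asymmetry_amplitude`` is the lateral bladder offset and the scale of
    the seeded organ-position perturbations; ``mirror`` reflects the whole
    geometry through the midsagittal plane (left/right labels swap).
    ``include_uterus=None`` keeps the uterine body exactly when the
    geometry is symmetric (the generic, pre-hysterectomy variant)."""

    inter_spine_width: float = 100.0
    pcl_length: float = 100.0
    sacrospinous_length: float = 45.0
    organ_scales: tuple[tuple[str, float], ...] = ()
    support_condition: str = "physiological"
    asymmetry_amplitude: float = 0.0
    seed: int = 0
    target_edge_length: float = 6.0
    include_uterus: bool | None = None
    mirror: bool = False

    def __post_init__(self):
        if self.inter_spine_width <= 0 or self.pcl_length <= 0:
            raise ParameterError("pelvimetry lengths must be positive")
        if self.sacrospinous_length <= _MIN_SSL_ARC:
            raise ParameterError(
                f"sacrospinous length must exceed {_MIN_SSL_ARC} mm"
            )
        if self.target_edge_length <= 0:
            raise ParameterError("target_edge_length must be positive")
        if self.asymmetry_amplitude < 0:
            raise ParameterError("asymmetry_amplitude must be >= 0")
        if self.support_condition not in ("physiological", "pathological"):
            raise ParameterError(
                f"unknown support condition {self.support_condition!r}"
            )
        for name, s in self.organ_scales:
            if s <= 0:
                raise ParameterError(f"scale for {name!r} must be positive")

    def scale(self, organ: str) -> float:
        return dict(self.organ_scales).get(organ, 1.0)

    @property
    def uterus_present(self) -> bool:
        if self.include_uterus is None:
            return self.asymmetry_amplitude == 0.0
        return self.include_uterus


def patient_like_params(**overrides) -> GeometryParams:
    """Default patient-like pre-operative state: post-hysterectomy,
    asymmetric bladder, pathological apical support."""
    base = dict(
        support_condition="pathological",
        asymmetry_amplitude=5.0,
        include_uterus=False,
        seed=0,
    )
    base.update(overrides)
    return GeometryParams(**base)


@dataclass
class TriSurface:
    """Triangulated open or closed shell with consistent orientation."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray     # (m, 3)
    meta: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on edges used by exactly one face (open-shell border)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])


@dataclass
class Polyline:
    points: np.ndarray  # (k, 3)

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc-length position ``s`` from the first vertex."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate(([0.0], np.cumsum(seg)))
        if not 0.0 <= s <= cum[-1] + 1e-12:
            raise ParameterError(
                f"arc position {s} mm outside [0, {cum[-1]:.6g}] mm"
            )
        s = min(s, cum[-1])
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = (s - cum[i]) / seg[i]
        return (1 - t) * self.points[i] + t * self.points[i + 1]


@dataclass
class PelvicGeometry:
    landmarks: dict[str, np.ndarray]
    organ_surfaces: dict[str, TriSurface]
    ligaments: dict[str, Polyline]
    ligament_active: dict[str, bool]
    reference_points: dict[str, tuple[str, int]]  # name -> (surface, vertex)
    symmetric: bool
    params: GeometryParams

    def reference_position(self, name: str) -> np.ndarray:
        surf, vid = self.reference_points[name]
        return self.organ_surfaces[surf].vertices[vid]

    def active_ligaments(self) -> list[str]:
        return [k for k, v in self.ligament_active.items() if v]


# ---------------------------------------------------------------------------
# construction

def _landmarks(p: GeometryParams, rng) -> dict[str, np.ndarray]:
    w2 = p.inter_spine_width / 2.0
    theta = np.deg2rad(10.0)  # PCL dips posteriorly below horizontal
    pubis = np.array([0.0, 60.0, 0.0])
    coccyx = pubis + p.pcl_length * np.array([0.0, -np.cos(theta), -np.sin(theta)])
    sacrum = np.array([0.0, -45.0, 25.0])
    lm = {
        "pubic_symphysis_inferior": pubis,
        "coccyx_last_joint": coccyx,
        "sacrum_center": sacrum,
        "ischial_spine_left": np.array([-w2, 0.0, 0.0]),
        "ischial_spine_right": np.array([w2, 0.0, 0.0]),
    }
    for side, sign in (("left", -1.0), ("right", 1.0)):
        spine = lm[f"ischial_spine_{side}"]
        target = np.array([sign * 8.0, -38.0, 12.0])
        d = target - spine
        length = p.sacrospinous_length
        if side == "left":
            # patient-like asymmetry shortens the left ligament slightly
            length = length - 0.1 * p.asymmetry_amplitude
        lm[f"sacrospinous_insertion_{side}"] = spine + length * d / np.linalg.norm(d)
    return lm


def _organ_layout(p: GeometryParams, rng) -> dict[str, dict]:
    """Analytic centres/axes of each organ, including asymmetry offsets."""
    A = p.asymmetry_amplitude
    jitter = {
        name: 0.25 * A * rng.standard_normal(3)
        for name in ("vagina", "bladder", "rectum")
    }
    for j in jitter.values():
        j[2] = 0.0  # keep vertical positions; asymmetry is in-plane
    lay = {
        "vagina": {
            # the pathological vault sits low, near the ischial-spine plane
            "axis": np.array(
                [[0.0, 18.0, -34.0], [0.0, 6.0, -12.0], [0.0, -10.0, 2.0]]
            ),
            "a_lat": 16.0 * p.scale("vagina"),
            "b_sag": 7.0 * p.scale("vagina"),
            "offset": jitter["vagina"] * np.array([1.0, 0.3, 0.0]),
        },
        "bladder": {
            "center": np.array([0.0, 30.0, 12.0])
            + np.array([A, 0.0, 0.0])
            + jitter["bladder"] * np.array([0.5, 0.3, 0.0]),
            "semi": np.array([27.0, 23.0, 19.0]) * p.scale("bladder"),
        },
        "rectum": {
            "axis": np.array(
                [[0.0, -4.0, -42.0], [0.0, -30.0, -18.0], [0.0, -38.0, 22.0]]
            ),
            "radius": 11.0 * p.scale("rectum"),
            "offset": jitter["rectum"] * np.array([0.6, 0.3, 0.0]),
        },
        "pelvic_floor": {
            "center_xy": (0.0, 5.0),
            "rx": 58.0 * p.scale("pelvic_floor"),
            "ry": 62.0 * p.scale("pelvic_floor"),
            "rim_z": -22.0,
            "depth": 22.0,
        },
        "uterus": {
            "center": np.array([0.0, -14.0, 20.0]),
            "semi": np.array([16.0, 13.0, 22.0]) * p.scale("uterus"),
        },
    }
    return lay


def _nearest_vertex(surface: TriSurface, target: np.ndarray) -> int:
    d = np.linalg.norm(surface.vertices - target[None, :], axis=1)
    return int(np.argmin(d))


def _build_surfaces(p: GeometryParams, lay, h: float) -> dict[str, TriSurface]:
    surfaces: dict[str, TriSurface] = {}
    sym = p.asymmetry_amplitude == 0.0

    v = lay["vagina"]
    verts, faces, meta = prim.tube_surface(
        v["axis"], v["a_lat"], v["b_sag"], h, cap_end=True
    )
    verts = verts + v["offset"][None, :]
    surfaces["vagina"] = TriSurface(verts, faces, meta)

    b = lay["bladder"]
    verts, faces, meta = prim.ellipsoid_surface(b["center"], b["semi"], h)
    surfaces["bladder"] = TriSurface(verts, faces, meta)

    r = lay["rectum"]
    verts, faces, meta = prim.tube_surface(
        r["axis"], r["radius"], r["radius"], h, cap_end=True, cap_start=True
    )
    verts = verts + r["offset"][None, :]
    surfaces["rectum"] = TriSurface(verts, faces, meta)

    f = lay["pelvic_floor"]
    verts, faces, meta = prim.basin_surface(
        f["center_xy"], f["rx"], f["ry"], f["rim_z"], f["depth"], h
    )
    surfaces["pelvic_floor"] = TriSurface(verts, faces, meta)

    # fascia sheets: ruled strips between the organ walls
    def _sheet(y_a, z_a, y_b, z_b, half_width, bow=2.0):
        n_c = max(5, int(round(2 * half_width / h)) + 1)
        if n_c % 2 == 0:
            n_c += 1  # odd count puts a column exactly on x = 0
        xs = np.linspace(-half_width, half_width, n_c)
        A = np.stack([xs, np.full(n_c, y_a), np.full(n_c, z_a)], axis=1)
        B = np.stack([xs, np.full(n_c, y_b), np.full(n_c, z_b)], axis=1)
        verts, faces, meta = prim.ruled_sheet(A, B, h)
        # slight anterior bow: a perfectly flat membrane has no first-order
        # transverse stiffness, which is both unphysical and ill-conditioned
        grid = meta["grid"]
        n_s = grid.shape[0] - 1
        for i in range(n_s + 1):
            verts[grid[i], 1] += bow * np.sin(np.pi * i / n_s)
        return TriSurface(verts, faces, meta)

    surfaces["fascia_pubocervical"] = _sheet(16.0, -2.0, 10.0, -16.0, 14.0)
    surfaces["fascia_endopelvic"] = _sheet(-2.0, -13.0, -9.0, -23.0, 14.0)

    if p.uterus_present:
        u = lay["uterus"]
        verts, faces, meta = prim.ellipsoid_surface(u["center"], u["semi"], h)
        surfaces["uterus"] = TriSurface(verts, faces, meta)

    if sym:
        for s in surfaces.values():
            s.vertices = prim.symmetrize_x(s.vertices, tol=1e-6)
    return surfaces


def _ligament_polylines(p: GeometryParams, lm, apex: np.ndarray) -> dict[str, Polyline]:
    ligs: dict[str, Polyline] = {}
    for side in ("left", "right"):
        ligs[f"sacrospinous_{side}"] = Polyline(
            np.vstack([lm[f"ischial_spine_{side}"], lm[f"sacrospinous_insertion_{side}"]])
        )
    w2 = p.inter_spine_width / 2.0

    def _bilateral(left_pt, right_pt, mid):
        return Polyline(np.vstack([left_pt, mid, right_pt]))

    ligs["uterosacral"] = _bilateral(
        np.array([-10.0, -45.0, 18.0]), np.array([10.0, -45.0, 18.0]), apex
    )
    ligs["cardinal"] = _bilateral(
        np.array([-w2 + 2.0, -18.0, 20.0]), np.array([w2 - 2.0, -18.0, 20.0]), apex
    )
    ligs["broad"] = _bilateral(
        np.array([-w2 - 2.0, -2.0, 18.0]), np.array([w2 + 2.0, -2.0, 18.0]), apex
    )
    ligs["round"] = _bilateral(
        np.array([-w2, 32.0, 2.0]), np.array([w2, 32.0, 2.0]), apex
    )
    ligs["ATFP"] = _bilateral(
        lm["ischial_spine_left"],
        lm["ischial_spine_right"],
        lm["pubic_symphysis_inferior"],
    )
    return ligs


def _mirror_geometry(geom: PelvicGeometry) -> PelvicGeometry:
    flip = np.array([-1.0, 1.0, 1.0])

    def swap(name: str) -> str:
        if name.endswith("_left"):
            return name[:-5] + "_right"
        if name.endswith("_right"):
            return name[:-6] + "_left"
        return name

    landmarks = {swap(k): v * flip for k, v in geom.landmarks.items()}
    surfaces = {}
    for k, s in geom.organ_surfaces.items():
        surfaces[k] = TriSurface(
            s.vertices * flip, s.faces[:, ::-1].copy(), dict(s.meta)
        )
    ligaments = {swap(k): Polyline(v.points * flip) for k, v in geom.ligaments.items()}
    active = {swap(k): v for k, v in geom.ligament_active.items()}
    return PelvicGeometry(
        landmarks=landmarks,
        organ_surfaces=surfaces,
        ligaments=ligaments,
        ligament_active=active,
        reference_points=dict(geom.reference_points),
        symmetric=geom.symmetric,
        params=geom.params,
    )


def build_pelvic_geometry(params: GeometryParams,
                          target_edge_length: float | None = None) -> PelvicGeometry:
    """Build the synthetic pre-operative pelvic geometry.

    Deterministic in ``(params, params.seed)``.  Raises ``GeometryError``
    when the requested asymmetry shortens a sacrospinous ligament below the
    30 mm needed to place anchors up to 3 cm from the ischial spine."""
    h = float(target_edge_length or params.target_edge_length)
    if h <= 0:
        raise ParameterError("target_edge_length must be positive")
    rng = np.random.default_rng(params.seed)
    lm = _landmarks(params, rng)
    lay = _organ_layout(params, rng)
    surfaces = _build_surfaces(params, lay, h)

    apex_idx = surfaces["vagina"].meta["apex"]
    apex = surfaces["vagina"].vertices[apex_idx]
    ligs = _ligament_polylines(params, lm, apex)
    for side in ("left", "right"):
        arc = ligs[f"sacrospinous_{side}"].arc_length()
        if arc < _MIN_SSL_ARC:
            raise GeometryError(
                f"sacrospinous_{side} arc length {arc:.1f} mm < {_MIN_SSL_ARC} mm; "
                "reduce asymmetry_amplitude"
            )
    active = {k: True for k in ligs}
    refs = {
        "C": ("vagina", apex_idx),
        "Ba": (
            "bladder",
            _nearest_vertex(
                surfaces["bladder"],
                lay["bladder"]["center"]
                + np.array([0.0, -0.6, -0.8]) * lay["bladder"]["semi"] * 0.95
                - np.array([lay["bladder"]["center"][0], 0.0, 0.0]),
            ),
        ),
        "Bp": ("rectum", _nearest_vertex(surfaces["rectum"], np.array([0.0, 5.0, -40.0]))),
    }
    geom = PelvicGeometry(
        landmarks=lm,
        organ_surfaces=surfaces,
        ligaments=ligs,
        ligament_active=active,
        reference_points=refs,
        symmetric=params.asymmetry_amplitude == 0.0,
        params=params,
    )
    geom = apply_support_condition(geom, params.support_condition)
    if params.mirror:
        geom = _mirror_geometry(geom)
    return geom


def apply_support_condition(geometry: PelvicGeometry, condition: str) -> PelvicGeometry:
    """Return the geometry under the given support condition.

    ``pathological`` flags the broad and round ligaments inactive (no
    downstream stiffness); ``physiological`` re-activates everything.
    Idempotent; everything except the flags is shared untouched."""
    if condition not in ("physiological", "pathological"):
        raise ParameterError(f"unknown support condition {condition!r}")
    active = {k: True for k in geometry.ligaments}
    if condition == "pathological":
        for name in PATHOLOGICAL_DISABLED:
            if name not in active:
                raise GeometryError(f"geometry lacks the {name!r} ligament group")
            active[name] = False
    return replace_geometry(geometry, ligament_active=active,
                            params=replace(geometry.params, support_condition=condition))


def replace_geometry(geom: PelvicGeometry, **kw) -> PelvicGeometry:
    data = dict(
        landmarks=geom.landmarks,
        organ_surfaces=geom.organ_surfaces,
        ligaments=geom.ligaments,
        ligament_active=geom.ligament_active,
        reference_points=geom.reference_points,
        symmetric=geom.symmetric,
        params=geom.params,
    )
    data.update(kw)
    return PelvicGeometry(**data)


# ---------------------------------------------------------------------------
# serialization

def geometry_to_json(geom: PelvicGeometry) -> str:
    doc = {
        "params": {
            **{k: getattr(geom.params, k) for k in (
                "inter_spine_width", "pcl_length", "sacrospinous_length",
                "support_condition", "asymmetry_amplitude", "seed",
                "target_edge_length", "include_uterus", "mirror")},
            "organ_scales": list(geom.params.organ_scales),
        },
        "symmetric": geom.symmetric,
        "landmarks": {k: v.tolist() for k, v in geom.landmarks.items()},
        "ligaments": {k: v.points.tolist() for k, v in geom.ligaments.items()},
        "ligament_active": geom.ligament_active,
        "reference_points": {k: list(v) for k, v in geom.reference_points.items()},
        "surfaces": {
            k: {"vertices": s.vertices.tolist(), "faces": s.faces.tolist()}
            for k, s in geom.organ_surfaces.items()
        },
    }
    return json.dumps(doc, sort_keys=True)


def geometry_from_json(text: str) -> PelvicGeometry:
    doc = json.loads(text)
    pd = doc["params"]
    pd["organ_scales"] = tuple(tuple(x) for x in pd.get("organ_scales", ()))
    params = GeometryParams(**pd)
    return PelvicGeometry(
        landmarks={k: np.asarray(v) for k, v in doc["landmarks"].items()},
        organ_surfaces={
            k: TriSurface(np.asarray(s["vertices"]), np.asarray(s["faces"], dtype=np.int64))
            for k, s in doc["surfaces"].items()
        },
        ligaments={k: Polyline(np.asarray(v)) for k, v in doc["ligaments"].items()},
        ligament_active=dict(doc["ligament_active"]),
        reference_points={k: (v[0], int(v[1])) for k, v in doc["reference_points"].items()},
        symmetric=bool(doc["symmetric"]),
        params=params,
    )
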