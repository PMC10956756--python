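"""Structured tessellation of the parametric anatomical primitives.

All generators produce triangulations that are *mirror symmetric* about the
midsagittal plane x = 0: node positions come in exact mirror pairs (after
:func:`symmetrize_x`) and the diagonal of every grid quad is chosen by the
sign of the quad centre's x coordinate, so reflecting the mesh maps
triangles onto triangles.  This is what lets a left-side and a right-side
surgery on the symmetric model produce mirror-image solutions down to
solver tolerance.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshError

__all__ = [
    "symmetrize_x",
    "ellipsoid_surface",
    "tube_surface",
    "basin_surface",
    "ruled_sheet",
]


def symmetrize_x(vertices: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Snap near-mirror vertex pairs to exact mirror images through x = 0.

    Vertices within ``tol`` of the plane are snapped onto it.  Vertices
    whose reflection matches another vertex within ``tol`` are averaged
    with it so the pair becomes bitwise mirror-symmetric."""
    v = np.array(vertices, dtype=float)
    mirrored = v * np.array([-1.0, 1.0, 1.0])
    tree = cKDTree(v)
    dist, idx = tree.query(mirrored, k=1)
    done = np.zeros(len(v), dtype=bool)
    for i in range(len(v)):
        if done[i] or dist[i] > tol:
            continue
        j = idx[i]
        if j == i:
            v[i, 0] = 0.0
            done[i] = True
            continue
        x = 0.5 * (v[i, 0] - v[j, 0])
        yz = 0.5 * (v[i, 1:] + v[j, 1:])
        v[i] = (x, *yz)
        v[j] = (-x, *yz)
        done[i] = done[j] = True
    return v


def _quad_faces(idx_a, idx_b, x_centers):
    """Triangulate one strip of quads between two vertex index rows.

    ``idx_a[j]``/``idx_b[j]`` are the bottom/top rows; quad j spans columns
    j..j+1.  The split diagonal flips with the sign of ``x_centers[j]``."""
    faces = []
    for j in range(len(idx_a) - 1):
        a0, a1 = idx_a[j], idx_a[j + 1]
        b0, b1 = idx_b[j], idx_b[j + 1]
        if x_centers[j] >= 0.0:
            faces.append((a0, a1, b1))
            faces.append((a0, b1, b0))
        else:
            faces.append((a0, a1, b0))
            faces.append((a1, b1, b0))
    return faces


def _phi_count(circumference: float, h: float, minimum: int = 8) -> int:
    n = max(minimum, int(round(circumference / h)))
    return int(np.ceil(n / 4.0)) * 4  # multiple of 4 keeps nodes on x = 0


def ellipsoid_surface(center, semiaxes, h):
    """Closed UV-tessellated ellipsoid; x is the lateral semi-axis.

    Returns (vertices, faces, meta) where meta records the pole indices and
    the ring structure."""
    cx = np.asarray(center, dtype=float)
    a, b, c = (float(s) for s in semiaxes)
    if min(a, b, c) <= 0.0:
        raise MeshError("ellipsoid semi-axes must be positive")
    r_mean = (a * b * c) ** (1.0 / 3.0)
    n_theta = max(4, int(round(np.pi * r_mean / h)))
    n_phi = _phi_count(2.0 * np.pi * r_mean, h)
    verts = [cx + np.array([0.0, 0.0, c])]  # top pole
    rings = []
    for i in range(1, n_theta):
        th = np.pi * i / n_theta
        ring = []
        for j in range(n_phi):
            ph = 2.0 * np.pi * j / n_phi
            ring.append(len(verts))
            verts.append(
                cx
                + np.array(
                    [
                        a * np.sin(th) * np.cos(ph),
                        b * np.sin(th) * np.sin(ph),
                        c * np.cos(th),
                    ]
                )
            )
        rings.append(ring)
    bottom = len(verts)
    verts.append(cx + np.array([0.0, 0.0, -c]))
    verts = np.asarray(verts)
    faces = []
    # top fan
    top_ring = rings[0]
    for j in range(n_phi):
        faces.append((0, top_ring[j], top_ring[(j + 1) % n_phi]))
    # quad strips
    for i in range(len(rings) - 1):
        ra = rings[i]
        rb = rings[i + 1]
        ra_w = ra + [ra[0]]
        rb_w = rb + [rb[0]]
        xc = 0.5 * (verts[ra_w[:-1], 0] + verts[np.roll(ra, -1), 0])
        faces.extend(_quad_faces(rb_w, ra_w, xc))
    # bottom fan
    bot_ring = rings[-1]
    for j in range(n_phi):
        faces.append((bottom, bot_ring[(j + 1) % n_phi], bot_ring[j]))
    meta = {"rings": rings, "top_pole": 0, "bottom_pole": bottom, "n_phi": n_phi}
    return verts, np.asarray(faces, dtype=np.int64), meta


def _bezier(p0, p1, p2, t):
    t = np.asarray(t, dtype=float)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def tube_surface(axis_points, a_lat, b_sag, h, cap_end=False, cap_start=False):
    """Elliptic tube along a midsagittal axis polyline.

    ``a_lat`` is the lateral (x) half-width, ``b_sag`` the in-plane one.
    ``cap_end=True`` closes the far end with a triangle fan to the axis
    endpoint (a closed organ apex); meta records that apex vertex.
    ``cap_start=True`` closes the near end likewise (meta ``start_cap``);
    a free membrane edge has no transverse stiffness, so ends that carry
    load are always capped."""
    pts = np.asarray(axis_points, dtype=float)
    if np.max(np.abs(pts[:, 0])) > 1e-9:
        raise MeshError("tube axis must lie in the midsagittal plane")
    seg = np.diff(pts, axis=0)
    arclen = np.concatenate(([0.0], np.cumsum(np.linalg.norm(seg, axis=1))))
    total = arclen[-1]
    n_rings = max(3, int(round(total / h)) + 1)
    s = np.linspace(0.0, total, n_rings)
    axis = np.empty((n_rings, 3))
    for k in range(3):
        axis[:, k] = np.interp(s, arclen, pts[:, k])
    # tangents in the sagittal plane
    tang = np.gradient(axis, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    lat = np.array([1.0, 0.0, 0.0])
    m = np.cross(tang, lat)
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    n_phi = _phi_count(np.pi * (a_lat + b_sag), h)
    verts = []
    rings = []
    for i in range(n_rings):
        ring = []
        for j in range(n_phi):
            ph = 2.0 * np.pi * j / n_phi
            ring.append(len(verts))
            verts.append(axis[i] + a_lat * np.cos(ph) * lat + b_sag * np.sin(ph) * m[i])
        rings.append(ring)
    apex = None
    if cap_end:
        apex = len(verts)
        verts.append(axis[-1] + 0.35 * b_sag * tang[-1])
    start_cap = None
    if cap_start:
        start_cap = len(verts)
        verts.append(axis[0] - 0.35 * b_sag * tang[0])
    verts = np.asarray(verts)
    faces = []
    for i in range(n_rings - 1):
        ra = rings[i] + [rings[i][0]]
        rb = rings[i + 1] + [rings[i + 1][0]]
        xc = 0.5 * (verts[ra[:-1], 0] + verts[np.roll(rings[i], -1), 0])
        faces.extend(_quad_faces(ra, rb, xc))
    if cap_end:
        last = rings[-1]
        for j in range(n_phi):
            faces.append((apex, last[j], last[(j + 1) % n_phi]))
    if cap_start:
        first = rings[0]
        for j in range(n_phi):
            faces.append((start_cap, first[(j + 1) % n_phi], first[j]))
    meta = {
        "rings": rings,
        "apex": apex,
        "start_cap": start_cap,
        "n_phi": n_phi,
        "arc_positions": (s / total).tolist(),
    }
    return verts, np.asarray(faces, dtype=np.int64), meta


def basin_surface(center_xy, rx, ry, rim_z, depth, h):
    """Elliptic basin membrane (pelvic floor): z = rim_z - depth*(1 - r^2).

    meta records the border (rim) ring for the Encastre boundary."""
    cx, cy = center_xy
    if abs(cx) > 1e-12:
        raise MeshError("basin centre must be on the midsagittal plane")
    n_r = max(3, int(round(0.5 * (rx + ry) / h)))
    n_phi = _phi_count(np.pi * (rx + ry), h)
    verts = [np.array([0.0, cy, rim_z - depth])]
    rings = []
    for i in range(1, n_r + 1):
        r = i / n_r
        ring = []
        for j in range(n_phi):
            ph = 2.0 * np.pi * j / n_phi
            ring.append(len(verts))
            verts.append(
                np.array(
                    [
                        rx * r * np.cos(ph),
                        cy + ry * r * np.sin(ph),
                        rim_z - depth * (1.0 - r * r),
                    ]
                )
            )
        rings.append(ring)
    verts = np.asarray(verts)
    faces = []
    first = rings[0]
    for j in range(n_phi):
        faces.append((0, first[j], first[(j + 1) % n_phi]))
    for i in range(len(rings) - 1):
        ra = rings[i] + [rings[i][0]]
        rb = rings[i + 1] + [rings[i + 1][0]]
        xc = 0.5 * (verts[ra[:-1], 0] + verts[np.roll(rings[i], -1), 0])
        faces.extend(_quad_faces(ra, rb, xc))
    meta = {"rings": rings, "border": rings[-1], "n_phi": n_phi, "center": 0}
    return verts, np.asarray(faces, dtype=np.int64), meta


def ruled_sheet(curve_a, curve_b, h):
    """Ruled membrane sheet between two polylines with equal point counts.

    meta records the two boundary rows (``row_a`` on curve_a, ``row_b``)."""
    A = np.asarray(curve_a, dtype=float)
    B = np.asarray(curve_b, dtype=float)
    if A.shape != B.shape:
        raise MeshError("ruled sheet curves must have matching shapes")
    span = float(np.mean(np.linalg.norm(B - A, axis=1)))
    n_s = max(2, int(round(span / h)))
    n_c = A.shape[0]
    verts = []
    grid = np.empty((n_s + 1, n_c), dtype=np.int64)
    for i in range(n_s + 1):
        t = i / n_s
        row = (1.0 - t) * A + t * B
        for j in range(n_c):
            grid[i, j] = len(verts)
            verts.append(row[j])
    verts = np.asarray(verts)
    faces = []
    for i in range(n_s):
        xc = 0.5 * (verts[grid[i, :-1], 0] + verts[grid[i, 1:], 0])
        faces.extend(_quad_faces(list(grid[i]), list(grid[i + 1]), xc))
    meta = {"row_a": list(grid[0]), "row_b": list(grid[-1]), "grid": grid}
    return verts, np.asarray(faces, dtype=np.int64), meta
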