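"""Watertight-mesh geometry primitives.

Everything downstream (registration, trunk measurements) reduces to a small
set of exact geometric operations on triangle meshes: transverse plane
slicing, planar polygon metrics (area, centroid, principal axis), volumes of
plane-bounded slabs, clipped surface areas, and polyline arclength.

Conventions
-----------
* Internal length unit is **millimetres**; reporting units (cm, dm^2, L, mm,
  degrees) are produced only at the reporting boundary via the ``MM2CM``,
  ``MM2_2DM2`` and ``MM3_2L`` constants.
* Meshes are :class:`trimesh.Trimesh` objects with counter-clockwise faces
  seen from outside.  :func:`make_mesh` is the checked constructor.
* Cross-section polygons are stored counter-clockwise in an in-plane
  orthonormal basis ``(u, v)`` supplied by the caller (u = lateral,
  v = anteroposterior for body-frame slices).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

logger = logging.getLogger("torsometry")

# unit conversions (internal mm -> reporting units)
MM2CM = 0.1          # length: mm -> cm
MM2_2DM2 = 1e-4      # area:   mm^2 -> dm^2
MM3_2L = 1e-6        # volume: mm^3 -> L

_MERGE_TOL = 1e-6    # endpoint merge tolerance for slice-loop assembly (mm)


class GeometryError(ValueError):
    """Raised when a geometric precondition is violated."""


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def make_mesh(vertices, faces, require_watertight: bool = True) -> trimesh.Trimesh:
    """Build a cleaned :class:`trimesh.Trimesh` and verify its invariants.

    Degenerate (zero-area) faces are removed; face indices are checked; when
    ``require_watertight`` the mesh must be a closed 2-manifold with
    consistent winding (every edge shared by exactly two faces).
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise GeometryError("face indices out of range")
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    area_faces = mesh.area_faces
    if np.any(area_faces <= 0):
        mesh.update_faces(area_faces > 0)
    if require_watertight and not (mesh.is_watertight and mesh.is_winding_consistent):
        raise GeometryError("mesh is not a watertight, consistently wound manifold")
    return mesh


def load_mesh(path) -> trimesh.Trimesh:
    """Load OBJ/PLY/STL; returns a single concatenated Trimesh."""
    loaded = trimesh.load(path, force="mesh", process=False)
    return trimesh.Trimesh(vertices=loaded.vertices, faces=loaded.faces, process=False)


# ---------------------------------------------------------------------------
# planes and cross-sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point on it and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise GeometryError("plane normal must be non-zero")
            n = n / norm
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """An orthonormal in-plane basis (u, v) with u x v = normal."""
        n = self.normal
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(ref, n)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v


@dataclass
class CrossSection:
    """A closed, simple, counter-clockwise planar polygon from a mesh slice.

    ``polygon`` holds the ring vertices (N x 2, mm) in the in-plane basis
    ``basis = (u, v)`` without repeating the first point.  ``level_t`` is the
    normalized trunk level (0 = PSIS, 1 = C7) when the slice came from a
    body-frame level; NaN otherwise.
    """

    plane: Plane
    polygon: np.ndarray
    basis: tuple[np.ndarray, np.ndarray]
    level_t: float = float("nan")

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise GeometryError("cross-section polygon needs >= 3 planar points")
        if _shoelace(poly) < 0:
            poly = poly[::-1]
        self.polygon = poly

    def is_simple(self) -> bool:
        from shapely.geometry import LinearRing

        try:
            return LinearRing(self.polygon).is_simple
        except Exception:
            return False

    def points_3d(self) -> np.ndarray:
        u, v = self.basis
        return self.plane.point + self.polygon[:, :1] * u + self.polygon[:, 1:] * v

    def to_csv(self, path) -> None:
        """Dump the in-plane polygon as CSV, one `x,y` row per vertex (mm)."""
        np.savetxt(path, self.polygon, delimiter=",", header="x_mm,y_mm",
                   comments="", fmt="%.6f")


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_cross_terms(poly: np.ndarray):
    """Per-edge cross products used by the polygon-moment closed forms."""
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return x, y, x1, y1, x * y1 - x1 * y


def polygon_area(section: CrossSection) -> float:
    """Enclosed area of the cross-section (mm^2), shoelace formula."""
    return abs(_shoelace(section.polygon))


def polygon_centroid(section: CrossSection) -> np.ndarray:
    """Area-weighted centroid of the enclosed region (mm, in-plane coords)."""
    x, y, x1, y1, c = _polygon_cross_terms(section.polygon)
    a = 0.5 * np.sum(c)
    if abs(a) < 1e-12:
        raise GeometryError("zero-area polygon has no centroid")
    cx = np.sum((x + x1) * c) / (6.0 * a)
    cy = np.sum((y + y1) * c) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moments(section: CrossSection):
    """Central second area moments (Sxx=int x^2 dA, Syy, Sxy) about the centroid."""
    x, y, x1, y1, c = _polygon_cross_terms(section.polygon)
    a = 0.5 * np.sum(c)
    cx, cy = polygon_centroid(section)
    sxx = np.sum(c * (x * x + x * x1 + x1 * x1)) / 12.0
    syy = np.sum(c * (y * y + y * y1 + y1 * y1)) / 12.0
    sxy = np.sum(c * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    sxx -= a * cx * cx
    syy -= a * cy * cy
    sxy -= a * cx * cy
    if a < 0:
        sxx, syy, sxy = -sxx, -syy, -sxy
    return sxx, syy, sxy


def polygon_principal_axis(section: CrossSection) -> float:
    """Signed angle (deg) of the MAJOR principal area axis to the +u axis.

    Wrapped to (-90, +90]; positive rotates +u toward +v (right-handed).
    Raises for isotropic sections (equal moments within 1e-9 relative).
    """
    sxx, syy, sxy = polygon_second_moments(section)
    tensor = np.array([[sxx, sxy], [sxy, syy]])
    evals, evecs = np.linalg.eigh(tensor)
    scale = max(abs(evals[0]), abs(evals[1]), 1e-300)
    if abs(evals[1] - evals[0]) <= 1e-9 * scale:
        raise GeometryError("axis undefined: isotropic section")
    major = evecs[:, int(np.argmax(evals))]
    angle = np.degrees(np.arctan2(major[1], major[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


# ---------------------------------------------------------------------------
# plane slicing
# ---------------------------------------------------------------------------

def _face_plane_segments(mesh: trimesh.Trimesh, plane: Plane) -> np.ndarray:
    """Oriented intersection segments (n, 2, 3) of mesh faces with a plane.

    Each segment points along cross(plane.normal, face_normal) so chained
    segments walk counter-clockwise in any basis (u, v) with u x v = normal.
    Vertices exactly on the plane are nudged to the positive side
    (simulation of simplicity), keeping loops closed on watertight input.
    """
    verts = mesh.vertices
    d = plane.signed_distance(verts)
    d = np.where(np.abs(d) < 1e-9, 1e-9, d)
    fd = d[mesh.faces]                       # (F, 3)
    crossing = ~(np.all(fd > 0, axis=1) | np.all(fd < 0, axis=1))
    if not np.any(crossing):
        return np.zeros((0, 2, 3))
    segs = []
    fnormals = mesh.face_normals
    for fi in np.nonzero(crossing)[0]:
        tri = mesh.faces[fi]
        pts = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = d[tri[a]], d[tri[b]]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                pts.append(verts[tri[a]] + t * (verts[tri[b]] - verts[tri[a]]))
        if len(pts) != 2:
            continue
        p0, p1 = pts
        direction = np.cross(plane.normal, fnormals[fi])
        if (p1 - p0) @ direction < 0:
            p0, p1 = p1, p0
        if np.linalg.norm(p1 - p0) > 1e-12:
            segs.append((p0, p1))
    if not segs:
        return np.zeros((0, 2, 3))
    return np.array(segs)


def slice_mesh(mesh: trimesh.Trimesh, plane: Plane,
               frame_basis: tuple[np.ndarray, np.ndarray] | None = None,
               level_t: float = float("nan")) -> list[CrossSection]:
    """Intersect a watertight mesh with a plane into closed cross-sections.

    Edge chains are assembled from face/plane segments with endpoint merging
    at 1e-6 mm.  Multiple loops are returned sorted by |area| descending;
    an empty intersection returns ``[]``.  Open chains (non-watertight
    input) raise, naming the gap location.
    """
    segs = _face_plane_segments(mesh, plane)
    if len(segs) == 0:
        return []
    if frame_basis is None:
        frame_basis = plane.basis()
    u, v = frame_basis

    def key(p):
        return tuple(np.round(p / _MERGE_TOL).astype(np.int64))

    start_index: dict[tuple, list[int]] = {}
    for i, (p0, _p1) in enumerate(segs):
        start_index.setdefault(key(p0), []).append(i)

    used = np.zeros(len(segs), dtype=bool)
    sections: list[CrossSection] = []
    for i0 in range(len(segs)):
        if used[i0]:
            continue
        chain = [segs[i0][0]]
        cur = i0
        used[i0] = True
        start_key = key(segs[i0][0])
        while True:
            end = segs[cur][1]
            k = key(end)
            if k == start_key:
                break
            nxt = None
            for cand in start_index.get(k, ()):
                if not used[cand]:
                    nxt = cand
                    break
            if nxt is None:
                raise GeometryError(
                    "open slice chain (non-watertight input?) near point "
                    f"({end[0]:.3f}, {end[1]:.3f}, {end[2]:.3f}) mm")
            chain.append(end)
            used[nxt] = True
            cur = nxt
        pts = np.asarray(chain)
        rel = pts - plane.point
        poly = np.column_stack([rel @ u, rel @ v])
        keep = np.ones(len(poly), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > _MERGE_TOL
        poly = poly[keep]
        if len(poly) >= 3:
            # drop collinear vertices (e.g. face-diagonal crossings on flat walls)
            prev = np.roll(poly, 1, axis=0)
            nxt = np.roll(poly, -1, axis=0)
            e1, e2 = poly - prev, nxt - poly
            turn = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
            scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            poly = poly[turn > 1e-9 * np.maximum(scale, 1e-12)]
        if len(poly) < 3 or abs(_shoelace(poly)) < 1e-9:
            continue
        sections.append(CrossSection(plane=plane, polygon=poly,
                                     basis=(u, v), level_t=level_t))
    sections.sort(key=polygon_area, reverse=True)
    if len(sections) > 1:
        logger.warning("plane slice produced %d loops; largest kept as torso "
                       "outline (extra loops may indicate registration failure)",
                       len(sections))
    return sections


# ---------------------------------------------------------------------------
# slab clipping: volumes and clipped surface areas
# ---------------------------------------------------------------------------

def _clip_poly_halfspace(poly: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a 3D polygon against d(x) >= 0.

    ``d`` holds the signed distances of ``poly``'s vertices.
    """
    out = []
    n = len(poly)
    for i in range(n):
        j = (i + 1) % n
        pi, pj = poly[i], poly[j]
        di, dj = d[i], d[j]
        if di >= 0:
            out.append(pi)
            if dj < 0:
                out.append(pi + (di / (di - dj)) * (pj - pi))
        elif dj >= 0:
            out.append(pi + (di / (di - dj)) * (pj - pi))
    return np.asarray(out) if out else np.zeros((0, 3))


def _oriented_slab(plane_lo: Plane, plane_hi: Plane):
    """Common slab normal n (lo -> hi) and the two bounding offsets."""
    n = plane_lo.normal.copy()
    if abs(abs(plane_lo.normal @ plane_hi.normal) - 1.0) > 1e-6:
        raise GeometryError("slab planes are not parallel")
    if n @ (plane_hi.point - plane_lo.point) < 0:
        n = -n
    h = float(n @ (plane_hi.point - plane_lo.point))
    if h <= 0:
        raise GeometryError("plane_lo must lie below plane_hi")
    return n, h


def _triangulate_fan(poly: np.ndarray) -> np.ndarray:
    """(n-2, 3, 3) triangle fan of a planar polygon about its first vertex."""
    return np.stack([np.broadcast_to(poly[0], (len(poly) - 2, 3)),
                     poly[1:-1], poly[2:]], axis=1)


def _cap_volume(mesh: trimesh.Trimesh, plane: Plane, outward: np.ndarray) -> float:
    """Signed divergence-theorem volume contribution of planar caps.

    Cut loops are triangulated by a centroid fan (valid for star-shaped
    loops about their centroid; torso sections are) and oriented so the cap
    normal equals ``outward``.
    """
    u, v = plane.basis()  # u x v = plane.normal
    total = 0.0
    for sec in slice_mesh(mesh, plane, frame_basis=(u, v)):
        centroid2 = polygon_centroid(sec)
        ring = sec.points_3d()
        c3 = plane.point + centroid2[0] * u + centroid2[1] * v
        a, b = ring, np.roll(ring, -1, axis=0)
        # fan triangles (c3, a_i, b_i) have normal +plane.normal for a CCW
        # ring in (u, v); signed tetra volumes about the origin
        tets = np.einsum("ij,ij->i", np.cross(a, b), np.broadcast_to(c3, a.shape))
        vol = float(np.sum(tets)) / 6.0
        if outward @ plane.normal < 0:
            vol = -vol
        total += vol
    return total


def section_volume(mesh: trimesh.Trimesh, plane_lo: Plane, plane_hi: Plane) -> float:
    """Volume (litres) of the mesh portion between two transverse planes.

    The surface is clipped to the slab, cut boundaries are capped with
    centroid fans, and the enclosed volume follows from the divergence
    theorem on the resulting closed surface.
    """
    if not mesh.is_watertight:
        raise GeometryError("section_volume requires a watertight mesh")
    n, h = _oriented_slab(plane_lo, plane_hi)
    verts = mesh.vertices
    d_lo = (verts - plane_lo.point) @ n          # keep d_lo >= 0
    d_hi = h - d_lo                              # keep d_hi >= 0
    tri_d_lo = d_lo[mesh.faces]
    tri_d_hi = d_hi[mesh.faces]
    total = 0.0
    inside = np.all(tri_d_lo >= 0, axis=1) & np.all(tri_d_hi >= 0, axis=1)
    outside = np.all(tri_d_lo < 0, axis=1) | np.all(tri_d_hi < 0, axis=1)
    tris_in = mesh.triangles[inside]
    if len(tris_in):
        total += float(np.sum(np.einsum(
            "ij,ij->i", np.cross(tris_in[:, 0], tris_in[:, 1]), tris_in[:, 2]))) / 6.0
    for fi in np.nonzero(~inside & ~outside)[0]:
        poly = mesh.triangles[fi]
        poly = _clip_poly_halfspace(poly, tri_d_lo[fi])
        if len(poly) < 3:
            continue
        poly = _clip_poly_halfspace(poly, (h - (poly - plane_lo.point) @ n))
        if len(poly) < 3:
            continue
        fan = _triangulate_fan(poly)
        total += float(np.sum(np.einsum(
            "ij,ij->i", np.cross(fan[:, 0], fan[:, 1]), fan[:, 2]))) / 6.0
    lo_plane = Plane(plane_lo.point, n)
    hi_plane = Plane(plane_lo.point + h * n, n)
    if np.min(d_lo) < 0:
        total += _cap_volume(mesh, lo_plane, outward=-n)
    if np.min(d_hi) < 0:
        total += _cap_volume(mesh, hi_plane, outward=n)
    return total * MM3_2L


def _poly_area_3d(poly: np.ndarray) -> float:
    a, b = poly, np.roll(poly, -1, axis=0)
    return 0.5 * float(np.linalg.norm(np.sum(np.cross(a, b), axis=0)))


def region_surface_area(mesh: trimesh.Trimesh, face_subset,
                        plane_lo: Plane | None = None,
                        plane_hi: Plane | None = None) -> float:
    """Surface area (dm^2) of a face subset, exactly clipped to a slab.

    Boundary triangles are Sutherland-Hodgman clipped against both slab
    planes rather than included or excluded whole, making the result stable
    under remeshing.  With no planes the subset area is unclipped.
    """
    face_subset = np.asarray(face_subset)
    if face_subset.dtype == bool:
        face_subset = np.nonzero(face_subset)[0]
    if len(face_subset) == 0:
        warnings.warn("region_surface_area: empty face subset", stacklevel=2)
        return 0.0
    if plane_lo is None and plane_hi is None:
        return float(mesh.area_faces[face_subset].sum()) * MM2_2DM2
    n, h = _oriented_slab(plane_lo, plane_hi)
    total = 0.0
    for fi in face_subset:
        poly = mesh.triangles[fi]
        d = (poly - plane_lo.point) @ n
        if np.all(d >= 0) and np.all(d <= h):
            total += mesh.area_faces[fi]
            continue
        poly = _clip_poly_halfspace(poly, d)
        if len(poly) < 3:
            continue
        poly = _clip_poly_halfspace(poly, h - (poly - plane_lo.point) @ n)
        if len(poly) < 3:
            continue
        total += _poly_area_3d(poly)
    return total * MM2_2DM2


def polyline_arclength(points) -> float:
    """Arclength (cm) of an ordered 3D polyline."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise GeometryError("polyline needs at least two points")
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1))) * MM2CM


# ---------------------------------------------------------------------------
# closest-point queries (KD-tree over triangles, exact projection)
# ---------------------------------------------------------------------------

class SurfaceProximity:
    """Exact closest-point-on-surface queries against a fixed triangle mesh.

    Candidate triangles come from a KD-tree over triangle centroids
    (k nearest, default 12); the exact closest point on each candidate is
    found by barycentric clamping and the global minimum kept.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 12):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles)
        self.k = min(k, len(self.triangles))
        self._tree = cKDTree(self.triangles.mean(axis=1))
        self._fnormals = np.asarray(mesh.face_normals)

    def query(self, points):
        """Return (closest_points, distances, face_indices, barycentric)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        m, k = cand.shape
        tri = self.triangles[cand.ravel()]          # (m*k, 3, 3)
        p = np.repeat(points, k, axis=0)
        cp, bary = _closest_point_triangle(p, tri[:, 0], tri[:, 1], tri[:, 2])
        dist = np.linalg.norm(cp - p, axis=1).reshape(m, k)
        best = np.argmin(dist, axis=1)
        rows = np.arange(m)
        flat = rows * k + best
        return (cp[flat], dist[rows, best], cand[rows, best], bary[flat])

    def face_normal(self, face_indices):
        return self._fnormals[np.asarray(face_indices)]


def _closest_point_triangle(p, a, b, c):
    """Vectorized closest point on triangles (a,b,c) to points p.

    Returns (closest, barycentric) with barycentric = (w_a, w_b, w_c).
    Standard region-based algorithm (Ericson).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    out = np.zeros_like(p)
    bary = np.zeros_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, pts, w):
        m = mask & ~done
        out[m] = pts[m]
        bary[m] = w[m]
        done[m] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), a, np.tile([1.0, 0, 0], (len(p), 1)))
    settle((d3 >= 0) & (d4 <= d3), b, np.tile([0, 1.0, 0], (len(p), 1)))
    settle((d6 >= 0) & (d5 <= d6), c, np.tile([0, 0, 1.0], (len(p), 1)))
    # edge AB
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    w = np.column_stack([1 - t, t, np.zeros_like(t)])
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab, w)
    # edge AC
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    w = np.column_stack([1 - t, np.zeros_like(t), t])
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t[:, None] * ac, w)
    # edge BC
    va = d3 * d6 - d5 * d4
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den != 0, num / den, 0.0)
    w = np.column_stack([np.zeros_like(t), 1 - t, t])
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t[:, None] * (c - b), w)
    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        wgt = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    w = np.column_stack([1 - v - wgt, v, wgt])
    settle(np.ones(len(p), dtype=bool), a + v[:, None] * ab + wgt[:, None] * ac, w)
    return out, bary
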