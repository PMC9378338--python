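"""Torso template atlas and template-to-scan registration.

The measurement pipeline never works on a raw scan directly: a generic,
perfectly symmetric torso template ("atlas") is deformed onto the scan with
a stiffness-regularized nonrigid ICP.  The result is a clean watertight
torso with the template's connectivity, so every anatomical definition made
once on the template (nine landmarks, the dorsal midline chain, left/right
dorsal face regions) transfers to every registered scan for free.

Axes convention: +x = patient right, +y = anterior, +z = cranial.

The template is generated programmatically as a stack of torso cross
sections on a regular grid (``n_levels`` rings of ``n_around`` vertices
plus two cap fans); its mirror symmetry, landmark indices and face labels
are exact by construction.  The cross-section profile has an elliptic front
and a flattened back (anatomically, backs are far flatter than an ellipse),
with an optional one-sided posterior hump used by the synthetic generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

from .geometry import (GeometryError, SurfaceProximity, logger, make_mesh)

LANDMARK_NAMES = ("PSIS_L", "PSIS_R", "ASIS_L", "ASIS_R", "XP", "JN",
                  "SP_L2", "SP_T8", "SP_C7")

# (trunk-level fraction t, ring-column fraction j/N); column 0 is the
# anterior midline, column 1/2 the posterior midline.  All j fractions have
# denominator 16 and all t fractions denominator 20, so landmarks fall on
# exact grid vertices whenever n_around % 16 == 0 and (n_levels-1) % 20 == 0.
LANDMARK_GRID = {
    "PSIS_L": (0.00, 7 / 16),
    "PSIS_R": (0.00, 9 / 16),
    "ASIS_L": (0.05, 1 / 16),
    "ASIS_R": (0.05, 15 / 16),
    "XP":     (0.70, 0.0),
    "JN":     (0.95, 0.0),
    "SP_L2":  (0.25, 0.5),
    "SP_T8":  (0.55, 0.5),
    "SP_C7":  (1.00, 0.5),
}

_ALIAS = {"L2": "SP_L2", "T8": "SP_T8", "C7": "SP_C7"}


def canonical_landmark_name(name: str) -> str:
    return _ALIAS.get(name, name)


class RegistrationError(RuntimeError):
    """Raised when nonrigid registration fails to converge."""


# ---------------------------------------------------------------------------
# landmark sets
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named anatomical 3D points (mm).

    The nine canonical landmarks must all be present; AC_L / AC_R
    (acromioclavicular joints) may be carried additionally for evaluation.
    """

    points: dict

    def __post_init__(self):
        self.points = {canonical_landmark_name(k): np.asarray(v, dtype=float)
                       for k, v in self.points.items()}
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValueError(f"missing landmarks: {missing}")

    def __getitem__(self, name):
        return self.points[canonical_landmark_name(name)]

    def __contains__(self, name):
        return canonical_landmark_name(name) in self.points

    def psis_centroid(self) -> np.ndarray:
        return 0.5 * (self["PSIS_L"] + self["PSIS_R"])

    def check_sidedness(self) -> bool:
        """Left/right pairs must straddle the fitted sagittal plane."""
        n = self["PSIS_R"] - self["PSIS_L"]
        n = n / np.linalg.norm(n)
        mids = []
        for base in ("PSIS", "ASIS"):
            mids.append(0.5 * (self[f"{base}_L"] + self[f"{base}_R"]))
        mid = np.mean(mids, axis=0)
        for base in ("PSIS", "ASIS"):
            if (self[f"{base}_L"] - mid) @ n >= 0 or (self[f"{base}_R"] - mid) @ n <= 0:
                return False
        return True

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        pts = {k: (matrix[:3, :3] @ v + matrix[:3, 3]) for k, v in self.points.items()}
        return LandmarkSet(pts)

    def to_json(self) -> str:
        return json.dumps({k: list(map(float, v)) for k, v in self.points.items()},
                          indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkSet":
        return cls({k: np.asarray(v) for k, v in json.loads(text).items()})


# ---------------------------------------------------------------------------
# parametric torso cross-section profile
# ---------------------------------------------------------------------------

def torso_outline(phi, a: float, b: float, profile: str = "flatback",
                  flat_frac: float = 0.45, hump: float = 0.0,
                  hump_phi0: float = 3 * np.pi / 2 - np.pi / 6,
                  hump_sigma: float = 0.35) -> np.ndarray:
    """Cross-section outline points at angles ``phi`` (radians, CCW from +x).

    ``profile='ellipse'`` is the plain ellipse with semi-axes (a, b);
    ``'flatback'`` keeps the elliptic front but replaces the back with a
    straight segment of half-width ``flat_frac * a`` at depth ``-b``,
    rounded to the flanks by quarter ellipses.  ``hump`` adds a one-sided
    Gaussian radial bump h*exp(-(phi-phi0)^2 / 2 sigma^2) (paraspinal
    prominence).  The region is star-shaped about the origin, so the
    outline is returned as r(phi)*(cos phi, sin phi).
    """
    phi = np.mod(np.asarray(phi, dtype=float), 2 * np.pi)
    c, s = np.cos(phi), np.sin(phi)
    r_ell = a * b / np.sqrt((b * c) ** 2 + (a * s) ** 2)
    if profile == "ellipse":
        r = r_ell
    elif profile == "flatback":
        r = r_ell.copy()
        post = s < 0
        xf = flat_frac * a
        # flat segment y = -b for |x| <= xf
        with np.errstate(divide="ignore", invalid="ignore"):
            r_flat = np.where(post, b / np.maximum(-s, 1e-12), np.inf)
        on_flat = post & (np.abs(r_flat * c) <= xf)
        r = np.where(on_flat, r_flat, r)
        # quarter-ellipse rounding centered (+-xf, 0), semi-axes (a-xf, b)
        round_side = post & ~on_flat
        if np.any(round_side):
            sgn = np.sign(c)
            ra, rb = a - xf, b
            # solve ((r c - sgn xf)/ra)^2 + (r s / rb)^2 = 1 for r > 0
            A = (c / ra) ** 2 + (s / rb) ** 2
            B = -2 * sgn * xf * c / ra ** 2
            C = (xf / ra) ** 2 - 1.0
            disc = np.maximum(B * B - 4 * A * C, 0.0)
            r_round = (-B + np.sqrt(disc)) / (2 * A)
            r = np.where(round_side, r_round, r)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    if hump:
        dphi = np.mod(phi - hump_phi0 + np.pi, 2 * np.pi) - np.pi
        r = r + hump * np.exp(-0.5 * (dphi / hump_sigma) ** 2)
    return np.column_stack([r * c, r * s])


def outline_area_centroid(outline: np.ndarray):
    """(area, centroid) of a closed outline polygon (shoelace)."""
    x, y = outline[:, 0], outline[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    area = 0.5 * np.sum(cr)
    cx = np.sum((x + x1) * cr) / (6 * area)
    cy = np.sum((y + y1) * cr) / (6 * area)
    return float(area), np.array([cx, cy])


# ---------------------------------------------------------------------------
# grid torso construction
# ---------------------------------------------------------------------------

def ring_angles(n_around: int) -> np.ndarray:
    """Column angles phi_j = pi/2 + 2 pi j / N (column 0 = anterior midline)."""
    return np.pi / 2 + 2 * np.pi * np.arange(n_around) / n_around


def build_grid_torso(height: float, a_of_t, b_of_t, n_levels: int,
                     n_around: int, profile: str = "flatback",
                     flat_frac: float = 0.45,
                     bow_of_t=None, twist_of_t=None,
                     hump: float = 0.0,
                     hump_phi0: float = 3 * np.pi / 2 - np.pi / 6,
                     hump_sigma: float = 0.35,
                     centroid_samples: int = 2048):
    """Stacked-cross-section torso mesh on a regular grid, plus metadata.

    Each level t_i = i/(n_levels-1) gets the outline for (a(t), b(t)),
    re-centred so its dense area centroid sits at the origin, rotated by
    twist(t) (radians, CCW seen from +z = from cranial), then translated to
    (bow(t), 0, t*height).  Returns ``(mesh, meta)`` where ``meta`` carries
    the grid layout, symmetry map, midline chain, face labels and landmark
    vertex indices.
    """
    if n_around < 32 or n_around % 16:
        raise ValueError("n_around must be >= 32 and divisible by 16")
    if n_levels < 21 or (n_levels - 1) % 20:
        raise ValueError("n_levels must be 20k+1 >= 21 (landmark levels on-grid)")
    a_fn = a_of_t if callable(a_of_t) else (lambda t, _a=float(a_of_t): _a)
    b_fn = b_of_t if callable(b_of_t) else (lambda t, _b=float(b_of_t): _b)
    bow_fn = bow_of_t if bow_of_t is not None else (lambda t: 0.0)
    twist_fn = twist_of_t if twist_of_t is not None else (lambda t: 0.0)

    phis = ring_angles(n_around)
    phis_dense = np.linspace(0, 2 * np.pi, centroid_samples, endpoint=False)
    levels_t = np.arange(n_levels) / (n_levels - 1)
    verts = np.empty((n_levels * n_around + 2, 3))
    kwargs = dict(profile=profile, flat_frac=flat_frac, hump=hump,
                  hump_phi0=hump_phi0, hump_sigma=hump_sigma)
    for i, t in enumerate(levels_t):
        a, b = a_fn(t), b_fn(t)
        if a <= 10 or b <= 10:
            raise ValueError("semi-axes must stay above 10 mm")
        ring = torso_outline(phis, a, b, **kwargs)
        _, cen = outline_area_centroid(torso_outline(phis_dense, a, b, **kwargs))
        ring = ring - cen
        th = twist_fn(t)
        if th:
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            ring = ring @ rot.T
        ring[:, 0] += bow_fn(t)
        verts[i * n_around:(i + 1) * n_around, 0:2] = ring
        verts[i * n_around:(i + 1) * n_around, 2] = t * height
    bot_c = n_levels * n_around
    top_c = bot_c + 1
    verts[bot_c] = [bow_fn(0.0), 0.0, 0.0]
    verts[top_c] = [bow_fn(1.0), 0.0, height]

    faces = []
    labels = []
    for i in range(n_levels - 1):
        for j in range(n_around):
            j1 = (j + 1) % n_around
            v00, v01 = i * n_around + j, i * n_around + j1
            v10, v11 = (i + 1) * n_around + j, (i + 1) * n_around + j1
            # outward CCW: ring angle increases CCW viewed from +z
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
            phi_mid = np.pi / 2 + 2 * np.pi * (j + 0.5) / n_around
            side = "left" if np.cos(phi_mid) < 0 else "right"
            aspect = "dorsal" if np.sin(phi_mid) < 0 else "ventral"
            labels.extend([f"{aspect}_{side}"] * 2)
    for j in range(n_around):
        j1 = (j + 1) % n_around
        faces.append([bot_c, j1, j])                       # bottom cap, normal -z
        labels.append("cap")
    base = (n_levels - 1) * n_around
    for j in range(n_around):
        j1 = (j + 1) % n_around
        faces.append([top_c, base + j, base + j1])         # top cap, normal +z
        labels.append("cap")

    mesh = make_mesh(verts, faces, require_watertight=True)

    symmetry = np.arange(len(verts))
    for i in range(n_levels):
        for j in range(n_around):
            symmetry[i * n_around + j] = i * n_around + (n_around - j) % n_around
    midline = np.array([i * n_around + n_around // 2 for i in range(n_levels)])
    landmark_index = {}
    for name, (t, jf) in LANDMARK_GRID.items():
        i = int(round(t * (n_levels - 1)))
        j = int(round(jf * n_around)) % n_around
        landmark_index[name] = i * n_around + j
    meta = dict(n_levels=n_levels, n_around=n_around, height=float(height),
                symmetry_map=symmetry, midline_chain=midline,
                face_labels=np.array(labels), landmark_index=landmark_index,
                levels_t=levels_t)
    return mesh, meta


# ---------------------------------------------------------------------------
# the template atlas
# ---------------------------------------------------------------------------

@dataclass
class TemplateAtlas:
    """Symmetric-connectivity torso template: the reference frame of all
    measurements.

    ``symmetry_map`` is an involution on vertex indices pairing left and
    right; ``midline_chain`` runs along the dorsal midline from the PSIS
    level to C7; every face carries a label in {dorsal_left, dorsal_right,
    ventral_left, ventral_right, cap}.
    """

    mesh: trimesh.Trimesh
    symmetry_map: np.ndarray
    landmark_index: dict
    midline_chain: np.ndarray
    face_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-6) -> None:
        sm = self.symmetry_map
        if not np.array_equal(sm[sm], np.arange(len(sm))):
            raise ValueError("symmetry_map is not an involution")
        mirrored = self.mesh.vertices.copy()
        mirrored[:, 0] *= -1.0
        if np.max(np.linalg.norm(mirrored[sm] - self.mesh.vertices, axis=1)) > tol:
            raise ValueError("template is not mirror-symmetric under symmetry_map")
        if np.any(sm[self.midline_chain] != self.midline_chain):
            raise ValueError("midline chain vertices must be symmetry fixed points")
        if not self.mesh.is_watertight:
            raise ValueError("template mesh must be watertight")
        for name in LANDMARK_NAMES:
            if name not in self.landmark_index:
                raise ValueError(f"missing landmark index {name}")

    def landmarks(self) -> LandmarkSet:
        return LandmarkSet({k: self.mesh.vertices[i]
                            for k, i in self.landmark_index.items()})

    def dorsal_faces(self) -> np.ndarray:
        return np.nonzero(np.isin(self.face_labels, ["dorsal_left", "dorsal_right"]))[0]

    def save(self, mesh_path, sidecar_path) -> None:
        """Serialize as PLY (ascii) + JSON sidecar."""
        self.mesh.export(mesh_path, encoding="ascii")
        sidecar = {
            "symmetry_map": self.symmetry_map.tolist(),
            "landmark_index": {k: int(v) for k, v in self.landmark_index.items()},
            "midline_chain": self.midline_chain.tolist(),
            "face_labels": self.face_labels.tolist(),
            "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in self.meta.items()
                     if k not in ("symmetry_map", "midline_chain", "face_labels",
                                  "landmark_index")},
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, mesh_path, sidecar_path) -> "TemplateAtlas":
        mesh = trimesh.load(mesh_path, force="mesh", process=False)
        mesh = make_mesh(mesh.vertices, mesh.faces)
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        atlas = cls(mesh=mesh,
                    symmetry_map=np.asarray(sc["symmetry_map"], dtype=np.int64),
                    landmark_index=sc["landmark_index"],
                    midline_chain=np.asarray(sc["midline_chain"], dtype=np.int64),
                    face_labels=np.asarray(sc["face_labels"]),
                    meta=sc.get("meta", {}))
        atlas.validate()
        return atlas


def _template_a(t):
    """Template lateral semi-axis (mm): hips / waist / chest / shoulders."""
    knots_t = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    knots_a = np.array([158.0, 142.0, 148.0, 162.0, 150.0])
    from scipy.interpolate import CubicSpline
    return float(CubicSpline(knots_t, knots_a)(t))


def build_template_atlas(n_levels: int = 61, n_around: int = 96,
                         height: float = 480.0) -> TemplateAtlas:
    """The shipped generic torso template (flat-backed, mirror symmetric).

    Defaults give a 61 x 96 grid over a 480 mm trunk (PSIS to C7), sized on
    adolescent torso proportions.
    """
    mesh, meta = build_grid_torso(height=height, a_of_t=_template_a,
                                  b_of_t=100.0, n_levels=n_levels,
                                  n_around=n_around, profile="flatback")
    atlas = TemplateAtlas(mesh=mesh, symmetry_map=meta["symmetry_map"],
                          landmark_index=meta["landmark_index"],
                          midline_chain=meta["midline_chain"],
                          face_labels=meta["face_labels"], meta=meta)
    atlas.validate()
    return atlas


@dataclass
class RegisteredTorso:
    """Atlas deformed into scan space: template connectivity, scan shape."""

    mesh: trimesh.Trimesh
    atlas: TemplateAtlas
    residual_rms: float

    def __post_init__(self):
        if len(self.mesh.vertices) != len(self.atlas.mesh.vertices) or \
           len(self.mesh.faces) != len(self.atlas.mesh.faces):
            raise ValueError("registered mesh must keep atlas vertex/face counts")

    def landmarks(self) -> LandmarkSet:
        return LandmarkSet({k: self.mesh.vertices[i]
                            for k, i in self.atlas.landmark_index.items()})


# ---------------------------------------------------------------------------
# rigid initialization
# ---------------------------------------------------------------------------

def _umeyama(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares similarity transform (rotation+scale+translation)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = np.mean(np.sum(sc ** 2, axis=1))
    scale = np.trace(np.diag(S) @ D) / var_s
    M = np.eye(4)
    M[:3, :3] = scale * R
    M[:3, 3] = mu_d - scale * R @ mu_s
    return M


def _apply(matrix: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ matrix[:3, :3].T + matrix[:3, 3]


def initial_rigid_align(atlas: TemplateAtlas, scan: trimesh.Trimesh,
                        hint_landmarks: LandmarkSet | None = None) -> np.ndarray:
    """Similarity (rigid + isotropic scale) alignment of template to scan.

    With ``hint_landmarks`` (debug/fixtures only) this is a landmark
    Procrustes fit.  The markerless default aligns principal axes of the
    two vertex clouds (longitudinal = largest extent), resolves the four
    axis-sign ambiguities by scoring subsampled closest-point RMS, and
    matches scale by longitudinal slab height.
    """
    if len(scan.vertices) == 0:
        raise GeometryError("empty scan")
    if hint_landmarks is not None:
        src = np.array([atlas.mesh.vertices[atlas.landmark_index[n]]
                        for n in LANDMARK_NAMES])
        dst = np.array([hint_landmarks[n] for n in LANDMARK_NAMES])
        return _umeyama(src, dst)

    tv = atlas.mesh.vertices
    sv = scan.vertices
    if np.linalg.matrix_rank(sv - sv.mean(axis=0), tol=1e-6) < 3:
        raise GeometryError("degenerate scan: rank < 3 point cloud")

    def pca_axes(pts):
        c = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - c, full_matrices=False)
        return c, Vt  # rows ordered by decreasing extent

    tc, taxes = pca_axes(tv)
    scc, saxes = pca_axes(sv)
    t_height = np.ptp((tv - tc) @ taxes[0])
    s_height = np.ptp((sv - scc) @ saxes[0])
    scale = s_height / t_height

    prox = SurfaceProximity(scan)
    probe = tv[::max(1, len(tv) // 300)]
    det_st = np.linalg.det(saxes) * np.linalg.det(taxes)
    best = None
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            s3 = det_st * s1 * s2  # forces det(R) = +1 (proper rotation)
            R = saxes.T @ np.diag([s1, s2, s3]) @ taxes
            M = np.eye(4)
            M[:3, :3] = scale * R
            M[:3, 3] = scc - scale * R @ tc
            _, dist, _, _ = prox.query(_apply(M, probe))
            rms = float(np.sqrt(np.mean(dist ** 2)))
            if best is None or rms < best[0]:
                best = (rms, M)
    return best[1]


# ---------------------------------------------------------------------------
# nonrigid ICP
# ---------------------------------------------------------------------------

@dataclass
class ICPParams:
    """Nonrigid ICP schedule: stiffness weights stepped coarse-to-fine.

    ``stiffness='bilaplacian'`` penalizes bending of the displacement field
    (squared graph Laplacian), which recovers smooth low-frequency warps
    with less tangential sliding than the first-order edge-difference
    penalty (``'laplacian'``, also available).  ``rigid_refine_iters``
    rounds of similarity-Procrustes ICP run between the PCA initialization
    and the nonrigid stages.
    """

    lambdas: tuple = (50.0, 20.0, 8.0, 3.0, 1.0)
    iters_per_stage: int = 20
    d_max: float = 30.0           # correspondence rejection distance (mm)
    normal_max_deg: float = 60.0  # correspondence normal disagreement limit
    divergence_tol: float = 1e-3  # allowed relative residual increase per stage
    stiffness: str = "bilaplacian"
    rigid_refine_iters: int = 30


def _edge_laplacian(mesh: trimesh.Trimesh) -> sp.csr_matrix:
    edges = mesh.edges_unique
    n = len(mesh.vertices)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    A = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(deg) - A


def nonrigid_icp(atlas: TemplateAtlas, scan: trimesh.Trimesh,
                 init: np.ndarray | None = None,
                 params: ICPParams | None = None) -> RegisteredTorso:
    """Deform the template onto a scan by stiffness-regularized nonrigid ICP.

    After PCA + similarity-ICP initialization, per-vertex displacements d
    minimize

        sum_i w_i ||x0_i + d_i - p_i||^2  +  lambda d^T S d

    where p_i is the closest point on the scan surface and S the stiffness
    operator: the graph bi-Laplacian S = L^2 by default, giving the bending
    penalty ||L d||^2 (the first-order edge-difference penalty
    sum_(i,j) ||d_i - d_j||^2 is available as S = L).  w_i in {0, 1} rejects correspondences farther than
    ``d_max`` or with normals disagreeing by more than ``normal_max_deg``,
    and lambda steps down over the coarse-to-fine schedule.  Each inner
    iteration is one sparse linear solve.  Deterministic: no randomization.
    """
    params = params or ICPParams()
    if init is None:
        init = initial_rigid_align(atlas, scan)
    x0 = _apply(init, atlas.mesh.vertices)
    lap = _edge_laplacian(atlas.mesh)
    if params.stiffness == "bilaplacian":
        stiff = (lap @ lap).tocsr()
    elif params.stiffness == "laplacian":
        stiff = lap
    else:
        raise ValueError(f"unknown stiffness {params.stiffness!r}")
    prox = SurfaceProximity(scan)
    cos_lim = np.cos(np.radians(params.normal_max_deg))
    for _ in range(params.rigid_refine_iters):
        cp, dist, _, _ = prox.query(x0)
        ok = dist <= params.d_max
        if ok.sum() < 4:
            break
        x0 = _apply(_umeyama(x0[ok], cp[ok]), x0)
    d = np.zeros_like(x0)
    residual = np.inf
    for lam in params.lambdas:
        stage_start = residual
        for _ in range(params.iters_per_stage):
            x = x0 + d
            cur = trimesh.Trimesh(vertices=x, faces=atlas.mesh.faces, process=False)
            cp, dist, fi, _ = prox.query(x)
            ok = dist <= params.d_max
            vn = cur.vertex_normals
            sn = prox.face_normal(fi)
            ok &= np.einsum("ij,ij->i", vn, sn) >= cos_lim
            if not np.any(ok):
                raise RegistrationError("all correspondences rejected "
                                        f"(d_max={params.d_max} mm)")
            w = ok.astype(float)
            A = sp.diags(w) + lam * stiff
            rhs = w[:, None] * (cp - x0)
            solve = spla.factorized(A.tocsc())
            d = np.column_stack([solve(rhs[:, k]) for k in range(3)])
            residual = float(np.sqrt(np.mean(dist[ok] ** 2)))
        if residual > stage_start * (1 + params.divergence_tol):
            raise RegistrationError(
                f"residual not decreasing in stage lambda={lam}: "
                f"{stage_start:.4f} -> {residual:.4f} mm RMS")
    final = trimesh.Trimesh(vertices=x0 + d, faces=atlas.mesh.faces, process=False)
    flipped = int(np.sum(np.einsum("ij,ij->i", final.face_normals,
                                   atlas.mesh.face_normals) < 0))
    if flipped:
        logger.warning("nonrigid ICP produced %d flipped triangles", flipped)
    return RegisteredTorso(mesh=final, atlas=atlas, residual_rms=residual)


def transfer_landmarks(reg: RegisteredTorso) -> LandmarkSet:
    """Landmark positions = registered positions of atlas landmark vertices."""
    return reg.landmarks()


def map_to_atlas_space(reg: RegisteredTorso, point_on_scan,
                       d_max: float = 30.0) -> np.ndarray:
    """Pull a scan-space point back into template space.

    Closest point on the registered mesh -> barycentric coordinates in its
    triangle -> the same barycentric point on the template triangle.
    """
    prox = SurfaceProximity(reg.mesh)
    _, dist, fi, bary = prox.query(np.asarray(point_on_scan, dtype=float))
    if dist[0] > d_max:
        raise GeometryError(f"point {dist[0]:.1f} mm from registered surface "
                            f"(d_max={d_max})")
    tri = reg.atlas.mesh.vertices[reg.atlas.mesh.faces[fi[0]]]
    return bary[0] @ tri
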