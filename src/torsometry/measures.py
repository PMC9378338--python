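"""Trunk-shape measurement suite on a registered torso.

Nine measurement families are computed from a :class:`RegisteredTorso` in a
landmark-derived body frame, split into *intrinsic* quantities (invariant
under rigid motion: spine length, back area, cross-section areas, section
volumes) and *pose-dependent* quantities (signed asymmetries: back surface
rotation, centroid deviation, trunk axis rotation, Qangle).

Sign conventions (stated once, used everywhere):

* lateral_u points toward the patient's RIGHT (PSIS_R - PSIS_L);
* positive BSR / trunk axis: LEFT side more posterior (a scoliometer laid
  across the back tips down to the right);
* positive centroid deviation / Qangle: deviation toward the patient's
  LEFT.  Magnitudes are convention-free.

"Maximum anywhere on the trunk" quantities are searched over 201 uniform
levels of t in [0, 1] (PSIS level to C7 level) and reported as the signed
value of maximal magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .atlas import (LandmarkSet, RegisteredTorso, canonical_landmark_name,
                    transfer_landmarks)
from .geometry import (MM2_2DM2, GeometryError, Plane, logger, polygon_area,
                       polygon_centroid, polygon_principal_axis,
                       polyline_arclength, region_surface_area, section_volume,
                       slice_mesh)

POSES = ("EOS", "A-pose", "Adam")
#: measures carried in the Adam (forward bend) pose; the rest are upright only
ADAM_MEASURES = ("spine_length", "back_area", "bsr")
DEFAULT_LEVELS = 201
# Profile slice planes are pulled 0.5% of trunk height inboard of the exact
# PSIS/C7 planes: a registered torso's end caps may sit a few mm inside the
# scan surface and slicing through the cap region yields distorted outlines.
_T_CLAMP = 5e-3
MIN_SECTION_AREA_DM2 = 1.0


class MeasureError(RuntimeError):
    """A measurement failed; carries the measure name."""


# ---------------------------------------------------------------------------
# body frame
# ---------------------------------------------------------------------------

@dataclass
class BodyFrame:
    """Anatomical axes from landmarks: origin at the PSIS centroid."""

    origin: np.ndarray
    lateral_u: np.ndarray
    anterior_v: np.ndarray
    longitudinal_w: np.ndarray
    trunk_height: float
    pose: str
    reference_mode: str           # 'coronal' (upright) or 'floor' (Adam)
    floor_normal: np.ndarray | None = None

    @property
    def coronal_plane(self) -> Plane:
        return Plane(self.origin, self.anterior_v)

    def section_basis(self):
        """In-slice (u, v) axes: lateral and anteroposterior reference.

        Upright poses use the coronal plane; the Adam pose references the
        floor, using the horizontal direction orthogonal to the trunk axis
        (sign-matched to lateral_u).
        """
        if self.reference_mode == "coronal":
            return self.lateral_u, self.anterior_v
        fn = self.floor_normal if self.floor_normal is not None \
            else np.array([0.0, 0.0, 1.0])
        u = np.cross(fn, self.longitudinal_w)
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            raise MeasureError("trunk axis parallel to floor normal")
        u = u / nu
        if u @ self.lateral_u < 0:
            u = -u
        v = np.cross(self.longitudinal_w, u)
        return u, v / np.linalg.norm(v)


def build_body_frame(landmarks: LandmarkSet, pose: str = "EOS",
                     floor_normal=None) -> BodyFrame:
    """Orthonormal body frame from the nine landmarks.

    origin = PSIS midpoint; w = unit(C7 - origin); u = unit(PSIS_R - PSIS_L)
    orthogonalized against w; v = w x u (right-handed, anterior).
    """
    if pose not in POSES:
        raise ValueError(f"pose must be one of {POSES}")
    origin = landmarks.psis_centroid()
    span = landmarks["PSIS_R"] - landmarks["PSIS_L"]
    if np.linalg.norm(span) < 1e-6:
        raise MeasureError("coincident PSIS landmarks")
    w = landmarks["SP_C7"] - origin
    height = float(np.linalg.norm(w))
    w = w / height
    u = span - (span @ w) * w
    u = u / np.linalg.norm(u)
    v = np.cross(w, u)
    mode = "floor" if pose == "Adam" else "coronal"
    fn = None
    if mode == "floor":
        fn = np.asarray(floor_normal, dtype=float) if floor_normal is not None \
            else np.array([0.0, 0.0, 1.0])
        fn = fn / np.linalg.norm(fn)
    return BodyFrame(origin=origin, lateral_u=u, anterior_v=v,
                     longitudinal_w=w, trunk_height=height, pose=pose,
                     reference_mode=mode, floor_normal=fn)


def level_plane(frame: BodyFrame, t: float) -> Plane:
    """Transverse plane at trunk-level fraction t (0 = PSIS, 1 = C7)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("level fraction t must be in [0, 1]")
    return Plane(frame.origin + t * frame.trunk_height * frame.longitudinal_w,
                 frame.longitudinal_w)


def _section_at(reg: RegisteredTorso, frame: BodyFrame, t: float,
                clamp: bool = True):
    """Largest cross-section loop at level t, or None if the slice is empty."""
    tc = min(max(t, _T_CLAMP), 1.0 - _T_CLAMP) if clamp else t
    secs = slice_mesh(reg.mesh, level_plane(frame, tc),
                      frame_basis=frame.section_basis(), level_t=t)
    return secs[0] if secs else None


# ---------------------------------------------------------------------------
# intrinsic measures
# ---------------------------------------------------------------------------

def spine_length(reg: RegisteredTorso) -> float:
    """Midline arclength (cm) from the PSIS centroid to C7.

    The midline is the registered atlas dorsal midline chain, prepended
    with the PSIS centroid.
    """
    lms = reg.landmarks()
    chain = reg.mesh.vertices[reg.atlas.midline_chain]
    return polyline_arclength(np.vstack([lms.psis_centroid(), chain]))


def back_area(reg: RegisteredTorso, frame: BodyFrame):
    """Dorsal surface area (dm^2) bounded caudally by PSIS, cranially by C7.

    Returns ``(total, left, right)``; halves come from the atlas dorsal
    face labels, each clipped exactly to the PSIS..C7 slab.
    """
    lo, hi = level_plane(frame, 0.0), level_plane(frame, 1.0)
    labels = reg.atlas.face_labels
    left = region_surface_area(reg.mesh, np.nonzero(labels == "dorsal_left")[0],
                               lo, hi)
    right = region_surface_area(reg.mesh, np.nonzero(labels == "dorsal_right")[0],
                                lo, hi)
    return left + right, left, right


def cross_section_area(reg: RegisteredTorso, frame: BodyFrame, at: str) -> float:
    """Enclosed area (dm^2) of the transverse slice through landmark ``at``
    (L2, T8 or JN)."""
    name = canonical_landmark_name(at)
    point = reg.landmarks()[name]
    plane = Plane(point, frame.longitudinal_w)
    secs = slice_mesh(reg.mesh, plane, frame_basis=frame.section_basis())
    if not secs:
        raise MeasureError(f"empty slice at landmark {at}")
    area = polygon_area(secs[0]) * MM2_2DM2
    if area < MIN_SECTION_AREA_DM2:
        logger.warning("cross-section at %s below %.0f dm^2 - check registration",
                       at, MIN_SECTION_AREA_DM2)
    return area


def section_volumes(reg: RegisteredTorso, frame: BodyFrame) -> dict:
    """The three torso section volumes (L): L2-T8, XP-JN, PSIS-JN."""
    lms = reg.landmarks()
    w = frame.longitudinal_w

    def plane_through(name):
        if name == "PSIS":
            return level_plane(frame, 0.0)
        return Plane(lms[name], w)

    out = {}
    for lo_name, hi_name in (("L2", "T8"), ("XP", "JN"), ("PSIS", "JN")):
        p_lo, p_hi = plane_through(lo_name), plane_through(hi_name)
        if (p_hi.point - p_lo.point) @ w <= 0:
            raise MeasureError(f"inverted landmark order for pair "
                               f"{lo_name}-{hi_name}")
        out[f"{lo_name}-{hi_name}"] = section_volume(reg.mesh, p_lo, p_hi)
    return out


# ---------------------------------------------------------------------------
# pose-dependent measures
# ---------------------------------------------------------------------------

def posterior_tangent_angle(polygon: np.ndarray) -> float:
    """Signed scoliometer angle (deg) of a 2D cross-section polygon.

    The tangent "resting across the back" is operationalized as the
    posterior supporting line: the convex-hull edge that faces posteriorly
    (outward normal with negative v) and spans the sagittal midline (the
    centroid's u).  Positive = left (-u) side more posterior.
    """
    from .geometry import CrossSection

    sec = CrossSection(plane=Plane([0, 0, 0], [0, 0, 1]), polygon=polygon,
                       basis=(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])))
    cu = polygon_centroid(sec)[0]
    hull = ConvexHull(polygon)
    pts = polygon[hull.vertices]      # counter-clockwise
    best = None
    for i in range(len(pts)):
        p0, p1 = pts[i], pts[(i + 1) % len(pts)]
        edge = p1 - p0
        outward_v = -edge[0]          # outward normal of CCW hull = (dy, -dx)
        if outward_v >= 0:            # not posterior-facing
            continue
        lo, hi = min(p0[0], p1[0]), max(p0[0], p1[0])
        if not (lo <= cu <= hi):
            continue
        depth = -0.5 * (p0[1] + p1[1])
        if best is None or depth > best[0]:
            best = (depth, p0, p1)
    if best is None:
        raise MeasureError("degenerate dorsal arc: no posterior supporting edge")
    _, p0, p1 = best
    if p0[0] > p1[0]:
        p0, p1 = p1, p0
    return float(np.degrees(np.arctan2(p1[1] - p0[1], p1[0] - p0[0])))


def bsr_at(reg: RegisteredTorso, frame: BodyFrame, t: float) -> float:
    """Back surface rotation (deg) at trunk level t; positive = left posterior."""
    sec = _section_at(reg, frame, t)
    if sec is None:
        raise MeasureError(f"empty slice at t={t}")
    return posterior_tangent_angle(sec.polygon)


def bsr_profile(reg: RegisteredTorso, frame: BodyFrame,
                n_levels: int = DEFAULT_LEVELS):
    """BSR sampled at uniform levels; returns (levels, angles, bsr_max).

    ``bsr_max`` is the signed value of maximal magnitude anywhere on the
    trunk; the fixed 25/50/75% levels are exact grid entries.
    """
    ts = np.linspace(0.0, 1.0, n_levels)
    vals = np.array([bsr_at(reg, frame, t) for t in ts])
    bsr_max = float(vals[int(np.argmax(np.abs(vals)))])
    return ts, vals, bsr_max


def centroid_profile(reg: RegisteredTorso, frame: BodyFrame,
                     n_levels: int = DEFAULT_LEVELS):
    """Leftward slice-centroid deviation (mm) vs the PSIS-level centroid."""
    ts = np.linspace(0.0, 1.0, n_levels)
    cu = np.empty(n_levels)
    for i, t in enumerate(ts):
        sec = _section_at(reg, frame, t)
        if sec is None:
            raise MeasureError(f"empty slice at t={t}")
        cu[i] = polygon_centroid(sec)[0]
    dev_left = -(cu - cu[0])      # +u is patient right; positive = left
    return ts, dev_left


def centroid_deviation(reg: RegisteredTorso, frame: BodyFrame,
                       n_levels: int = DEFAULT_LEVELS) -> float:
    """Signed maximal-magnitude coronal centroid deviation (mm, + = left)."""
    _, dev = centroid_profile(reg, frame, n_levels)
    return float(dev[int(np.argmax(np.abs(dev)))])


def trunk_axis(reg: RegisteredTorso, frame: BodyFrame,
               n_levels: int = DEFAULT_LEVELS) -> float:
    """Signed maximal-magnitude principal-axis angle (deg) of transverse
    slices vs the coronal plane; near-isotropic levels are skipped."""
    ts = np.linspace(0.0, 1.0, n_levels)
    vals = []
    for t in ts:
        sec = _section_at(reg, frame, t)
        if sec is None:
            continue
        try:
            vals.append(polygon_principal_axis(sec))
        except GeometryError:
            logger.debug("trunk_axis: isotropic section at t=%.3f skipped", t)
    if not vals:
        raise MeasureError("trunk axis undefined: all levels isotropic")
    vals = np.asarray(vals)
    return float(vals[int(np.argmax(np.abs(vals)))])


# ---------------------------------------------------------------------------
# back symmetry line, harmonic fit, Qangle
# ---------------------------------------------------------------------------

def symmetry_line(reg: RegisteredTorso, n_points: int = DEFAULT_LEVELS) -> np.ndarray:
    """The dorsal back symmetry line: the registered atlas midline chain
    resampled to ``n_points`` uniformly in t; (n_points, 3) mm."""
    chain = reg.mesh.vertices[reg.atlas.midline_chain]
    t_in = np.linspace(0.0, 1.0, len(chain))
    t_out = np.linspace(0.0, 1.0, n_points)
    return np.column_stack([np.interp(t_out, t_in, chain[:, k]) for k in range(3)])


@dataclass
class HarmonicFit:
    """Fourth-order harmonic model of lateral deviation x(t), t in [0, 1]:
    x(t) = a0 + sum_k a_k cos(2 pi k t) + b_k sin(2 pi k t), k = 1..4."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    residual_rms: float = 0.0

    ORDER = 4

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        x = np.full_like(t, self.a0, dtype=float)
        for k in range(1, self.ORDER + 1):
            x = x + self.a[k - 1] * np.cos(2 * np.pi * k * t) \
                  + self.b[k - 1] * np.sin(2 * np.pi * k * t)
        return x

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        d = np.zeros_like(t, dtype=float)
        for k in range(1, self.ORDER + 1):
            w = 2 * np.pi * k
            d = d - self.a[k - 1] * w * np.sin(w * t) \
                  + self.b[k - 1] * w * np.cos(w * t)
        return d


def fit_harmonic(line: np.ndarray, frame: BodyFrame) -> HarmonicFit:
    """Least-squares 4th-order harmonic fit of the line's leftward lateral
    deviation against normalized level t."""
    line = np.asarray(line, dtype=float)
    if len(line) < 2 * HarmonicFit.ORDER + 1:
        raise MeasureError("need at least 9 points for a 4th-order harmonic fit")
    t = np.linspace(0.0, 1.0, len(line))
    x = -(line - frame.origin) @ frame.lateral_u     # leftward (+)
    cols = [np.ones_like(t)]
    for k in range(1, HarmonicFit.ORDER + 1):
        cols.append(np.cos(2 * np.pi * k * t))
        cols.append(np.sin(2 * np.pi * k * t))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    return HarmonicFit(a0=float(coef[0]), a=coef[1::2].copy(), b=coef[2::2].copy(),
                       residual_rms=float(np.sqrt(np.mean(resid ** 2))))


@dataclass
class QangleResult:
    angle_deg: float
    has_curve: bool
    apex_t: float = float("nan")
    t_below: float = float("nan")
    t_above: float = float("nan")


def qangle(fit: HarmonicFit, trunk_length: float,
           n_dense: int = 2001) -> QangleResult:
    """Topographic Cobb-angle analogue from the fitted symmetry line.

    The physical slope is s(t) = x'(t) / trunk_length.  The apex is the
    interior extremum of |x(t) - mean|; the end tangents are the nearest
    slope extrema on each side of the apex (range ends allowed).  The angle
    is atan(s_above) - atan(s_below), signed by the apex direction
    (positive = apex toward patient left).
    """
    if trunk_length <= 0:
        raise ValueError("trunk_length must be positive")
    t = np.linspace(0.0, 1.0, n_dense)
    x = fit(t) - fit.a0
    mag = np.abs(x)
    interior = (mag[1:-1] >= mag[:-2]) & (mag[1:-1] >= mag[2:])
    cand = np.nonzero(interior)[0] + 1
    cand = cand[mag[cand] > 1e-9]
    if len(cand) == 0:
        return QangleResult(angle_deg=0.0, has_curve=False)
    apex = int(cand[np.argmax(mag[cand])])
    s = fit.derivative(t) / trunk_length
    ds = np.diff(s)
    extrema = np.nonzero(np.sign(ds[1:]) != np.sign(ds[:-1]))[0] + 1
    below = extrema[extrema < apex]
    above = extrema[extrema > apex]
    i_below = int(below[-1]) if len(below) else 0
    i_above = int(above[0]) if len(above) else n_dense - 1
    ang = np.degrees(np.arctan(s[i_above]) - np.arctan(s[i_below]))
    sign = 1.0 if x[apex] > 0 else -1.0
    return QangleResult(angle_deg=float(sign * abs(ang)), has_curve=True,
                        apex_t=float(t[apex]), t_below=float(t[i_below]),
                        t_above=float(t[i_above]))


# ---------------------------------------------------------------------------
# the full suite
# ---------------------------------------------------------------------------

@dataclass
class MeasurementSuite:
    """All reported quantities for one scan, in the paper-table units."""

    pose: str
    spine_length_cm: float
    back_area_dm2: float
    back_area_left_dm2: float
    back_area_right_dm2: float
    bsr_deg: dict                     # keys '25', '50', '75', 'max'
    xsa_dm2: dict | None = None       # keys 'L2', 'T8', 'JN'
    xsv_l: dict | None = None         # keys 'L2-T8', 'XP-JN', 'PSIS-JN'
    centroid_dev_mm: float | None = None
    axis_max_deg: float | None = None
    qangle_deg: float | None = None
    qangle_has_curve: bool | None = None
    suppressed: tuple = ()
    residual_rms_mm: float = 0.0

    def to_dict(self) -> dict:
        out = {"pose": self.pose,
               "spine_length_cm": self.spine_length_cm,
               "back_area_dm2": self.back_area_dm2,
               "back_area_left_dm2": self.back_area_left_dm2,
               "back_area_right_dm2": self.back_area_right_dm2,
               "residual_rms_mm": self.residual_rms_mm,
               "suppressed": list(self.suppressed)}
        for key, val in self.bsr_deg.items():
            out[f"bsr_{key}_deg"] = val
        if self.xsa_dm2 is not None:
            for key, val in self.xsa_dm2.items():
                out[f"xsa_{key}_dm2"] = val
        if self.xsv_l is not None:
            for key, val in self.xsv_l.items():
                out[f"xsv_{key}_l"] = val
        if self.centroid_dev_mm is not None:
            out["centroid_dev_mm"] = self.centroid_dev_mm
        if self.axis_max_deg is not None:
            out["axis_max_deg"] = self.axis_max_deg
        if self.qangle_deg is not None:
            out["qangle_deg"] = self.qangle_deg
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def to_rows(self, subject="", rater="", placement="", trial="") -> list:
        """Long-format rows (subject, rater, placement, trial, parameter,
        value) for the reliability statistics."""
        rows = []
        for key, val in sorted(self.to_dict().items()):
            if isinstance(val, (int, float)) and key != "residual_rms_mm":
                rows.append((subject, rater, placement, trial,
                             f"{self.pose}:{key}", float(val)))
        return rows


def measure_all(reg: RegisteredTorso, landmarks: LandmarkSet | None = None,
                pose: str = "EOS", floor_normal=None,
                n_levels: int = DEFAULT_LEVELS) -> MeasurementSuite:
    """Run every measure applicable to the pose.

    Upright poses (EOS, A-pose) carry the full suite; the Adam forward-bend
    pose carries only spine length, back area and the BSR family — the
    other measures are suppressed and flagged.
    """
    if landmarks is None:
        landmarks = transfer_landmarks(reg)
    frame = build_body_frame(landmarks, pose=pose, floor_normal=floor_normal)

    def run(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise MeasureError(f"{name}: {exc}") from exc

    sp_len = run("spine_length", lambda: spine_length(reg))
    ba, ba_l, ba_r = run("back_area", lambda: back_area(reg, frame))
    ts, vals, bsr_max = run("bsr", lambda: bsr_profile(reg, frame, n_levels))
    quarter = (n_levels - 1) // 4
    bsr = {"25": float(vals[quarter]), "50": float(vals[2 * quarter]),
           "75": float(vals[3 * quarter]), "max": bsr_max}

    if pose == "Adam":
        return MeasurementSuite(
            pose=pose, spine_length_cm=sp_len, back_area_dm2=ba,
            back_area_left_dm2=ba_l, back_area_right_dm2=ba_r, bsr_deg=bsr,
            suppressed=("xsa", "xsv", "centroid_dev", "axis", "qangle"),
            residual_rms_mm=reg.residual_rms)

    xsa = {at: run(f"xsa_{at}", lambda at=at: cross_section_area(reg, frame, at))
           for at in ("L2", "T8", "JN")}
    xsv = run("xsv", lambda: section_volumes(reg, frame))
    cdev = run("centroid_dev", lambda: centroid_deviation(reg, frame, n_levels))
    axis = run("axis", lambda: trunk_axis(reg, frame, n_levels))
    line = run("symmetry_line", lambda: symmetry_line(reg, n_levels))
    fit = run("fit_harmonic", lambda: fit_harmonic(line, frame))
    qa = run("qangle", lambda: qangle(fit, frame.trunk_height))
    return MeasurementSuite(
        pose=pose, spine_length_cm=sp_len, back_area_dm2=ba,
        back_area_left_dm2=ba_l, back_area_right_dm2=ba_r, bsr_deg=bsr,
        xsa_dm2=xsa, xsv_l=xsv, centroid_dev_mm=cdev, axis_max_deg=axis,
        qangle_deg=qa.angle_deg, qangle_has_curve=qa.has_curve,
        residual_rms_mm=reg.residual_rms)
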