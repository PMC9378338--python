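"""Parametric synthetic scoliotic torsos with analytic ground truth.

The generator stands in for the optical scanner and the human cohort: it
emits watertight torso meshes with controllable lateral spine deviation
(coronal bow), axial rotation (vertebral rotation analogue), a one-sided
dorsal hump (rib prominence), pose perturbations between repeated "scans",
and per-rater noise for reliability studies.  Every deformity parameter has
an exact analytic counterpart recorded in :class:`GroundTruth`, which is
what makes desk-scale validation of the measurement pipeline possible.

Shape model (axes: +x patient right, +y anterior, +z cranial):

* cross-section at trunk level t in [0, 1] (PSIS -> C7): the flat-backed
  torso profile (see :func:`torsometry.atlas.torso_outline`) with semi-axes
  a(t), b(t), recentred on its area centroid;
* coronal bow: centroid path c(t) = A sin(pi t), displacing sections toward
  the patient's LEFT (-x) for A > 0 (sign convention: positive lateral
  quantities point left);
* axial rotation: each section rotated by theta(t) = Theta sin(pi t) about
  its centroid, positive rotating the left side posteriorly;
* dorsal hump: Gaussian radial bump of height h on the left paraspinal back
  (swapped by ``hump_side``).

Defaults model a mid-adolescent trunk: height 480 mm, half-width ~150 mm,
half-depth 100 mm, with moderate scoliotic deformity (Theta = 10 deg,
A = 15 mm, h = 8 mm) comparable to the deformity range of an AIS clinic
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from .atlas import (LANDMARK_GRID, LandmarkSet, TemplateAtlas, RegisteredTorso,
                    build_grid_torso, outline_area_centroid, ring_angles,
                    torso_outline)

DEG = np.pi / 180.0


def _as_fn(value):
    if callable(value):
        return value
    if isinstance(value, tuple) and len(value) == 2:
        return CubicSpline(np.asarray(value[0], float), np.asarray(value[1], float))
    v = float(value)
    return lambda t, _v=v: _v


@dataclass
class TorsoSpec:
    """Parameters of one synthetic torso.

    ``a`` and ``b`` (mm) may be scalars, callables of t, or
    ``(knots_t, values)`` tuples fitted with a cubic spline.  ``theta_deg``
    and ``bow_mm`` are the amplitudes of the single-lobe profiles
    theta(t) = Theta sin(pi t) and c(t) = A sin(pi t).
    """

    height: float = 480.0
    a: object = (np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
                 np.array([158.0, 142.0, 148.0, 162.0, 150.0]))
    b: object = 100.0
    bow_mm: float = 15.0          # lateral bow amplitude A, +ve toward left
    theta_deg: float = 10.0       # axial rotation amplitude Theta, CCW from above
    hump_mm: float = 8.0          # dorsal hump height h
    hump_side: str = "left"
    profile: str = "flatback"
    flat_frac: float = 0.45
    n_levels: int = 41
    n_around: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.hump_side not in ("left", "right"):
            raise ValueError("hump_side must be 'left' or 'right'")

    def a_fn(self):
        return _as_fn(self.a)

    def b_fn(self):
        return _as_fn(self.b)

    def bow_fn(self):
        A = self.bow_mm
        return lambda t: -A * np.sin(np.pi * t)   # -x is patient left

    def twist_fn(self):
        th = self.theta_deg * DEG
        return lambda t: th * np.sin(np.pi * t)

    def hump_phi0(self):
        off = np.pi / 6
        return 3 * np.pi / 2 - off if self.hump_side == "left" else 3 * np.pi / 2 + off

    def mirrored(self) -> "TorsoSpec":
        return replace(self, bow_mm=-self.bow_mm, theta_deg=-self.theta_deg,
                       hump_side=("right" if self.hump_side == "left" else "left"))


@dataclass
class GroundTruth:
    """Analytic ground truth for a generated torso (all lengths mm)."""

    spec: TorsoSpec
    landmarks: dict
    xsa_mm2: object               # callable t -> cross-section area
    centroid_left_mm: object      # callable t -> leftward centroid offset
    theta_deg: object             # callable t -> axial rotation (deg, +left post.)
    midline: np.ndarray           # dense dorsal midline polyline (K, 3)
    spine_length_mm: float
    dorsal_area_mm2: float

    def xsv_mm3(self, t_lo: float, t_hi: float) -> float:
        """Section volume between trunk levels by 1D quadrature of XSA."""
        val, _ = quad(self.xsa_mm2, t_lo, t_hi, limit=200)
        return val * self.spec.height

    def landmark_set(self) -> LandmarkSet:
        return LandmarkSet(self.landmarks)


def _outline_kwargs(spec: TorsoSpec) -> dict:
    return dict(profile=spec.profile, flat_frac=spec.flat_frac,
                hump=spec.hump_mm, hump_phi0=spec.hump_phi0())


def _level_transform(spec: TorsoSpec, t: float, pts2: np.ndarray,
                     centroid: np.ndarray) -> np.ndarray:
    """Apply the per-level recentre/rotate/translate chain to outline points."""
    th = spec.twist_fn()(t)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    out = (pts2 - centroid) @ rot.T
    out[:, 0] += spec.bow_fn()(t)
    return out


def generate_torso(spec: TorsoSpec):
    """Generate a watertight torso mesh with analytic ground truth.

    Returns ``(mesh, landmarks, truth)``; landmark positions are exact grid
    vertices (the template uses the same parametric placement rule, so
    landmark correspondence is resolution independent).
    """
    a_fn, b_fn = spec.a_fn(), spec.b_fn()
    if abs(spec.bow_mm) >= 0.8 * min(a_fn(0.5), a_fn(0.0)):
        raise ValueError("bow amplitude too large for semi-axis (self-intersection)")
    mesh, meta = build_grid_torso(
        height=spec.height, a_of_t=a_fn, b_of_t=b_fn,
        n_levels=spec.n_levels, n_around=spec.n_around,
        profile=spec.profile, flat_frac=spec.flat_frac,
        bow_of_t=spec.bow_fn(), twist_of_t=spec.twist_fn(),
        hump=spec.hump_mm, hump_phi0=spec.hump_phi0())

    landmarks = {name: mesh.vertices[idx]
                 for name, idx in meta["landmark_index"].items()}

    dense_phi = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    okw = _outline_kwargs(spec)

    def xsa(t):
        area, _ = outline_area_centroid(
            torso_outline(dense_phi, a_fn(t), b_fn(t), **okw))
        return abs(area)

    def theta_of(t):
        return spec.twist_fn()(t) / DEG

    # dense dorsal midline: material point phi = 3 pi / 2 at each level
    ts = np.linspace(0.0, 1.0, 2001)
    mid_pts = np.empty((len(ts), 3))
    for i, t in enumerate(ts):
        a, b = a_fn(t), b_fn(t)
        p2 = torso_outline(np.array([3 * np.pi / 2]), a, b, **okw)
        _, cen = outline_area_centroid(torso_outline(dense_phi, a, b, **okw))
        p2 = _level_transform(spec, t, p2, cen)
        mid_pts[i] = [p2[0, 0], p2[0, 1], t * spec.height]
    psis_c = 0.5 * (landmarks["PSIS_L"] + landmarks["PSIS_R"])
    spine_len = float(np.linalg.norm(mid_pts[0] - psis_c) +
                      np.sum(np.linalg.norm(np.diff(mid_pts, axis=0), axis=1)))

    # dorsal surface area by fine quadrature on the analytic surface
    dorsal_area = _dorsal_area_quadrature(spec, n_t=400, n_phi=512)

    truth = GroundTruth(spec=spec, landmarks=landmarks, xsa_mm2=xsa,
                        centroid_left_mm=lambda t: float(spec.bow_mm) * np.sin(np.pi * t),
                        theta_deg=theta_of, midline=mid_pts,
                        spine_length_mm=spine_len, dorsal_area_mm2=dorsal_area)
    return mesh, LandmarkSet(landmarks), truth


def _dorsal_area_quadrature(spec: TorsoSpec, n_t: int, n_phi: int) -> float:
    """Dorsal (phi in (pi, 2 pi)) surface area via a fine parametric grid."""
    a_fn, b_fn = spec.a_fn(), spec.b_fn()
    okw = _outline_kwargs(spec)
    dense_phi = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    phis = np.linspace(np.pi, 2 * np.pi, n_phi + 1)
    ts = np.linspace(0.0, 1.0, n_t + 1)
    grid = np.empty((len(ts), len(phis), 3))
    for i, t in enumerate(ts):
        a, b = a_fn(t), b_fn(t)
        p2 = torso_outline(phis, a, b, **okw)
        _, cen = outline_area_centroid(torso_outline(dense_phi, a, b, **okw))
        p2 = _level_transform(spec, t, p2, cen)
        grid[i, :, 0:2] = p2
        grid[i, :, 2] = t * spec.height
    d_t = np.diff(grid, axis=0)[:, :-1]
    d_p = np.diff(grid, axis=1)[:-1]
    cross1 = np.cross(d_p, d_t)
    d_t2 = np.diff(grid, axis=0)[:, 1:]
    d_p2 = np.diff(grid, axis=1)[1:]
    cross2 = np.cross(d_p2, d_t2)
    return float(0.5 * (np.linalg.norm(cross1, axis=-1).sum() +
                        np.linalg.norm(cross2, axis=-1).sum()))


def as_registered(mesh: trimesh.Trimesh, spec: TorsoSpec) -> RegisteredTorso:
    """Wrap a generated torso as its own registered torso (identity atlas).

    The generator emits meshes on the same grid layout as the template, so
    a generated torso can serve directly as a RegisteredTorso whose atlas is
    the symmetric (undeformed) version of itself.  Used to test measurement
    code independently of registration.
    """
    sym_spec = replace(spec, bow_mm=0.0, theta_deg=0.0, hump_mm=0.0)
    ref, meta = build_grid_torso(height=sym_spec.height, a_of_t=sym_spec.a_fn(),
                                 b_of_t=sym_spec.b_fn(), n_levels=spec.n_levels,
                                 n_around=spec.n_around, profile=spec.profile,
                                 flat_frac=spec.flat_frac)
    atlas = TemplateAtlas(mesh=ref, symmetry_map=meta["symmetry_map"],
                          landmark_index=meta["landmark_index"],
                          midline_chain=meta["midline_chain"],
                          face_labels=meta["face_labels"], meta=meta)
    atlas.validate()
    return RegisteredTorso(mesh=mesh, atlas=atlas, residual_rms=0.0)


def adam_pose(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
              bend_deg: float = 80.0):
    """Forward-bend (Adam's test) version of an upright torso.

    The trunk is bent with constant curvature in the sagittal plane (total
    bend ``bend_deg``) about a neutral axis through the section centres, so
    the dorsal surface — the outside of the bend — lengthens, then rotated
    rigidly so the mid-trunk axis is horizontal (back facing up, floor
    normal +z).  Returns ``(mesh, landmarks)``.
    """
    psi_tot = bend_deg * DEG
    v = mesh.vertices
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    h = zmax - zmin
    radius = h / psi_tot

    def bend(pts):
        t = (pts[:, 2] - zmin) / h
        psi = psi_tot * t
        cy = radius * (1 - np.cos(psi))
        cz = zmin + radius * np.sin(psi)
        y = pts[:, 1]
        out = np.empty_like(pts)
        out[:, 0] = pts[:, 0]
        out[:, 1] = cy + y * np.cos(psi)
        out[:, 2] = cz - y * np.sin(psi)
        return out

    tilt = psi_tot / 2 - np.pi / 2  # brings the mid-trunk tangent horizontal, back up
    R = trimesh.transformations.rotation_matrix(tilt, [1, 0, 0])[:3, :3]
    new_v = bend(v.copy()) @ R.T
    lm = {k: (bend(p[None, :].copy())[0]) @ R.T for k, p in landmarks.points.items()}
    return (trimesh.Trimesh(vertices=new_v, faces=mesh.faces, process=False),
            LandmarkSet(lm))


# ---------------------------------------------------------------------------
# scan-protocol perturbations
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Crossed reliability-study design: subjects x raters x placements x trials.

    Mirrors the clinical protocol: each pose is scanned twice without moving
    the feet (test-retest), the subject steps out and is repositioned for two
    more scans (remove-replace), and the whole sequence is repeated with a
    second rater.  Noise scales:

    * ``sigma_trial_*``: within-placement jitter (postural sway, sensor
      noise) applied to every scan;
    * ``sigma_pose_*``: between-placement re-posing, re-drawing the pose
      deformity increments (Delta Theta, Delta A);
    * ``sigma_rater_*``: systematic per-rater guidance bias on pose.
    """

    n_subjects: int = 46
    n_raters: int = 2
    n_placements: int = 2
    n_trials: int = 2
    sigma_trial_rot_deg: float = 0.5
    sigma_trial_shift_mm: float = 2.0
    sigma_trial_vertex_mm: float = 0.3
    sigma_pose_theta_deg: float = 2.0
    sigma_pose_bow_mm: float = 3.0
    sigma_rater_theta_deg: float = 1.0
    sigma_rater_bow_mm: float = 1.5
    bmi_scale_sd: float = 0.12    # per-subject BMI proxy scaling of (a, b)
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_trial_rot_deg", "sigma_trial_shift_mm",
                     "sigma_trial_vertex_mm", "sigma_pose_theta_deg",
                     "sigma_pose_bow_mm", "sigma_rater_theta_deg",
                     "sigma_rater_bow_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _small_rotation(rng, sigma_deg: float) -> np.ndarray:
    ang = rng.normal(0.0, sigma_deg * DEG, size=3)
    Rx = trimesh.transformations.rotation_matrix(ang[0], [1, 0, 0])[:3, :3]
    Ry = trimesh.transformations.rotation_matrix(ang[1], [0, 1, 0])[:3, :3]
    Rz = trimesh.transformations.rotation_matrix(ang[2], [0, 0, 1])[:3, :3]
    return Rz @ Ry @ Rx


def perturb_scan(mesh: trimesh.Trimesh, landmarks: LandmarkSet,
                 design: StudyDesign, condition: str, seed: int,
                 pose_delta: tuple | None = None):
    """One simulated repeat "scan": pose + sensor noise on a generated torso.

    ``condition`` is ``'test-retest'`` (small rigid jitter + vertex noise) or
    ``'remove-replace'`` (additionally re-poses the torso with a bow/twist
    increment; pass ``pose_delta=(d_theta_deg, d_bow_mm)`` to inject rater
    bias, else increments are drawn from the design sigmas).  Deterministic
    given ``seed``.
    """
    if condition not in ("test-retest", "remove-replace"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    v = mesh.vertices.copy()
    lm = {k: p.copy() for k, p in landmarks.points.items()}

    if condition == "remove-replace":
        if pose_delta is None:
            pose_delta = (rng.normal(0, design.sigma_pose_theta_deg),
                          rng.normal(0, design.sigma_pose_bow_mm))
        d_theta, d_bow = pose_delta
        zmin, zmax = v[:, 2].min(), v[:, 2].max()
        h = max(zmax - zmin, 1e-9)

        def warp(pts):
            t = np.clip((pts[:, 2] - zmin) / h, 0, 1)
            th = d_theta * DEG * np.sin(np.pi * t)
            x, y = pts[:, 0].copy(), pts[:, 1].copy()
            pts[:, 0] = x * np.cos(th) - y * np.sin(th) - d_bow * np.sin(np.pi * t)
            pts[:, 1] = x * np.sin(th) + y * np.cos(th)
            return pts

        v = warp(v)
        for k in lm:
            lm[k] = warp(lm[k][None, :].copy())[0]

    R = _small_rotation(rng, design.sigma_trial_rot_deg)
    shift = rng.normal(0.0, design.sigma_trial_shift_mm, size=3)
    center = v.mean(axis=0)
    v = (v - center) @ R.T + center + shift
    for k in lm:
        lm[k] = R @ (lm[k] - center) + center + shift

    if design.sigma_trial_vertex_mm > 0:
        normals = trimesh.Trimesh(vertices=v, faces=mesh.faces,
                                  process=False).vertex_normals
        v = v + normals * rng.normal(0.0, design.sigma_trial_vertex_mm,
                                     size=len(v))[:, None]
    out = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    return out, LandmarkSet(lm)


# ---------------------------------------------------------------------------
# rating-study simulation
# ---------------------------------------------------------------------------

def population_icc(sigma2_subject: float, sigma2_rater: float,
                   sigma2_trial: float) -> float:
    """ICC implied by the variance components of the proxy model."""
    return sigma2_subject / (sigma2_subject + sigma2_rater + sigma2_trial)


def simulate_rating_study(design: StudyDesign, spec_population, seed: int,
                          mode: str = "proxy"):
    """Simulate a full crossed rating study; returns (long_table, truth_info).

    ``mode='proxy'`` draws measurements from the closed-form variance
    component model value = subject + rater + noise; ``spec_population`` is
    then a mapping {parameter: (sigma2_subject, sigma2_rater, sigma2_trial)}.
    The long table has columns subject, rater, placement, trial, parameter,
    value; ``truth_info`` maps parameter -> population ICC.

    ``mode='pipeline'`` runs generated torsos through perturbation and a
    direct measurement callable: ``spec_population`` is then
    ``(specs, measure_fn)`` with ``measure_fn(mesh, landmarks) -> dict``.
    """
    import pandas as pd

    if design.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    if mode == "proxy":
        truth = {}
        for param, (s2s, s2r, s2t) in spec_population.items():
            truth[param] = population_icc(s2s, s2r, s2t)
            subj = rng.normal(0, np.sqrt(s2s), size=design.n_subjects)
            rater = rng.normal(0, np.sqrt(s2r), size=design.n_raters)
            for i in range(design.n_subjects):
                for r in range(design.n_raters):
                    for p in range(design.n_placements):
                        for tr in range(design.n_trials):
                            val = subj[i] + rater[r] + rng.normal(0, np.sqrt(s2t))
                            rows.append((i, r, p, tr, param, val))
        return (pd.DataFrame(rows, columns=["subject", "rater", "placement",
                                            "trial", "parameter", "value"]),
                truth)
    if mode != "pipeline":
        raise ValueError(f"unknown mode {mode!r}")
    specs, measure_fn = spec_population
    rater_bias = [(rng.normal(0, design.sigma_rater_theta_deg),
                   rng.normal(0, design.sigma_rater_bow_mm))
                  for _ in range(design.n_raters)]
    for i, spec in enumerate(specs):
        mesh, lms, _truth = generate_torso(spec)
        for r in range(design.n_raters):
            for p in range(design.n_placements):
                place_seed = int(rng.integers(0, 2 ** 31 - 1))
                prng = np.random.default_rng(place_seed)
                d_theta = prng.normal(0, design.sigma_pose_theta_deg) + rater_bias[r][0]
                d_bow = prng.normal(0, design.sigma_pose_bow_mm) + rater_bias[r][1]
                for tr in range(design.n_trials):
                    trial_seed = int(rng.integers(0, 2 ** 31 - 1))
                    m2, lm2 = perturb_scan(
                        mesh, lms, design,
                        "remove-replace" if p > 0 else "test-retest",
                        trial_seed, pose_delta=(d_theta, d_bow) if p > 0 else None)
                    for param, val in measure_fn(m2, lm2).items():
                        rows.append((i, r, p, tr, param, float(val)))
    return (pd.DataFrame(rows, columns=["subject", "rater", "placement",
                                        "trial", "parameter", "value"]), None)


def cohort_specs(n_subjects: int, seed: int,
                 base: TorsoSpec | None = None) -> list:
    """Draw a cohort of torso specs with AIS-like deformity spread.

    Theta ~ |N(0, 8 deg)|, bow ~ N(0, 12 mm), hump ~ |N(0, 6 mm)|, and a
    per-subject BMI proxy scaling of both semi-axes.
    """
    base = base or TorsoSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        scale = float(np.exp(rng.normal(0.0, 0.12)))
        a0, b0 = base.a_fn(), base.b_fn()
        out.append(replace(
            base,
            a=(lambda t, s=scale, f=a0: s * f(t)),
            b=(lambda t, s=scale, f=b0: s * f(t)),
            theta_deg=float(abs(rng.normal(0, 8.0)) * rng.choice([-1, 1])),
            bow_mm=float(rng.normal(0, 12.0)),
            hump_mm=float(abs(rng.normal(0, 6.0))),
            hump_side=str(rng.choice(["left", "right"])),
            seed=int(rng.integers(0, 2 ** 31 - 1))))
    return out
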