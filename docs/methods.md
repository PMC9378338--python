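# Methods

This note documents the models, conventions, numerical choices and known
limitations of `torsometry`. Axes throughout: +x patient right, +y
anterior, +z cranial; internal lengths in millimetres, reported units cm /
dm² / L / mm / degrees.

## Geometry core

All measurements reduce to exact operations on watertight triangle meshes.

**Plane slicing.** Face/plane intersection segments are oriented along
`cross(plane_normal, face_normal)` and chained into closed loops with
endpoint merging at 1e-6 mm; vertices exactly on the plane are nudged 1e-9
to the positive side (simulation of simplicity), so watertight input always
yields closed loops and an open chain is reported with its gap location.
Collinear loop vertices (face-diagonal crossings on flat walls) are
dropped. When a slice produces several loops the largest-area loop is taken
as the torso outline and a warning is logged — the template torso has no
arms, so extra loops indicate registration failure.

**Polygon metrics.** Area (shoelace), area centroid and central second
moments come from the standard boundary-integral closed forms; the
principal trunk axis is the eigenvector of the larger second-moment
eigenvalue, wrapped to (−90°, +90°], positive rotating +u toward +v. A
section whose moment eigenvalues agree within 1e-9 relative is reported as
"axis undefined" rather than returning noise.

**Slab volumes.** The surface is clipped to the slab between two parallel
transverse planes (Sutherland–Hodgman per triangle), cut boundaries are
capped by centroid fans of the slice loops (torso sections are star-shaped
about their centroids), and the volume follows from the divergence theorem
on the resulting closed surface. This makes volume additivity across any
interior partition plane exact to floating-point (observed ~1e-15
relative). Region surface areas clip boundary triangles exactly against the
slab planes instead of including/excluding whole triangles, which makes
back-area resolution-stable.

**Closest-point queries.** Exact point-to-triangle projection over the k=12
nearest triangle candidates from a KD-tree on triangle centroids. This is
the workhorse of registration; it is fully vectorized and deterministic.

## Template atlas

The atlas is generated programmatically: a stack of `n_levels` torso cross
sections of `n_around` vertices each plus two cap fans, spanning the trunk
from the PSIS plane (t = 0) to the C7 plane (t = 1), default 61 x 96 over
480 mm. The cross-section profile has an elliptic front and a *flattened
back*: a straight posterior segment of half-width 0.45·a at depth −b,
rounded into the flanks by quarter ellipses. Backs are much flatter than
ellipses, and the flat segment is what lets a scoliometer-style tangent
line respond 1:1 to axial rotation (see BSR below).

Grid constraints: `n_around % 16 == 0` and `(n_levels − 1) % 20 == 0`.
These make the nine landmark parameter positions (anterior/posterior
midline columns, ±π/8 off-midline columns; levels at multiples of 0.05)
fall on exact grid vertices at any compliant resolution, so the template's
landmark vertices and the synthetic generator's landmark truth coincide
parametrically — landmark correspondence carries no quantization error.
Mirror symmetry, the symmetry involution, dorsal/ventral face labels and
the dorsal midline chain are exact by construction and verified by
`TemplateAtlas.validate()`.

## Registration

Markerless initialization: PCA axis alignment of the vertex clouds
(longitudinal = largest extent), the four proper-rotation sign combinations
scored by subsampled closest-point RMS, isotropic scale from longitudinal
extents, then up to 30 rounds of similarity-Procrustes ICP. A
landmark-hint Procrustes initialization exists for debugging and fixtures.

Nonrigid stage: per-vertex displacements d minimize

    sum_i w_i ||x0_i + d_i − p_i||² + λ dᵀS d

with p_i the closest scan-surface point, w_i ∈ {0,1} rejecting
correspondences beyond d_max = 30 mm or with normals disagreeing by > 60°,
and λ stepped over {50, 20, 8, 3, 1} with 20 inner iterations (one sparse
factorization + solve) per stage. The stiffness S is the **graph
bi-Laplacian** (bending energy ‖L d‖²) rather than the first-order
edge-difference penalty: on warp-recovery fixtures the first-order penalty
leaves 3–6 mm of tangential landmark sliding, while the bending penalty
reproduces smooth low-frequency warps to < 2 mm RMS at the same residual.
The first-order penalty remains available (`ICPParams(stiffness=
'laplacian')`). Registration contains no randomness; a residual that fails
to decrease over a full λ stage raises with diagnostics, and flipped
triangles are counted and warned about.

**Correspondence limitation.** Closest-point data cannot observe tangential
sliding along a smooth section outline. Axial twist therefore gets
partially redistributed along the trunk (a 10° mid-trunk twist produces
several mm of tangential landmark error at the trunk ends), and a one-sided
hump can rotate the fitted frame by ~1–2°. The *surface geometry* of the
registration is unaffected (residuals ~0.3–0.5 mm), so geometric measures
remain accurate; only material correspondence under twist degrades. The
landmark-transfer validation therefore uses observable deformations
(lateral bow, isotropic size and height change), and the twist case is
asserted only loosely. Resolving this ambiguity needs features beyond the
torso surface (e.g., full-body context), which is out of scope.

## Body frame and measurements

Frame: origin = PSIS midpoint; w = unit(C7 − origin); u = unit(PSIS_R −
PSIS_L) orthogonalized against w; v = w × u. Upright poses (EOS, A-pose)
reference the coronal plane; the Adam forward-bend pose references the
floor, using the horizontal in-slice direction sign-matched to u. Profile
measures sample 201 uniform levels t ∈ [0, 1]; slice planes are pulled
0.5 % of trunk height inboard of the exact end planes because a registered
torso's caps may sit a few millimetres inside the scan and cap-zone slices
are distorted.

* **Spine length** (cm): arclength of the registered dorsal midline chain,
  prepended with the PSIS centroid.
* **Back area** (dm²): dorsal-labelled faces clipped to the PSIS–C7 slab;
  left and right halves also reported.
* **XSA** (dm²): largest slice loop through the transverse plane at L2, T8,
  JN; loops under 1 dm² log a registration-quality warning.
* **XSV** (L): slab volumes L2–T8, XP–JN, PSIS–JN; inverted landmark order
  raises, naming the pair.
* **BSR** (deg): the scoliometer tangent is operationalized as the
  posterior supporting line of the section — the convex-hull edge that
  faces posteriorly and spans the sagittal midline (the centroid's lateral
  coordinate), i.e. the line a scoliometer would rest on across both
  paraspinal prominences. Positive = left side more posterior. Note that
  for a *purely elliptic* (smooth convex) section this line provably does
  not rotate 1:1 with the section (a 150/100 mm ellipse rotated 10° gives
  ~5.5°); with the flat-backed profile it does, exactly. Reported at
  25/50/75 % and as the signed maximum-magnitude value over the trunk.
* **Centroid deviation** (mm): leftward slice-centroid offset vs the
  PSIS-level slice centroid; signed maximum over the trunk. Positive =
  toward patient left.
* **Trunk axis** (deg): signed maximum principal-axis angle; near-isotropic
  levels are skipped with a log entry, all-isotropic raises.
* **Qangle** (deg): the back symmetry line (the registered midline chain —
  the pipeline has full correspondence, so the correspondence line is used
  rather than re-deriving it by asymmetry minimization) is resampled to 201
  points, its leftward deviation fit with a 4th-order harmonic; the apex is
  the interior extremum of |x(t) − a0|, end tangents are the nearest slope
  extrema on each side (range ends allowed), and the angle is
  atan(s_above) − atan(s_below) with physical slope s = x'/trunk length,
  signed by apex direction. A monotone curve returns 0 with a "no curve"
  flag.

The Adam pose carries only spine length, back area and the BSR family; the
remaining measures are suppressed and listed in the suite's `suppressed`
field. Intrinsic measures are rigid-motion invariant to < 1e-6 relative
when measured directly; through re-registration they agree to ~1e-3
(registration is deterministic but not exactly equivariant in floating
point).

## Synthetic torso generator

The generator emulates the scanner + cohort: stacked flat-backed (or
elliptic) sections with spline semi-axis profiles a(t), b(t); lateral bow
c(t) = A sin(πt) toward the patient's left for A > 0; axial rotation
θ(t) = Θ sin(πt) about each section's area centroid; a one-sided Gaussian
dorsal hump g(φ) = h·exp(−(φ−φ0)²/2σφ²), σφ = 0.35 rad, centred 30° off
the posterior midline. Defaults (H = 480 mm, a ≈ 140–160 mm, b = 100 mm,
Θ = 10°, A = 15 mm, h = 8 mm) describe a mid-adolescent trunk with
moderate AIS-range deformity; the cohort sampler draws Θ ~ ±|N(0, 8°)|,
A ~ N(0, 12 mm), h ~ |N(0, 6 mm)| and a log-normal (σ = 0.12) BMI-proxy
scale on both semi-axes.

Ground truth is analytic: XSA(t) by dense-outline shoelace (4096 points),
XSV by 1D quadrature of XSA, centroid and rotation curves exactly A sin(πt)
and Θ sin(πt), the dorsal midline curve and its arclength by dense
sampling (2001 levels), dorsal area by fine parametric quadrature
(400 × 512). Mirroring the spec (A→−A, Θ→−Θ, hump side swap) mirrors the
mesh exactly, vertex for vertex.

An Adam's-bend operator bends the trunk with constant sagittal curvature
(default 80°) about the section centres — the dorsal surface, on the
outside of the bend, lengthens, as in the clinical pose — then lays the
trunk horizontal, back up.

Scan-protocol perturbations: *test-retest* applies small rigid jitter
(σ = 0.5°, 2 mm) plus 0.3 mm vertex noise along normals; *remove-replace*
additionally re-poses with ΔΘ ~ N(0, 2°), ΔA ~ N(0, 3 mm) (per-rater bias
σ = 1° / 1.5 mm in pipeline studies). All draws are deterministic given the
seed. What the generator does **not** emulate: soft-tissue deformation,
breathing, clothing, scanner occlusion/holes beyond simple face deletion,
and arms — so passing tests demonstrate correctness of the measurement
machinery and its noise response, not robustness to real scanner artefacts.

## Reliability statistics

ICC(2,1) is the two-way random-effects, absolute-agreement, single-rating
coefficient: (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)), with
the standard F-quantile confidence bounds (Satterthwaite df for the
column/error mix), α = 0.05 two-sided. Negative estimates are reported as
computed. The implementation is verified against a definitional
sums-of-squares oracle (≤ 1e-10) and against `pingouin.intraclass_corr`.

A caveat established by simulation here: with k = 2 raters redrawn per
study, the F-based CI covers each study's *realized* (conditional-on-its-
raters) ICC at ~99 %, but the unconditional super-population ICC at only
~67 % for n = 200 — an estimator property (one-sided misses when the two
drawn raters happen to agree), not an implementation defect. Reliability
reports should read the CI as conditional on the study's raters.

Study tables are long-format (subject, rater, placement, trial, parameter,
value). Scan-pair policy for the report: test-retest = the two trials of
placement 0; remove-replace = first trial of each placement; inter-rater =
each rater's first scan. RMS error is the quadratic mean of differences.
The BMI screen uses relative inter-rater differences for intrinsic
measures, absolute for pose-dependent, Spearman correlation, and
Bonferroni–Holm at family α = 0.05. Paired ICC-set comparison uses the
two-tailed paired t test with a documented degenerate convention: zero
difference variance returns (0, n−1, 1.0) if the mean difference is zero,
(±inf, n−1, 0.0) otherwise.

## Problem sizes in tests and validation

Registration fixtures run at the 41 × 48 template resolution with scans at
81 × 96; analytic-accuracy checks use 61 × 128 meshes; profile measures use
the default 201 levels in validation and 21–41 levels in fast unit tests;
ICC simulations use 200–500 replicates in proxy (closed-form) mode. These
sizes were chosen so the entire validation runs on one CPU in minutes while
every tolerance is met with margin; accuracy improves monotonically with
mesh resolution (verified on analytic shapes).

## Known limitations

* Tangential correspondence under axial twist and strong one-sided humps
  (discussed above): landmark transfer and the frame inherit a few mm /
  ~1° of bias on twisted torsos; geometric measures are unaffected.
* The BSR supporting line needs a non-convex or flattened dorsal profile to
  track rotation; on a perfectly elliptical torso BSR under-reports
  rotation by construction (any scoliometer would).
* Cap-zone slices within ~0.5 % of the trunk ends are avoided rather than
  repaired.
* No handling of limbs or head in scans: the pipeline assumes a torso-only
  scan or relies on correspondence rejection (d_max) to ignore extra
  geometry nearby.
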