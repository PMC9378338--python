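# torsometry

Automated surface-topographic measurement of trunk shape for spinal
deformity assessment.

Adolescent idiopathic scoliosis (AIS) is a 3D deformity of the spine whose
severity is classically graded on radiographs (Cobb angle), at the cost of
repeated ionizing exposure, and whose visible expression — rib prominence,
waist and shoulder asymmetry — is what patients actually see.  `torsometry`
implements a fully automated pipeline that turns a raw 3D torso scan
(OBJ/PLY/STL triangle mesh from any surface scanner) into a suite of
objective trunk-shape measurements, with no fiducial markers and no manual
landmarking, plus the statistical toolkit to quantify their reliability.

## How it works

1. **Template registration.** A generic, perfectly mirror-symmetric torso
   template ("atlas") is deformed onto the scan with a stiffness-regularized
   nonrigid ICP (coarse-to-fine schedule, bending-energy regularizer,
   closest-point correspondences with distance and normal gating).  The
   output is a clean watertight torso with fixed connectivity and full
   anatomical correspondence to the atlas, so the nine landmarks (PSIS and
   ASIS bilaterally, xiphoid process XP, jugular notch JN, and the L2 / T8
   / C7 spinous processes), the dorsal midline chain and the left/right
   dorsal regions — defined once on the template — transfer to every scan.
2. **Body frame.** From the landmarks: origin at the PSIS centroid,
   longitudinal axis `w` toward C7, lateral axis `u` toward the patient's
   right, anterior `v = w x u`; trunk levels are parametrized by
   `t ∈ [0, 1]` from the PSIS plane to the C7 plane.
3. **Measurements.** Intrinsic (rigid-motion invariant): spine length (cm),
   back surface area (dm²), cross-section areas at L2/T8/JN (dm²), section
   volumes L2–T8, XP–JN, PSIS–JN (L).  Pose-dependent (signed
   asymmetries): back surface rotation BSR (the scoliometer angle, at
   25/50/75 % levels and its maximum anywhere on the trunk), coronal
   centroid deviation (mm), transverse principal-axis rotation (deg), and
   the Qangle — a Cobb-style angle between the inflection tangents of a
   fourth-order harmonic fit to the back symmetry line.
4. **Reliability.** ICC(2,1) (two-way random, absolute agreement, single
   rating, with F-based 95 % CI), RMS error, Spearman screening of
   consistency vs BMI with Bonferroni–Holm correction, and paired
   comparison of ICC sets.

Because clinical scans cannot ship with a package, validation is built on a
**parametric synthetic scoliotic torso generator** with exact analytic
ground truth: controllable lateral spine bow `c(t) = A sin(πt)`, axial
rotation `θ(t) = Θ sin(πt)`, one-sided dorsal hump, pose perturbations
between repeated "scans" and per-rater bias for ICC studies.

## Worked example

```python
import torsometry as tm

# a synthetic scoliotic subject: 15 mm leftward bow, 10 deg axial rotation,
# 8 mm left dorsal hump, trunk height 480 mm
spec = tm.TorsoSpec()
mesh, landmarks, truth = tm.generate_torso(spec)

# register the shipped symmetric template and measure
atlas = tm.build_template_atlas(n_levels=41, n_around=48)
reg = tm.nonrigid_icp(atlas, mesh)
suite = tm.measure_all(reg)
print(f"residual      {reg.residual_rms:.2f} mm RMS")
print(f"spine length  {suite.spine_length_cm:.1f} cm")
print(f"back area     {suite.back_area_dm2:.1f} dm2")
print(f"XSA L2        {suite.xsa_dm2['L2']:.2f} dm2")
print(f"BSR max       {suite.bsr_deg['max']:+.1f} deg")
print(f"centroid dev  {suite.centroid_dev_mm:+.1f} mm")
```

prints (registration at the 41 x 48 test resolution):

```
residual      0.49 mm RMS
spine length  47.6 cm
back area     20.3 dm2
XSA L2        4.79 dm2
BSR max       +7.6 deg
centroid dev  +13.7 mm
```

The signed conventions: positive BSR / axis = the patient's left side is
more posterior; positive centroid deviation / Qangle = deviation toward the
patient's left.  Here the +7.6° BSR maximum reflects the injected 10°
rotation (blended with the 8 mm hump and blurred slightly by template
correspondence), and the +13.7 mm centroid deviation recovers the injected
15 mm leftward bow.  Measuring the generated mesh directly (bypassing
registration, `tm.as_registered`) gives +9.2° and +15.7 mm.

A command-line interface wraps the same pipeline:

```bash
torsometry atlas-build --out atlas/
torsometry measure scan1.obj scan2.obj --pose A-pose --out results/
torsometry simulate --subjects 5 --seed 1 --out simulated/
torsometry reliability simulated/study.csv --out report.csv
```

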