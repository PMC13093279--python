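# Methods

This note records the models, conventions and numerical choices behind
`surftrack`, and what the synthetic-data tests do and do not demonstrate
about measured data.

## Coordinate frame and transforms

All quantities live in a fixed right-handed patient frame: `x` = LR
(positive toward the patient's left), `y` = AP (positive anterior),
`z` = SI (positive superior); lengths in mm, angles in degrees. A
`RigidTransform` maps reference-frame coordinates to current-frame
coordinates (`p_cur = R p_ref + t`), so its 6-DoF decomposition reads
directly as "displacement since the reference image". The relative motion
of the body with respect to the mask is `M_rel = M_body · M_mask⁻¹`,
identity when body and mask move together.

**Displacement decomposition.** The translational part of a displacement is
the motion of the *reporting origin* (`t(o) − o`); the rotational part is an
intrinsic Euler decomposition, by default yaw (SI) → pitch (LR) → roll (AP),
right-hand rule about each positive axis. No convention for the rotation
sequence or signs is canonical in this setting; ours is configurable, and a
tested property shows the sequence choice moves the decomposed angles only
at second order (≈ θ²/2 rad: 0.009° at 1°, < 0.002° below ~0.35°), i.e. it
is immaterial for the ≲1.5° rotations seen in practice. Gimbal lock
(|middle angle| near 90°) is flagged with a warning; it cannot occur for
clinical-scale motion.

**Reporting origin.** The origin sits on the chair's vertical rotation axis
(15 cm anterior to the backrest plane in the default geometry) at the SI
height of the anchor marker — A2 for abdominal setups, H1 for head-and-neck
— in the reference image. Rotations therefore have a clinically meaningful
lever arm: a pure yaw shows up as yaw plus the LR/AP motion of the axis
point it is reported about.

## Camera model, calibration and triangulation

Cameras follow the pinhole model with Brown–Conrady distortion
(k1,k2,k3,p1,p2; zero by default — no coefficients are published for the
rig we emulate, and the machine-vision lenses involved are nearly
distortion-free; the pipeline accepts coefficients when supplied).
Intrinsics are inputs, not estimated: the default synthetic values derive
from the 25-mm lens and a 2.4-µm pixel pitch implied by a 5496 × 3672
sensor, giving f ≈ 10 417 px.

**Extrinsics** are fit per camera by nonlinear least squares (Levenberg–
Marquardt over 6 pose parameters, rotation vector + translation) on the
reprojection residuals of the grid-plate detections from six plate poses.
The RMS reprojection error is reported per residual *coordinate*, so on
noisy data the optimum sits at the injected/detection noise floor (0.5 px
noise → RMS ≈ 0.5 px). Degenerate inputs (fewer than 6 points, collinear
points) and non-convergence raise errors with diagnostics.

**Triangulation** is a linear DLT solve in undistorted normalized
coordinates followed by Gauss–Newton refinement of the summed squared pixel
reprojection error (3 iterations; the DLT start is near-optimal, and on
noiseless data the result is exact to machine precision). Ray pairs
subtending less than 1° raise a degenerate-geometry error. Camera pairs
follow the side rule: left-side markers use front+left, right-side
front+right, the lateral pair is the fallback when the front camera misses
the marker; a marker seen by fewer than two cameras is flagged invalid,
never silently dropped.

**Grid verification** triangulates a held-out plate pose (41 × 58 points,
5.0-mm spacing, 2378 points) with each camera pair and reports per-axis and
3D absolute-error mean, SD (n−1) and 95th percentile (linear interpolation
between order statistics, recorded in the report metadata).

## Marker detection

Each 5-mm black marker is detected inside a static per-marker patch box:
binarise (Otsu by default; fixed threshold optionally), then take the
centroid of the zero-valued pixels as the sub-pixel 2D position. Pixel
(row i, col j) has centre (u,v) = (j,i), 0-based. Detections with fewer
than `min_area` = 10 dark pixels are invalid (speckle rejection; also how
covered/removed markers surface in the outputs). The binarised-centroid
detector is quantisation-limited: for the ~17-px marker radius of the
default rig its error floor is ≈ 0.03 px RMS (~4 µm·px⁻¹-scale, i.e.
≈ 0.004 mm per marker at 0.144 mm/px), which is why end-to-end accuracy
statements for the image path are made at the 0.05-px level while the
cloud-level registration oracles hold to 1e-9.

## Registration and tracking

The inner rigid fit is the closed-form Kabsch/Procrustes solution via SVD
with the determinant correction (reflections never returned); ICP
alternates nearest-neighbour correspondence with Kabsch updates until the
RMS change drops below 1e-6 mm (max 50 iterations, identity init — the
millimetric motions at hand are well inside the convergence basin). A
labeled-correspondence mode bypasses the nearest-neighbour step and serves
as the exact oracle in tests. Only markers valid in *both* clouds
participate; frames with fewer than three usable markers are flagged
unregistered and the pipeline continues. The per-iteration RMS history is
exposed; non-increase is asserted in the test suite.

**Respiratory smoothing.** Abdominal body markers (A1–A9) move with
breathing, which the 5-s frame cadence cannot resolve (a ~4-s cycle aliases
to a ~20-s apparent one). Before the body registration of an
intra-fractional session their positions are smoothed with a 5-frame
moving average — centred, edges truncated to the available frames
(a trailing window is available as an option). The moving-average gain
|sin(5ωΔt/2)/(5 sin(ωΔt/2))| bounds the leakage of a breathing sinusoid
into the body transform for interior frames. One consequence of the
truncated edges is that the *reference frame itself* (frame 0) is smoothed
over only three frames, so an O(amplitude) constant respiratory offset can
enter every displacement of a session; the tests pin this behaviour
exactly, and it should be kept in mind when reading AP displacement series
of abdominal sessions. Inter-fractional single images are never smoothed.
Thigh markers (A10, A11) are excluded from the body fit and reported as raw
per-marker displacement vectors.

## Setup-error statistics, BDT, comparisons

For each axis, with subject means m_s and per-subject SDs s_s over
repetitions (all SDs with n−1): μ = mean(m_s), Σ = SD(m_s) over subjects,
σ = mean(s_s). 3D setup errors are the L2 norms of the translational
triplets per repetition; μ/Σ/σ of those norms plus their plain
mean ± SD are reported, with rotations summarised per axis. Note that
mean-of-SD is a biased estimator of an underlying Gaussian σ*:
E[s] = c₄(n)·σ*, c₄(5) ≈ 0.940 for five repetitions — a property of the
definition, not of the implementation. Subjects with fewer than two
repetitions are excluded from σ and flagged.

**BDT.** A frame is within tolerance when all |translations| ≤ t_tol and
all |rotations| ≤ r_tol (defaults ±2 mm/±1° abdominal, ±1.5 mm/±1°
head-and-neck). Frame 0 is the reference (zero by construction) and
contributes no interval; each later within-tolerance frame contributes one
full 5-s interval, so a 241-frame 20-min session can attain exactly 20 min.
The default convention sums all within-tolerance intervals; an
"until first violation" convention is selectable, and reports name the
convention used. Per-axis tolerable times use the same counting per
component; the total is never greater than the smallest per-axis time.
Unregistered frames count as violations.

**Comparisons.** Means are compared with Welch's unequal-variance t-test
(Welch–Satterthwaite df), variances with the Brown–Forsythe test (one-way
ANOVA on |y − median|), both two-sided at α = 0.05; for pair families
(e.g. all six pairs of four head-and-neck setups) p-values are
Holm–Bonferroni adjusted within each test family, while a single pair is
reported unadjusted. The implementations delegate to scipy/statsmodels and
are verified against formula-level brute-force oracles in the test suite.

## Synthetic scenes

The simulator generates every input with known ground truth stored
alongside, so each stage is tested simulate-then-recover; downstream tests
read truth only from the simulator record.

* **Rig**: three 5496 × 3672 cameras, 25-mm lenses, 1500 mm from the
  rotation axis (front at azimuth 0°, laterals at ±75° so the lateral pair
  still subtends 150° and sees the anterior surface), aimed at the marker
  volume. The true rig of the emulated experiment is unpublished; these are
  plausible defaults, all in one config object.
* **Layouts**: 26 markers per setup. Abdominal: A1–A9 on a 3 × 3 grid of an
  elliptic-cylinder torso (respiratory surrogates), A10–A11 on the thighs,
  M1–M15 on a mask shell 8 mm proud of the skin. Head-and-neck: H1–H10 on
  an ellipsoidal head through the mask holes, M1–M16 on the mask shell.
  Minimum inter-marker spacing > 20 mm (nearest-neighbour-ICP safety
  margin, tested).
* **Intra-fractional motion**: saturating drift A(1 − e^(−t/τ)) per axis
  (defaults: +1.5 mm AP, −1.5 mm SI, small LR and rotations, τ = 150 s —
  anterior/inferior drift largest in the first five minutes); additive
  zero-mean respiration (1.5 mm AP sinusoid, 4-s period) on respiratory
  markers only, deliberately aliased by the 5-s cadence; a small
  independent mask-relative drift; near-static thigh offsets; 4% marker
  dropout per frame (never on the reference frame); 0.2-px detection noise.
* **Inter-fractional setups**: per subject one systematic offset
  ~ N(0, Σ*) (defaults 2.0 mm / 0.8°), per repetition an additional random
  offset ~ N(0, σ*) (1.5 mm / 0.5°), five repetitions.
* **Grid fixture**: six tilted calibration plate poses plus one held-out
  verification pose near the axis.
* All randomness flows from one seed through named substreams
  (`SeedSequence([seed, crc32(name)])`), so stages re-run independently and
  bit-identically.

**What the synthetic data does not emulate**: occlusion and visibility are
not modelled (a marker is "seen" whenever it projects in bounds); skin and
cloth deform only through the bulk respiratory term; no photorealistic
rendering, camera synchronisation lag, thermal drift of the rig, or chair
rotation. Passing recovery tests therefore demonstrates the correctness of
the *computation* under the stated motion model, not the field accuracy of
a physical camera installation.

## Problem sizes and defaults used in tests and the acceptance script

Sessions are the full 241 frames (20 min at 5 s); grid stages use all
6 × 2378 calibration observations; ICP oracle sweeps use 200 random scenes;
type-I error checks use 2000 null replicates of n = 10 samples;
inter-fractional recovery uses 200 subjects × 5 repetitions; the
demonstration report uses 15 subjects, matching the emulated study's
enrolment. These sizes keep the whole suite comfortably fast on a single
CPU while leaving Monte-Carlo error well below the asserted bounds.

## Known limitations

* Automatic tracking of drifting patch boxes is out of scope; boxes are
  static per session, sized for the expected few-mm motion.
* No deformable or affine registration; the method is rigid by design.
* The σ (random setup error) definition is biased low by c₄(n) for small
  repetition counts (see above).
* The truncated-edge smoothing of the reference frame injects a constant
  respiratory offset of up to ~a/3 into abdominal displacement series.
* No bundle adjustment across cameras; each camera is calibrated
  independently against the known plate.
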