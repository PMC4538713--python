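# Methods

`navmc` implements motion quality control and frame-based motion correction
for simultaneous PET/MR brain imaging driven by *sparsely sampled MR
navigators*: fast low-resolution 3D EPI volumes acquired in the gaps between
diagnostic MR sequences, each providing a snapshot of head pose during the
PET acquisition.

## Motion model and the magnitude metric

Head motion is modelled as rigid: a 4×4 homogeneous matrix with an
orthonormal rotation block (det +1) and a translation column in mm,
generated from six parameters (rx, ry, rz in degrees; tx, ty, tz in mm).
Rotations are intrinsic, applied x→y→z about the world origin, followed by
the translation. The world frame is right-handed RAS with the origin at the
scanner centre of field of view (cFOV); +y is anterior. Angles are stored
in degrees to match neuroimaging reporting; radians are used internally.
Parameter extraction from a matrix uses the same convention; at gimbal lock
(|ry| = 90°) the extracted angles are chosen so the matrix is reproduced
exactly, which is the only property downstream code relies on.

A transform maps reference-space coordinates to moved-space coordinates.
The **motion magnitude** at a reference point `p` is `|T(p) − p|`. The
canonical QC point is the frontal cortex point `(0, 60, 0)` mm — 60 mm
anterior of the cFOV — where rotations produce their largest displacement
(the front of the head moves most); the cFOV point `(0, 0, 0)` is tracked
alongside to separate rotational from translational motion. For a pure
rotation by θ about an axis through the origin the magnitude at radius r is
the chord `2 r sin(θ/2)`; for a pure translation it is the translation norm
at every point. Whether an upstream registration package would report the
transform or its inverse is not observable from magnitudes alone; `navmc`
fixes the reference→moved convention and documents it throughout.

## Navigator registration

Each navigator is rigidly registered to the first navigator of the session
(the reference position). The implementation is intentionally plain and
deterministic:

* **Metric**: normalised cross-correlation (default), which is invariant to
  the global intensity scaling differences EPI volumes show between
  acquisitions; SSD is available for speed on intensity-calibrated data.
  The metric is evaluated by trilinear interpolation of the moving volume
  at transformed fixed-voxel positions; samples outside the moving FOV are
  excluded rather than zero-filled, and a pose is rejected outright if
  fewer than 25% of the fixed voxels remain in overlap.
* **Masking and subsampling**: the metric uses only fixed voxels above a
  low intensity threshold (25% of the robust maximum, dilated by 2 voxels)
  — background voxels are pure noise and dilute NCC — and at most 20 000
  of them (even stride), which leaves registration accuracy unchanged on
  the navigator grids used here while bounding the cost of one metric
  evaluation.
* **Pre-smoothing**: both volumes are smoothed by 0.8 voxel sigma before
  metric evaluation at every pyramid level, including the finest. This is
  not cosmetic: on noisy images, intensity metrics are biased toward
  slightly rotated/shifted poses where sub-voxel interpolation averages
  away moving-image noise and spuriously raises the correlation. Without
  the smoothing this bias reaches ~1° on SNR-20 navigators; with it,
  recovery errors drop to ~0.1° / 0.1 mm.
* **Optimisation**: a 3-level Gaussian pyramid (subsampling 4, 2, 1) with a
  deterministic shrinking-step coordinate search over the six parameters
  (initial step 2 mm / 2°, halved to 0.01 at the finest level; fixed axis
  order; first improving move accepted). The identity is kept as a
  candidate at every level, so the returned metric is never worse than the
  identity's. There is no randomness unless optional perturbation restarts
  are enabled, in which case they are seeded.

The ten navigators of a burst are registered independently (the default;
averaging before registration is possible by passing the mean volume).
The transform returned maps fixed-space points to moving-space sample
locations, which for a moving head equals the head-motion transform itself.

## Frame definition — the midpoint rule

PET frames are split at the midpoints between consecutive navigator start
times, so every instant of PET data is linked to the nearest motion sample.
The first frame starts at the scan start and the last ends at the scan end;
frames are half-open `[start, end)` with the last closed, so they tile the
scan window exactly. A navigator outside the scan window still contributes
its midpoints, but its frame is clipped to the window and dropped (with a
warning) if clipping empties it.

Applying the rule to the mean burst times 73, 441, 698, 876, 1412, 1947 s
on a [0, 1980] s window gives boundaries 257, 569.5, 787, 1144, 1679.5 s
and durations 257, 312.5, 217.5, 357, 535.5, 300.5 s. Published mean frame
durations for this protocol (259, 306, 191, 342, 546, 157 s) are *not*
exactly reproducible from mean navigator times under the midpoint rule —
per-subject scan-window handling averages differently — so the toolkit
implements the stated rule and makes no attempt to reverse-engineer
per-subject details.

## Motion QC

The QC products are: a **motion trace** (per-navigator transform and
magnitudes at the frontal-cortex and cFOV points, with the identity
reference prepended), the **intra-burst spread** (largest magnitude of each
burst transform referred to the burst's own first navigator — internal
consistency isolates registration noise from real inter-burst motion), and
the **MC decision**: correction is recommended when the maximum magnitude
at the frontal-cortex point strictly exceeds 4.0 mm. Clinical use of this
protocol corrected the subjects above 4 mm; a contrary phrasing in the
source literature ("MC will not have any (positive) effect at motion
magnitudes >4 mm") is evidently a typo for "<4 mm" and the operational rule
is implemented. The burst representative transform is the burst's first
navigator's (averaging rigid transforms needs extra machinery and is not
the default).

## Frame-based correction (MAF)

Multiple-acquisition-frames correction: each frame is reconstructed at its
own pose, pulled back to the first frame's space (the reference frame
carries no transform), and the aligned frames are averaged.  Because `T_n`
maps reference space to frame-`n` space, the corrected value at `p` is
frame `n` interpolated at `T_n(p)` — trilinear, matching the ~5 mm smooth
PET resolution; sinc/spline interpolation is deliberately omitted.
Averaging is **duration-weighted** by default: with frame lengths spanning
roughly 157–546 s, a plain mean would mis-weight counts; `uniform` mirrors
a literal plain average. Voxels that no frame covers get zero weight and
are NaN in the output — never silently zero — and a weight map records the
effective seconds per voxel. Intra-frame motion is assumed negligible;
decay correction is assumed already applied per frame (as scanner
reconstructions do), so averaging constant-activity frames is unbiased.

## SUVr

SUVr is the mean uptake in a target cortical region divided by the mean in
the cerebellum reference region, with uptake above 1.5 (strict) classified
as abnormal (PiB-positive). The direction is target/cerebellum: published
positive-subject values (2.59–3.05 against a 1.5 cutoff) admit no other
reading, although the phrase "cerebellum to region ratio" appears in the
source literature; the ambiguity is noted here once. Masks are supplied on
the image grid (no atlas registration); invalid voxels from correction are
excluded from means. For quantification on the synthetic phantom, masks
are eroded by 2 voxels (~one 5 mm-FWHM blur sigma at 2 mm voxels) to pull
region means off partial-volume-affected compartment edges.

## The synthetic session generator

No patient data ships with the package; the simulator emulates the study
conditions and provides exact ground truth.

* **Phantom**: nested ellipsoids on a 128×128×63 grid at 2 mm — head
  (scalp), brain with a 12 mm cortical shell, white-matter interior,
  cerebellum, ventricle — with independent PET-activity and MR-contrast
  levels per compartment. Defaults describe an amyloid-positive pattern:
  cortex 2.6, white 1.5, cerebellum 1.0, ventricle 0.3, scalp 0.2
  (arbitrary kBq/mL-like units). The 12 mm shell is thicker than human
  cortex; it is chosen so region means remain meaningful at the ~5 mm PET
  resolution of this crude piecewise-constant geometry. The head spans
  ±65/±80/±50 mm, keeping it fully inside the FOV under the largest
  simulated motions (conservation checks rely on this).
* **Motion scripts**: piecewise-constant pose events (optionally linear
  drift), identity at scan start. The canonical preset is "nod + slide" —
  negative pitch plus inferior translation, the dominant clinical motion
  pattern — stepped up between navigator bursts and scaled (by root
  finding on the chord-plus-translation displacement) so the largest pose
  has exactly the requested magnitude at the frontal-cortex point.
* **Rendering**: a moved volume is the phantom *analytically evaluated* at
  `M⁻¹(p)` on the grid — no interpolation error enters the ground truth.
  Navigators: 64×64×36 at 3 mm, blurred 4 mm FWHM (finite EPI resolution),
  plus Gaussian noise at SNR 20 (in-head mean over sigma; Rician effects
  are ignored at this SNR). Six bursts of ten navigators at mean times 73,
  441, 698, 876, 1412, 1947 s; the scan window is [0, 1980] s so the late
  sixth burst lies inside (a strict 1800 s window would exclude it).
  PET frames: activity under the frame's pose, blurred by a 5 mm FWHM
  isotropic PSF (scanner + reconstruction filter), Poisson-sampled at 0.5
  expected counts per voxel·second·activity-unit — about 5% relative noise
  in cortex for a 5-minute frame, matching reconstructed-image noise
  levels — and returned in activity units. No attenuation, scatter,
  randoms, or MR physics are modelled.
* **Determinism**: one seed drives all noise; identical seed and spec give
  bit-identical sessions.

What passing on this generator does *not* show: robustness to EPI
distortion, Rician noise, attenuation artefacts, realistic anatomy, or
intra-frame motion (available only as a deliberate violation mode).

## Problem sizes used by the test suite and acceptance script

Parameter-recovery tests use 20 navigator pairs at the full navigator grid;
burst-noise tests use 20 zero-motion bursts of 10; the correction benefit
uses 10 preset sessions at 8 mm motion with burst-representative
registration (5 registrations per session). `scripts/acceptance.py` runs
the same pipeline at reduced counts (5 pairs, 3 bursts, 2 sessions, 1000
schedules) — sizes chosen as a desk-scale demonstration of the same
properties.

## Known limitations

* The registration capture range is bounded by the coarse pyramid level;
  initial misalignments far beyond ~15 mm / 10° may need the optional
  seeded perturbation restarts.
* Rigid-only: no EPI distortion or slice-to-volume correction.
* The burst representative is the first navigator, not a rigid-transform
  average.
* SUVr masks must already live on the image grid; atlas registration is out
  of scope.
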