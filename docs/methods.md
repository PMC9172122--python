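# Methods

This note documents the model conventions, the synthetic data generator,
and the numerical choices made where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Segments, frames and angle conventions

Seven segments are modeled — shank, hindfoot, midfoot, forefoot, optional
medial/lateral forefoot, hallux — each assumed rigid.  Anatomical
coordinate systems follow ISB axes (x anterior, y superior, z to the
subject's right) for both feet; for the left foot the order of a handful
of cross-product arguments is flipped so the constructions stay
right-handed with z pointing to the subject's right.

Two published constructions are self-referential as printed and are
resolved here as follows:

* **Shank.** The formula column defines X from Y and Y from a projection
  that needs a plane normal.  We follow the description column: build the
  quasi-frontal plane through the origin (the malleolar midpoint), LM and
  FH; project TT onto it; Y runs from the origin to that projection;
  X = Y × (LM − O) for the right foot; Z completes.  The printed
  alternative (substituting LM for FH in the plane) is not used.
* **Hallux.** "Z = cross(X, Z)" is read as Z = X × Y, the only
  right-handed completion consistent with Y = Z_medial-forefoot × X.

All axis vectors are normalized after every cross product.  Each
construction here happens to be exactly orthogonal by design (the second
axis is always a cross product involving the first), so normalization
never changes directions, only lengths.

Joint angles use the z–x′–y″ floating-axis sequence on
R = R_prox^T R_dist, radians internally, degrees at every interface.
Sign convention: dorsiflexion, inversion, internal rotation/adduction
positive.  For the left foot the frontal and transverse components of the
raw decomposition are negated so the clinical meaning is side-independent;
the mirror-consistency property (identical curves for a z-mirrored foot)
is enforced by test at 1e-9 deg.  At the frontal-plane singularity
(|frontal| = 90°, unreachable for physiological foot joints) the
transverse angle is set to zero by convention and the remaining rotation
folds into the sagittal angle; the flag `PlaneAngles.gimbal` reports it.

The hallux carries a single marker: its frame is built from the
HM1→HLX vector and the medial forefoot's medio-lateral axis, so its
frontal-plane angle is structurally undetermined and emitted as NaN.
The foot–shank angle (F_SK) is a hook only: the caller supplies a foot
frame from whatever lower-extremity model is in use; no default foot
frame is invented.

## Calibration and reconstruction

Static marker positions are the arithmetic mean over the static trial's
frames (frames with a gap in a marker are excluded for that marker).
For the shank, hindfoot and forefoot the anatomical frame is stored in the
deterministic three-marker technical frame; reconstruction during gait is
therefore exactly invertible on rigid data (asserted at 1e-9).  A
least-squares pose fit over more markers would average soft-tissue noise
but lose exact invertibility; the three-marker construction matches the
model's explicit tracking-marker sets and is the default.  The midfoot,
medial/lateral forefoot and hallux have no static-only markers and are
recomputed directly every frame.

The floor is the lab plane y = floor_y (default 0; configurable for
raised walkways).  "Projected on the ground" means setting the vertical
coordinate to floor level.  The MLA's virtual points CAp (floor projection
of the midpoint of CALP and the ST/PT midpoint) and HM1p (floor projection
of HM1) are stored in hindfoot and forefoot coordinates at calibration.
Consequently the MLA is invariant under any rigid motion of the foot
*given a fixed calibration*, but a calibration recomputed from a static
trial tilted out of the floor plane yields different virtual points —
inherent to a gravity-referenced arch definition, not a defect.

`full_foot_contact` is a user flag, not auto-detected (no reliable
detection rule exists for equinus postures).  Without full contact the
CAp fallback places the point at `reference_ratio × calcaneal_length` in
hindfoot coordinates.  The packaged default ratio is derived from the
synthetic template foot and is a labeled synthetic stand-in, not
population reference data; labs should extract their own ratio from a
reference dataset.

## Gait events and normalization

Events come from the vertical velocity of the foot centre (midpoint of
CALD and HM2; heel-only or toe-only are configurable): the trajectory is
low-pass filtered (4th-order zero-lag Butterworth, 7 Hz default),
differentiated centrally, and prominent minima/maxima are initial contact
and toe-off.  Peaks must exceed both a relative threshold (25% of the
largest |velocity|) and an absolute floor (100 mm/s), so standing trials
produce zero events; a minimum spacing (0.35 s) suppresses double peaks,
and same-type events without an opposite event in between are resolved by
keeping the stronger one.  Strides (IC→IC) are linearly resampled to 101
points, 0–100% inclusive, and averaged point-wise.  Linear interpolation
bounds the min/max distortion by (max slope × sample period), which the
tests assert; the resampling error against a smooth curve is the usual
h²|f″|/8 (≈0.004° for a 10° sinusoid at 100 Hz).

## Marker-placement sensitivity

Displacements run −10…+10 mm in 1 mm steps (21 points, 0 included) along
a foot-specific frame: x = horizontal projection of CALD→HM2, y = lab
vertical, z = x × y.  That frame is our concrete reading of a
"foot-specific CS" for displacement directions; it is configurable and
recorded in output metadata.  The fit is ordinary least squares on the
*signed* per-plane orientation errors (fitting absolute errors would bias
slopes toward zero crossings); the record keeps the signed slope, the
absolute gradient and R².  A marker that does not participate in a
segment's frame yields an explicit not-applicable result, never a zero.

Because the displacement frame is gravity-referenced, gradients are
invariant under floor-preserving rigid motions (yaw + translation) —
asserted at 1e-6 — but not under arbitrary tilts, which change the
displacement directions relative to the foot.

Geometry note: the frontal-plane gradient to medio-lateral displacement
of CALD or CALP is, to first order, (180/π)/d °/mm with d the CALD–CALP
spacing.  On the template (d = 40 mm) the two gradients straddle that
value: displacing either marker also shifts the hindfoot origin, yawing
the (pitched) anterior axis, which leaks into the frontal angle by
sin(pitch); the leak is antisymmetric between the two markers, so their
mean matches the closed form (within 2%, by test) while the individual
values differ by roughly ±6%.

## Soft-tissue-artifact style comparisons

`angles_from_two_marker_sets` compares segment orientations and joint
angles between two marker configurations of the same foot (e.g. with and
without artifact offsets).  Because the two configurations may be
recorded in different global poses, configuration B is first registered
onto A by a least-squares rigid fit (Kabsch) over the shared markers;
joint-angle differences are relative rotations and never needed the
registration.  Set `align=False` when the sets are known to share a lab
frame.

## The synthetic generator

The template foot is a fixed set of anthropometrically plausible marker
coordinates for a neutral-standing right foot of roughly EU shoe size 41
(40 mm CALD–CALP spacing, ~235 mm heel-to-toe), mirrored in z for the
left side and scaled uniformly (0.7–1.4 covers child to large adult).
Fixed constants — not random draws — keep every geometric result
deterministic.

Walking is rigid-per-segment motion down a kinematic chain driven by
prescribed smooth periodic joint curves.  The model shares markers
between articulating segments (BM2/BM5 define both the midfoot and the
forefoot; HM1 belongs to the forefoot and is the hallux origin), so
arbitrary 3-DOF motion at every joint cannot be rigidly consistent with
the model's own constructions.  The generator therefore prescribes
exactly the consistent degrees of freedom:

* hindfoot–shank and midfoot–hindfoot: full 3-DOF Cardan curves;
* forefoot–midfoot: one DOF about the tarsometatarsal axis through BM2
  and BM5 — the shared markers lie on the joint axis and are rigid in
  both segments (a mirrored axis gets the opposite rotation sign so left
  and right feet move symmetrically);
* hallux–medial forefoot: sagittal and transverse; the frontal DOF is
  structurally zero because the hallux y axis is built perpendicular to
  the medial forefoot z.

With this chain every anatomical *and* technical frame moves rigidly and
the full pipeline recovers the prescribed curves to numerical precision
(< 1e-6°, in practice ~1e-12°) on noise-free data — the central
end-to-end test.  Ground truth for the derived joints (FF_HF, FFM_MF,
FFL_MF) is computed analytically from the prescribed rotations, never
from the generated markers, so the recovery test is not circular.

Default conditions: stride time 1.1 s, 60% stance, 3 strides, 1.2 m
stride length, 60 mm foot-centre swing clearance, sagittal amplitudes
12° (ankle), 4° (Chopart), 5° (Lisfranc axis), 15° (MTP), smaller
frontal/transverse amplitudes — unremarkable values for barefoot walking
at comfortable speed.  Curve offsets default to the template's static
angles, so a zero-amplitude profile holds the static pose exactly.

The foot-centre height is built from two opposite raised-cosine velocity
bumps per stride: an upward bump peaking exactly at toe-off and a
downward bump peaking exactly at initial contact.  These peak times are
the generator's ground-truth events and coincide with the features the
velocity-based detector looks for — physically, the heel's descent rate
peaks at heel strike and its rise rate at push-off.  Between the bumps
the foot centre is stationary in stance and at constant height in
mid-swing; forward progression is a smooth bump during swing with no
stance slip.

Perturbations: misplacement offsets move a marker on the template before
motion (a marker glued on in the wrong spot, rigidly carried thereafter);
soft-tissue offsets are pose-dependent functions added after rigid
motion, by default linear in the ankle sagittal deviation — sufficient to
exercise the two-marker-set comparison, with no claim of physiological
fidelity; isotropic Gaussian noise comes from a seeded generator and is
bit-reproducible.

What the generator does *not* emulate: genuine soft-tissue dynamics
(frequency content, correlation across markers), marker occlusion
patterns, foot deformation within segments, double support asymmetries,
or between-subject anatomical variation beyond uniform scale.  Passing
tests therefore demonstrate the correctness of the computational
pipeline, not the model's biological validity on real feet.

## Numerical choices

* Rotation matrices are validated orthonormal (1e-9) with det +1; frames
  failing this raise immediately rather than propagate.
* `angle_between` uses atan2(‖u×v‖, u·v), stable near 0° and 180°.
* Sensitivity slopes via `np.polyfit` degree 1; R² from the residuals.
* The two-measurement SD uses the n−1 denominator (|a−b|/√2).
* SEM aggregation: per-time-point error variance, square root, then
  average over the cycle, mirroring the σ computation; the alternative
  (time-average the variance first) is available as
  `aggregate="time_first"`.
* Shapiro–Wilk at α = 0.05 selects median [IQR] vs mean ± SD for group
  summaries; both are always retained in the record.
* Problem sizes in the shipped tests — 3-stride trials at 100 Hz,
  100 noise realizations for the spurious-event check, 200 subjects for
  the SEM Monte-Carlo — were chosen as the smallest sizes at which the
  asserted statistical tolerances are comfortably stable.

## Known limitations

* Only the downstream computation of soft-tissue-artifact errors (two
  marker configurations → angle differences) is implemented; deriving
  artifact-free marker positions from imaging is out of scope.
* No gap filling: missing tracking markers flag a frame invalid, they are
  never interpolated.
* C3D reading requires the optional `ezc3d` dependency; TRC and wide CSV
  are always available.
* The hallux frontal angle and any joint translation are not reported by
  design.
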