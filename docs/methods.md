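# Methods

## Canonical frame and calibration

All geometry is computed in a canonical frontal frame: millimetres, origin at
the femoral head center, +x medial, +y distal. Landmark files carry pixel
coordinates plus a two-point calibration marker of known physical length;
loading scales by `known_distance_mm / |marker_a − marker_b|`, mirrors left
limbs (x → −x) and translates the origin. One code path then serves both
sides, and mirror invariance of every measure and plan is a testable frame
property rather than a per-function obligation. Coordinates stay real-valued
throughout — no pixel snapping — so construction residuals (point-on-circle,
isometry of rotations) hold to ~1e-9 relative and are asserted at that
tolerance.

## Alignment measures

- **WBL ratio**: the weight-bearing line F→C1 is intersected with the
  *infinite* line through the plateau edges and reported as a signed
  percentage of plateau width from the medial edge. The infinite-line choice
  means severe varus yields negative ratios instead of an error; clinically
  reported preoperative ratios do go negative, so clipping or failing would
  lose information.
- **mFTA**: 180° minus the angle F–K–C1, where K is the plateau midpoint,
  signed by which side of the femoral mechanical axis the ankle falls
  (medial = varus = positive). The measure is stored signed and rendered as
  "varus x°" / "valgus x°" in reports.
- **mMPTA**: the medial angle ∠(medial edge)–K–C1.

K serves as the knee center for both the femoral and tibial mechanical axes.
A separate femoral-side knee center (e.g. the notch) is common in practice;
using one shared K keeps pre/post comparisons consistent and makes the
straight limb measure exactly (50 %, 0°, 90°). This is a documented modelling
choice, not a geometric necessity.

## The planning construction

The plan is a compass-and-straightedge construction; every length enters as
the radius of a drawn circle, which is why the residual identities are exact:

1. Target point O at `target_ratio` % of plateau width (default 50; 62.5
   = Fujisawa preset for over-correction strategies); target line L1 = F→O
   extended 80 mm past the ankle level.
2. Hinge H at `hinge_distal_offset` (default 15 mm) below the *lateral*
   plateau edge and `hinge_medial_offset` (default 8 mm) medial to the
   lateral cortex. The medial offset is applied **horizontally** (parallel to
   the x axis), matching on-screen calliper use; an offset normal to the
   local cortex tangent would differ by < cos error of the cortex slope
   (≲ 0.1 mm for anatomical slopes) and the published phrasing does not
   disambiguate.
3. Osteotomy site S: distal crossing of the circle (M, `osteotomy_radius`,
   default 40 mm) with the medial cortex polyline.
4. Ankle image I: distal crossing of the circle (H, |HC1|) with L1;
   θ = ∠C1-H-I. Distal-branch selection is explicit everywhere; the proximal
   branches are anatomically meaningless.
5. Chord endpoints P (ray H→C1) and G (ray H→I) at radius |HS|;
   gap = |PG| = 2 |HS| sin(θ/2); intraoperative opening = gap +
   `blade_thickness` (default 0.9 mm saw kerf).

**Closure** is the central invariant: because I lies on L1 and on the circle
about H through C1, rotating the distal segment about H by θ maps C1 onto I
exactly, so the postoperative WBL ratio equals the target to floating-point
precision (asserted at 1e-6 percentage points over the whole plannable varus
range).

Degenerate inputs: a limb already at the target produces a valid θ = 0 plan
flagged "no correction needed"; a limb whose WBL is lateral to the target is
rejected — a medial opening wedge only corrects varus. The boundary uses a
1e-9-percentage-point tolerance so exactly-at-target limbs plan rather than
fail. Openings above 15 mm get an informational "structural bone graft
recommended" note. Construction failures (cortex too short for the hinge,
osteotomy circle missing the cortex) raise `ConstructionError` naming the
failing step.

Parameter units are millimetres and percent. Scale equivariance (θ invariant,
gap ∝ k) and calibration/planning commutation hold when the length parameters
are expressed in the same unit as the coordinates and scaled with them; the
tests state it that way.

## Classification

Postoperative ratios are classified against `target ± halfwidth`
(default 50 ± 5 %). Boundary values classify as acceptable: the published
wording defines under/over as strictly exceeding the band.

## Synthetic limbs and the noise model

The generator emulates a standing whole-leg radiograph's frontal skeleton:
straight vertical femur, the whole deformity placed in the proximal tibia as
an MPTA deficit (the OWHTO indication), plateau horizontal. `tibia_length`
is the vertical extent of the tibial segment, so varus v puts the ankle at
x = `tibia_length`·tan v. Cortices are polylines parallel to the tibial
axis, inset `cortex_inset` (default 2 mm) from the plateau edges, with an
optional metaphyseal flare decaying exponentially (30 mm depth constant) and
a 10 mm proximal overshoot so that noise cannot strand a trace distal to the
plateau. Defaults — femur 420 mm, tibia 365 mm, plateau width 75 mm, varus
6.4° — are typical adult dimensions at the reported cohort's stature, with
the default varus at the cohort's mean preoperative deformity.

Landmark noise is iid isotropic Gaussian per landmark (σ default 1.5 mm, a
plausible observer digitization error); cortex polylines are perturbed
rigidly by a single offset so they never self-intersect. This emulates
observer placement error only: it has no radiographic magnification gradient,
no rotation/flexion malposition, no correlated edge-detection bias, and the
skeleton is 2D. Passing tests therefore demonstrate correctness of the
geometry and the error-propagation machinery, not clinical accuracy on real
radiographs.

The Monte-Carlo driver separates planning error (plan built on one noisy
copy) from measurement error (outcome read off a second noisy copy) with the
noiseless limb in between, mirroring how a planned-on radiograph and a
follow-up radiograph are two digitizations of one limb. One RNG substream
per replicate, keyed (seed, index), makes results independent of replicate
ordering and exactly reproducible; failed constructions are counted, never
dropped. In simulation the executed rotation is known exactly, so the
simulator reports θ directly rather than modelling a radiographic
wedge-angle measurement.

## Statistics

Paired *t*-tests are two-tailed on post − pre differences (scipy), α = 0.05;
an all-zero difference vector reports t = 0, p = 1, while a non-zero
constant difference is an error (t undefined). ICC forms follow convention
where the source of ratings does not pin them down: inter-rater = ICC(2,1)
(two-way random effects, absolute agreement, single measure), intra-rater
= ICC(3,1) (two-way mixed, consistency). Both are computed from the explicit
two-way ANOVA mean squares — this keeps perfect-agreement tables (residual
MS = 0) exactly at 1.0 — and are verified against `pingouin.intraclass_corr`
in the tests. Category boundaries 0.40 and 0.75 belong to "fair to good".
Cohort summaries print mean ± sd unconditionally (no normality screening)
and average nothing across observers; rating tables are passed in as given.
Classification percentages are rounded to one decimal.

## Problem sizes

The shipped tests and the acceptance script use 200 noiseless limbs for the
closure sweep, 500 replicates for noisy deformity recovery, 1000 random
plans for the chord identity, 100 random configurations against the numeric
root-finder oracle, and a 54-knee reconstructed cohort — sizes at which
every stochastic check is stable to well inside its asserted tolerance while
the whole suite runs in seconds.

## Known limitations

- 2D frontal plane only: no tibial slope (sagittal) planning, no 3D.
- No image processing: landmarks arrive digitized; DICOM is out of scope.
- The hinge's 8 mm offset direction and the shared knee center K are
  documented conventions (see above), not uniquely determined by the method's
  published description.
- The simulator models the osteotomy as an ideal rigid rotation about a
  point hinge: no hinge fracture, bone elasticity, or fixation loss.
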