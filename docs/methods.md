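# Methods

## Problem and scope

The package estimates seven anthropometric parameters — body height (BH),
arm span (AS), and arm/calf/hip/thigh/waist girths (AC, CC, HC, TC, WC), all
in meters — from a single full-body point cloud of a standing adult in
T-pose. Inputs are assumed axis-aligned in the canonical body frame
(`y` vertical with feet at `y = 0`, `z` sagittal with the subject facing
`+z`, `x` transversal); `canonicalize` only translates, it never rotates.
Device drivers, depth-map conversion, mesh reconstruction, pose estimation
and clothed or non-standard bodies are out of scope. Turntable captures with
known platform angles are merged by inverse rotation about the vertical
axis; fine registration is delegated to an optional user-supplied hook,
since it is standard point-cloud tooling rather than part of this method.

## Segmentation model

Segmentation assumes one connected standing figure with arms extended
laterally. It proceeds entirely through geometric landmarks:

1. **Hip point.** The point centroid's height approximates the hip level on
   a standing adult (legs below, torso/arms/head above roughly balance).
   Within `hip_band_halfwidth` (default 0.05 m) of the centroid height, the
   point with the smallest `z` — the rear-most buttock point — is `PH`;
   `PH.y` is the hip-girth plane and the upper/lower body divide. This
   requires the buttocks to be the posterior extremum of the band, true for
   typical adult anatomy and enforced in the synthetic generator by a
   posterior hip bulge.
2. **Lateral midline.** `xH` is the midpoint of the extreme `x` values in a
   band of half-height `thH` (default 0.02 m) around `PH.y`. It splits left
   from right; boundary ties go to the left side.
3. **Knees.** `knee_y = foot_y + (knee_height_frac / hip_height_frac) ·
   (hip_y − foot_y)` per leg. The default ratios (0.285 and 0.53 of stature)
   are standard adult segment proportions; they are calibration constants,
   not measured landmarks, and are exposed in `SegmentationConfig`.
4. **Upper-body outline.** The upper body is projected onto XY and its
   outline extracted as an alpha shape (Delaunay triangles with circumradius
   ≤ `concave_alpha` kept; boundary = edges on exactly one kept triangle;
   largest loop returned, oriented counter-clockwise). A concave outline is
   essential: the convex hull would bridge the armpits.
5. **Arm junctions.** Each side's outline arc (vertices with `x < xH` or
   `x > xH`) is resampled at uniform arc-length spacing `contour_step`
   (default 0.01 m) and walked from its lowest point. After skipping the
   initial horizontal hip-cut edge, the first unit step whose |x|-component
   exceeds `thdir` (default 0.5, i.e. a turn more than ~30° from vertical)
   marks the armpit (`PRAdown`/`PLAdown`). The walk continues out the arm
   and back; the first point re-entering `|x − x_armpit| ≤ eps_x` from above
   is the shoulder-top junction (`PRAup`/`PLAup`). If the outline never
   returns within `eps_x`, the closest-`x` point after the hand extreme is
   used and a warning logged; a candidate with lateral reach below
   `min_arm_extent` (default 0.05 m) is rejected, which is what makes
   armless shapes fail loudly instead of producing fake junctions.
6. **Labels.** Arms are the upper-body points lateral of their junction-down
   `x` (ties to the torso); the head is everything above
   `shoulder_y = max(PRAup.y, PLAup.y)`; the torso is split into upper and
   lower halves at the midpoint of its `y` extent (a geometric, not
   point-count, split). Legs split left/right at `xH` and thigh/lower-leg at
   the knee height. The assignment is a total partition: every point gets
   exactly one of the nine labels.

### Thresholds and proportions

All defaults assume adult-scale bodies sampled at millimeter-to-centimeter
point spacing:

| name | default | meaning |
|------|---------|---------|
| `thH` | 0.02 m | lateral-midline band half-height |
| `thdir` | 0.5 | lateral-turn threshold on unit contour steps |
| `thcut` | 0.01 m | slab half-thickness for girths |
| `hip_band_halfwidth` | 0.05 m | hip-search band around the centroid |
| `concave_alpha` | 0.02 m | alpha-shape characteristic length |
| `eps_x` | 0.01 m | junction up/down x-matching tolerance |
| `contour_step` | 0.01 m | outline resampling step |
| `min_arm_extent` | 0.05 m | minimum lateral reach of a real arm |
| `knee_height_frac` | 0.285 | knee height / stature |
| `hip_height_frac` | 0.53 | hip height / stature |
| `shoulder_height_frac` | 0.81 | shoulder height / stature |
| `waist_frac_of_torso` | 0.35 | waist above hip / hip-to-neck distance |
| `upperarm_frac_of_arm` | 0.56 | upper-arm / whole-arm length |
| `calf_search_band` | 0.3 | calf-bulge search band (fraction of leg span) |

`concave_alpha` trades off two errors: the alpha shape rounds concave
corners (the armpits) by up to ~alpha, pulling the detected junction below
the true corner, while an alpha below ~2× the point spacing fragments the
outline. 0.02 m keeps the junction error under ~2 cm at the densities this
package targets (≥ 15 000 points/m²); sparser scans need a larger value.
`contour_step` resampling exists because raw alpha-shape boundary vertices
jitter at the sampling scale, and a single near-vertical jitter step on the
horizontal hip edge would otherwise end the "skip the bottom edge" phase
early. All lengths scale together via `SegmentationConfig.scaled(s)`, which
is also the form in which scale equivariance of the landmarks holds exactly.

## Girth measurement

A girth site is a plane: `x = PAC` for arms (projection onto YZ), `y = c`
for torso/leg sites (projection onto XZ). Points within `thcut` of the plane
are projected and the perimeter of their convex hull is summed from the
ordered hull vertices, closing last-to-first. Site placement: arm girth
midway between armpit and elbow (elbow by the upper-arm fraction); waist at
`waist_frac_of_torso` of the hip-to-torso-top distance; hip at `PH.y`,
pooling lower-torso and thigh points because the plane is their boundary;
thigh at the segment's mid-height; calf at the height of the rear-most point
within the search band (the posterior bulge marks the maximum-circumference
level — a bulge-free leg yields a logged warning and a noise-driven height).
AC/TC/CC are computed for both sides; the right side is the headline value,
matching single-side manual measurement convention.

Two intrinsic biases follow from the convex hull and are left in place
deliberately rather than corrected: concave cross-sections are
overestimated (the hull is their convex envelope), and outward-pointing
noise inflates the hull because hull vertices are extreme points. With 2 mm
radial noise at default density this inflation is ~0.3% (arm, where the
noise direction is nearly parallel to the slab axis) to ~4% (calf, the
smallest horizontal-slab section). Degenerate slabs (< 3 points or
collinear) raise errors instead of returning zeros, so a bad segmentation
surfaces instead of biasing a cohort silently.

## Synthetic bodies and what they do (not) show

The generator assembles a T-pose figure from primitives with closed-form
cross-sections: elliptic cylinders for calves, thighs and arms; a torso
column tapering linearly hip → waist → chest; an ellipsoid head topping out
exactly at `stature`; flat caps at feet and hands making BH and AS exact.
Posterior Gaussian-profile offsets at the hip (1.5 cm) and calf (1.2 cm)
give the rear-most-point searches a unique, anatomically sensible argmin.
Every girth ground truth is an ellipse arc length, evaluated through the
complete elliptic integral of the second kind (machine precision; verified
against direct quadrature in the tests).

The default body (stature 1.802 m, arm span 1.84 m, girths AC 0.350,
CC 0.390, HC 1.059, TC 0.586, WC 0.888 m) matches the mean of the adult-male
population the package emulates; `sample_cohort` draws stature from a
truncated Normal(1.802, 0.065) m on [1.65, 2.00] and scales girth semi-axes
with stature plus per-subject (sd 6%) and per-site (sd 3%) factors. Surface
sampling density defaults to 50 000 points/m² (≈ 4.5 mm spacing, the order
of a merged consumer-depth-camera scan); the noise model displaces points
radially from the vertical body axis with Gaussian amplitude (default sigma
2 mm, the order of consumer time-of-flight ranging noise).

What passing on these bodies shows: the landmark logic, site placement,
hull perimeter and statistics are internally correct, and the pipeline is
robust to radial noise and population-scale shape variation. What it does
not show: performance on real bodies, whose cross-sections are not convex
ellipses (the waist/hip especially), whose pose deviates from ideal T-pose,
and whose scans contain occlusion holes, registration ghosting and clothing
— all outside the generator's scope.

## Statistics

`d = mean(DC − GS)`: the sign convention makes an underestimating estimator
negative. `Δ = 100·d / mean(GS)`. Bland-Altman: differences `DC − GS`
against pair means; `sd_diff` uses the n−1 denominator; `CR = 2·sd_diff`;
`CV = 100·sd_diff / mean of the pooled GS and DC values`; limits of
agreement `d ± 1.96·sd_diff`. Quartiles use linear interpolation. The
Mann-Whitney U test is applied unpaired and two-sided via the normal
approximation with tie and continuity corrections; with all pooled values
identical p = 1 is returned by convention. For 4-vs-4 samples the
approximation tracks exhaustive permutation enumeration to about 0.02
(worst near large p, where it is conservative); at n ≥ 50 per arm its
type-I error at alpha = 0.05 is calibrated within [0.03, 0.07]. Pearson r
requires ≥ 3 pairs and nonzero variance in both samples; degenerate inputs
raise instead of returning NaN.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: the default body
(~110 000 points) for recovery checks, clean and at sigma = 2 mm; 20 cohort
bodies for segmentation invariants (partition, nine non-empty segments,
mirror label swap, landmark scale equivariance); a 30-subject noisy cohort
processed end-to-end for the agreement report (|Δ| < 7% holds for BH, AS and
all five girths under these conditions); and 2000 replicates for test
calibration. These sizes were chosen so a full validation runs in minutes on
one core while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* Landmark heights inherit the proportion constants; atypical body
  proportions (or children) need re-calibration via `SegmentationConfig`.
* The hip-band search assumes the cloud centroid lies within
  `hip_band_halfwidth` of the true hip level; extreme limb poses violate it.
* Convex-hull girths systematically exceed tape measurements on concave
  sections and under noise; no smoothing or denoising is applied.
* The merge step trusts the platform angles; unmodeled subject sway between
  frames is not corrected unless a refinement hook is supplied.
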