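# anthroscan

Estimation of human anthropometric parameters from a single full-body 3D
point cloud, as captured by an inexpensive depth camera on a rotating
platform. Given a T-pose scan in meters (PLY, PCD or XYZ), the package
estimates seven parameters used in standard anthropometric assessment:

| symbol | parameter      | how it is estimated |
|--------|----------------|---------------------|
| BH     | body height    | vertical extent of the cloud |
| AS     | arm span       | transversal extent of the cloud |
| AC     | arm girth      | cross-section perimeter of the upper arm |
| CC     | calf girth     | perimeter at the calf's maximum circumference |
| HC     | hip girth      | perimeter at the hip plane |
| TC     | thigh girth    | perimeter at mid-thigh |
| WC     | waist girth    | perimeter at the waist plane |

It is aimed at researchers in sports science, ergonomics and clinical
anthropometry who want tape-measure-style body dimensions from depth-camera
scans without manual intervention, plus the method-agreement statistics
needed to validate such estimates against manual gold-standard measurement.

## Method

The scan lives in a canonical body frame: `y` vertical (feet at `y = 0`),
`z` sagittal (subject facing `+z`), `x` transversal.

**Segmentation.** The cloud is split into nine parts (head, upper/lower
torso, left/right arm, thigh and lower leg) from geometric landmarks: the
hip point `PH` is the rear-most point in a horizontal band around the
cloud's geometric center; its height is both the hip-girth plane and the
upper/lower body divide; the lateral midline `xH` is the midpoint of the
transversal extremes around the hip plane; knees follow standard body
proportions; and the arm junctions are found by walking the concave-hull
outline of the upper body's XY projection upward until a unit step vector
turns lateral (its |x|-component exceeds the threshold `thdir`).

**Girths.** Each girth is the perimeter of the convex hull of a thin slab of
points around the measurement plane, projected onto that plane:

```
L = Σₖ d(Pₖ, Pₖ₊₁),   Pₙ₊₁ = P₁
```

where `P₁ … Pₙ` are the ordered hull vertices and `d` the Euclidean
distance.

**Agreement statistics.** Gold-standard (GS) vs estimate (DC) comparisons
use the absolute difference `d = mean(DC − GS)`, relative difference
`Δ = 100·d / mean(GS)` (%), Pearson `r`, a two-sided Mann-Whitney U test,
and Bland-Altman quantities: `sd` of the paired differences, coefficient of
repeatability `CR = 2·sd`, coefficient of variance `CV = 100·sd / x̄GS+DC`
(pooled mean), and limits of agreement `d ± 1.96·sd`.

Because no public scan corpus accompanies the method, the package includes a
parametric synthetic T-pose body generator (elliptic-cylinder limbs and
torso, ellipsoid head, posterior hip/calf bulges, optional radial depth
noise) whose seven parameters are known in closed form, enabling end-to-end
validation.

## Worked example

```sh
python examples/01_generate_and_measure.py
```

```
generated 108439 surface points
parameter    truth [m]  estimate [m]    error
BH              1.8020        1.8020   -0.00%
AS              1.8400        1.8400    0.00%
AC              0.3500        0.3499   -0.01%
CC              0.3905        0.3908    0.09%
HC              1.0591        1.0596    0.05%
TC              0.5860        0.5860   -0.00%
WC              0.8881        0.8939    0.65%
```

Each row compares the analytic ground-truth value of the synthetic body with
the estimate recovered by the full pipeline; on a clean scan all seven
parameters are recovered to well under 1%. The other examples cover
segmentation inspection (`02`), turntable merging (`03`) and a cohort-level
agreement study (`04`).

The same pipeline is available from the shell:

```sh
anthroscan synth   -o body.ply --seed 0
anthroscan measure -i body.ply -o results.txt --labels-out labeled.ply
anthroscan evaluate -i paired_table.tsv -o report.tsv --ba-dir ba/
```

## Limitations

T-pose, minimally clothed, axis-aligned scans only; the convex hull
overestimates concave cross-sections (most visible at the waist); body
proportions and thresholds are calibration constants exposed in
`SegmentationConfig`, not universal values. See `docs/methods.md` for the
full model description and numerical choices.
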