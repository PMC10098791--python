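"""End-to-end agreement study on a small synthetic cohort.

Draws 8 subjects with realistic stature/girth variation, adds 2 mm depth
noise to each scan, runs the full pipeline, and compares the estimates (DC)
against the generator's analytic ground truth (GS) with the same statistics
used to validate depth-camera anthropometry against manual measurement:
absolute difference d, relative difference delta, Pearson r, coefficient of
repeatability CR = 2*sd(diff), and coefficient of variance
CV = 100*sd(diff)/pooled mean. Positive d here means the convex-hull girth
slightly overestimates the true cross-section perimeter under outward noise.
"""

import numpy as np

from anthroscan import (
    PairedMeasurements,
    add_depth_noise,
    evaluate_parameters,
    generate_body,
    measure_cloud,
    sample_cohort,
)

PARAMS = ("BH", "AS", "AC", "CC", "HC", "TC", "WC")

gs = {k: [] for k in PARAMS}
dc = {k: [] for k in PARAMS}
for params in sample_cohort(8, seed=11):
    cloud, gt = generate_body(params)
    noisy = add_depth_noise(cloud, 0.002, seed=params.seed + 1)
    measured, _ = measure_cloud(noisy)
    for k in PARAMS:
        gs[k].append(getattr(gt, k))
        dc[k].append(getattr(measured, k))

table = evaluate_parameters(
    {k: PairedMeasurements(np.array(gs[k]), np.array(dc[k])) for k in PARAMS}
)
cols = ["parameter", "gs_mean", "dc_mean", "d", "delta_pct", "r", "CR", "CV_pct", "p"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
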