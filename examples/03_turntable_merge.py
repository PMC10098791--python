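"""Merge two turntable half-scans into a full ring and measure its girth.

A depth camera sees only the surface facing it; on a rotating platform each
frame covers roughly half the silhouette. With the platform angles known,
the frames are rotated back and concatenated. The merged cylinder's girth,
measured by the slab/convex-hull method, matches the analytic circumference
2*pi*r.
"""

import numpy as np

from anthroscan import (
    GirthSite,
    PointCloud,
    TurntableCapture,
    girth_at_site,
    merge_turntable_scans,
)

rng = np.random.default_rng(0)
r, n = 0.10, 8000
theta = rng.uniform(-np.pi / 2, np.pi / 2, n)  # camera-facing half only
y = rng.uniform(0.0, 0.4, n)
half = PointCloud(np.c_[r * np.cos(theta), y, r * np.sin(theta)])

capture = TurntableCapture(frames=[half, half], angles_deg=[0.0, 180.0])
merged = merge_turntable_scans(capture)

girth = girth_at_site(merged, GirthSite("y", 0.2), thcut=0.02)
print(f"merged points : {len(merged)}")
print(f"measured girth: {girth:.4f} m")
print(f"expected 2*pi*r: {2 * np.pi * r:.4f} m")
print(f"relative error: {100 * (girth / (2 * np.pi * r) - 1):+.2f}%")
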