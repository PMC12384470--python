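"""The rank-weighted colocalization coefficient (RWC) on small inputs.

First a four-pixel toy pair computed by hand, then the red->green RWC of a
rendered cell across the degradation grid, showing the strictly decreasing
response and the directional asymmetry against the stable marker.
"""

import numpy as np

from ciliaquant import DegradationModel, coloc_image, render_cell, rwc, sample_cell

# Four pixels, perfectly anti-ranked channels: rank differences (3,1,1,3),
# Rmax 3, weights (0, 2/3, 2/3, 0), so RWC = (3+2)*(2/3)/10 = 1/3.
primary = np.array([[4.0, 3.0, 2.0, 1.0]])
secondary = np.array([[1.0, 2.0, 3.0, 4.0]])
print(f"toy RWC = {rwc(primary, secondary, 0.0, 0.0):.6f}  (exactly 1/3)")

spec = sample_cell(np.random.default_rng(3))
print("\ndelta   RWC red->green   RWC green->red")
for delta in (0.0, 0.25, 0.5, 0.75, 1.0):
    rng = np.random.default_rng(42)
    green, red, _, _ = render_cell(
        spec, DegradationModel(delta, noise_sd=0.0, background_level=150.0), rng)
    res = coloc_image(red, green)
    print(f" {delta:.2f}       {res.rwc_red_green:.3f}            "
          f"{res.rwc_green_red:.3f}")

print("\nThe red->green direction collapses as antibody signal leaves the")
print("cilium; the green->red direction, anchored on the stable axoneme")
print("marker, decays far more slowly — the asymmetry that makes the")
print("red->green coefficient the sensitive storage-quality readout.")
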