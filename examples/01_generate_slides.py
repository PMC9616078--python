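"""Generate a small multicenter synthetic slide dataset.

Each slide is an RGB image with a near-white background, a pink tissue
region, and (for dysplastic categories) lesion blobs whose texture encodes
the category.  A paletted PNG mask labels every pixel (0 background,
1 tissue, 2 LGD, 3 HGD, 4 IIN).
"""

import numpy as np

from gastrograph.synthetic import CenterStyle, generate_cohort

counts = {
    "ZS": {"NED": 2, "LGD": 1, "HGD": 1, "IIN": 1},
    "MH": {"NED": 1, "LGD": 1, "HGD": 1, "IIN": 1},
}
styles = {
    "ZS": CenterStyle(),                                   # reference staining
    "MH": CenterStyle(gain=(1.1, 0.95, 0.9), noise=2.0),   # warmer, noisier scanner
}

slides = generate_cohort(counts, styles, seed=0, width=512, height=512)

print(f"{'slide':<12} {'center':<7} {'label':<5} tissue%  lesion/tissue%")
for s in slides:
    tissue = (s.mask >= 1).mean() * 100
    lesion = 100 * (s.mask >= 2).sum() / max(1, (s.mask >= 1).sum())
    print(f"{s.slide_id:<12} {s.center:<7} {s.category:<5} {tissue:6.1f}  {lesion:6.1f}")

# The lesion/tissue percentage tracks each slide's requested
# lesion_area_fraction; NED slides have none by construction.
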