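"""Dataset preprocessing: bounding box, fixed-grid crop, histogram
matching and flip doubling."""

import numpy as np

from hipposeg import (PhantomConfig, compute_bounding_box, crop_to_box,
                      flip_double, generate_cohort, histogram_match)

cohort = generate_cohort(PhantomConfig(seed=2), 2, seed=2)
labels = [l for _, l in cohort]

box = compute_bounding_box(labels, margin=4)
print(f"union foreground box {box.min_corner} .. {box.max_corner} "
      f"(margin 4, clipped to the grid)")

target = (48, 48, 48)
cropped = [(crop_to_box(v, box, target), crop_to_box(l, box, target))
           for v, l in cohort]
print(f"all subjects cropped/padded to {cropped[0][0].shape}")

ref = cropped[0][0]
matched = histogram_match(cropped[1][0], ref)
q = np.linspace(0.1, 0.9, 5)
print("t1w quantiles  ref:", np.round(np.quantile(ref.data[0], q), 2))
print("           matched:", np.round(np.quantile(matched.data[0], q), 2))
# After matching, the second subject's intensity distribution tracks the
# reference subject's quantile for quantile.

doubled = flip_double(cropped)
print(f"{len(cropped)} subjects -> {len(doubled)} after left-right mirroring")
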