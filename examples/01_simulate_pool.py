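"""Simulate a small pool of synthetic FLIM tissue sections.

Builds a desk-scale study pool (10 normal / 8 CIN1 / 6 CIN2 / 8 CIN3
sections at 48x48 px, 48 time bins) and prints, per class, the ground-truth
whole-epithelium mean lifetime.  Normal sections should sit near 850 ps and
CIN sections progressively lower -- the contrast every later stage builds on.
"""

import numpy as np

import epiflim as ef

config = ef.reduced_config(48, 48)
pool = ef.generate_pool(config, seed=1, render=False)

print(f"pool: {len(pool)} samples, image {config.image_size} px, "
      f"pixel {config.pixel_size:.1f} um, bin {config.bin_width:.0f} ps")
for label in ef.PATHOLOGY_CLASSES:
    means = [np.nanmean(s.true_tau2_map) for s in pool if s.label == label]
    print(f"  {label:>6}: n={len(means):2d}  whole-ROI tau2 = "
          f"{np.mean(means):5.0f} +/- {np.std(means):3.0f} ps")
print("Lower mean lifetime with increasing CIN grade reflects the "
      "loss of cellular maturation that the classifier exploits.")
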