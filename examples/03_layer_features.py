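"""Stratify an epithelium into 10 layers and extract per-layer statistics.

Shows the depth profile of the diagnostic lifetime tau2: in a normal
section the per-layer mean rises from the basal layer (1) to the
superficial layer (10); in a CIN3 section the top half is shortened and
nearly flat.
"""

import numpy as np

import epiflim as ef

config = ef.reduced_config(64, 64, sample_rsd=0.0)  # profile without sample noise

for label in ("normal", "CIN3"):
    sample = ef.generate_sample(label, config, np.random.default_rng(2))
    image = ef.fit_image(sample.decay_cube, config.bin_width,
                         threshold=config.photon_threshold)
    layer_map = ef.assign_layers(sample.geometry, image.tau2_map.shape, 10)
    feats = ef.layer_statistics(image, layer_map)
    print(f"{label}: per-layer mean tau2 (ps), basal -> superficial")
    print("  " + "  ".join(f"{m:4.0f}" for m in feats.mu))
print("The normal ramp tracks cellular maturation toward the surface; "
      "its absence in the CIN3 top half is the diagnostic signature.")
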