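"""Fit one synthetic decay cube to a tau2 lifetime image.

Simulates a single normal section, estimates the instrument response from
the pooled rising edge, fits the IRF-convolved bi-exponential model at
every above-threshold pixel, and compares the recovered lifetime map with
the ground truth.  Median recovery error should be a few percent and the
reduced chi-square close to 1.
"""

import numpy as np

import epiflim as ef

config = ef.reduced_config(64, 64)
sample = ef.generate_sample("normal", config, np.random.default_rng(1))

image = ef.fit_image(
    sample.decay_cube,
    bin_width=config.bin_width,
    threshold=config.photon_threshold,
    pixel_size=config.pixel_size,
)

inside = image.valid_mask & sample.roi_mask
err = (image.tau2_map[inside] - sample.true_tau2_map[inside]) / sample.true_tau2_map[inside]
chi2 = image.extras["chi2"][inside]
print(f"fitted {int(image.valid_mask.sum())} of {image.tau2_map.size} pixels "
      f"(photon threshold {config.photon_threshold})")
print(f"median |tau2 error|: {100 * np.median(np.abs(err)):.1f} %")
print(f"median reduced chi-square: {np.median(chi2):.2f}")
print("Values near a few percent and chi2 ~ 1 mean the per-pixel NLLS "
      "recovers the diagnostic lifetime component faithfully.")
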