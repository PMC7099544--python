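"""Demonstrate the high-pass character of the ICF in k-space.

The ICF behaves as a high-pass filter when the diagonal gradients prevail
over the pixel intensity.  This script drives the sphere phantom into that
regime, classifies each pixel's regime, and compares the fraction of
spectral energy in the central low-frequency band before and after
filtering: a high-pass output holds less of its energy near DC.
"""

import numpy as np

from icfilt import (
    GRADIENT_LIKE,
    SyntheticSpec,
    classify_image,
    compute_icf_image,
    generate,
    gradient_dominant_variant,
    low_frequency_energy_fraction,
    traditional_hpf,
)

sphere = generate(SyntheticSpec("sphere", size=(64, 64)))
gd = gradient_dominant_variant(sphere, gain=100.0)

result = compute_icf_image(gd)
labels = classify_image(gd, factor=10.0)
nd = ~result.degenerate_mask
frac_gradient = np.mean(labels[nd] == GRADIENT_LIKE)
print(f"gradient-like pixels among {nd.sum()} non-degenerate: {frac_gradient:.1%}")

f_orig = low_frequency_energy_fraction(gd)
f_icf = low_frequency_energy_fraction(result.deltaE_map)
f_hpf = low_frequency_energy_fraction(traditional_hpf(gd))
print(f"low-frequency energy fraction (central 1/8 band, DC included):")
print(f"  input image:        {f_orig:.4f}")
print(f"  ICF map:            {f_icf:.4f}")
print(f"  convolutional HPF:  {f_hpf:.6f}")
print("Both filters push spectral energy out of the low-frequency band; the")
print("convolutional kernel does so more aggressively, matching its sharper look.")
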