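"""Histogram + Gaussian-curve summary of a filtered image.

For the ICF map of the sphere phantom, computes the histogram, the sample
mean and population standard deviation, and the summary curve value at each
bin centre — in both the published normalisation (sigma inside the square
root) and the standard Gaussian density, plus the cumulative alternative.
"""

from icfilt import SyntheticSpec, compute_icf_image, generate, summarize_image

image = generate(SyntheticSpec("sphere", size=(64, 64)))
icf = compute_icf_image(image).deltaE_map

for fidelity in ("printed", "standard"):
    s = summarize_image(icf, n_bins=64, fidelity=fidelity)
    peak = s.values.max()
    print(f"{fidelity:8s} density: mu={s.mu:.4f} sigma={s.sigma:.4f} "
          f"peak f-value={peak:.5f}")

s_cdf = summarize_image(icf, n_bins=64, curve="cdf")
print(f"cumulative curve rises from {s_cdf.values[0]:.4f} to {s_cdf.values[-1]:.4f}")
print("A narrow ICF histogram (small sigma) gives a tall summary curve; the two")
print("normalisations differ by the factor sqrt(sigma)/sigma.")
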