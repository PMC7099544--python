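# icfilt

High-pass filtering of 2D grayscale images through the **intensity-curvature
functional (ICF)** of a bivariate cubic B-spline pixel model, with the
comparison filters and k-space evaluation tooling needed to study it.

## The problem and the idea

A conventional digital high-pass filter (HPF) is defined through image
gradients. When a model polynomial is fitted to an image pixel-by-pixel,
however, the intensity value usually dwarfs the gradient terms, so the fit
alone does not behave like an HPF. The ICF approach recasts high-pass design
as a resampling problem: replace the pixel intensity with the product of the
intensity and the *classic curvature* of the fitted model (the sum of its
four second-order partial derivatives), and take the ratio of that quantity
before and after interpolation.

At each pixel with intensity f(0,0) and diagonal neighbours at (±1/2, ±1/2),
the cubic B-spline model is

    h4(x, y) = f(0,0) + α3·[(1/2)s³ − s² + 2/3] + α2·[−(1/6)s³ + s² − 2s + 4/3],
    s = x + y,   α2 = f(0,0) − f(+1/2,+1/2),   α3 = f(0,0) − f(−1/2,−1/2).

The two intensity-curvature terms are the pixel-domain integrals

    E0(x,y)  = ∬ f(0,0)·{curvature at (0,0)} du dv = 4xy·f(0,0)·(−2α3 + 2α2),
    EIN(x,y) = ∬ 4·h4(u,v)·{α3[3(u+v)−2] + α2[2−(u+v)]} du dv,

and the ICF is their ratio ΔE = E0/EIN. Treating f(0,0) as the filter input
x[n] and ΔE as the output y[n] gives the transfer function TF = ΔE/f(0,0)
and closed-form input/output equations built from polynomial blocks
e1…e12, ω. Writing ΔE = f·ζ/(f·γ + λ) exposes when the ICF is *image-like*
(intensity prevails) versus *gradient-like* (the α-driven terms prevail —
the high-pass regime).

The package provides:

- `model_core` — the spline model, its derivatives, per-pixel coefficients;
- `icf_engine` — E0/EIN/ΔE/TF maps, the filter input/output equations, the
  e-term blocks, and the image-like/gradient-like/indeterminate classifier;
- `reference_filters` — a traditional zero-sum convolutional HPF and a
  per-pixel particle-swarm (PSO) HPF;
- `spectral` — k-space magnitude, inverse-Fourier reconstruction through a
  filter map, difference maps, low-frequency energy fractions;
- `synthetic_data` — spherical/toroidal/elliptical light sources, an
  MRI-like vessel phantom, elementary patterns, and a gradient-dominant
  variant;
- `stats_report` — histogram + Gaussian-curve summaries;
- `io` / `cli` — image readers/writers, the end-to-end comparison pipeline
  with a hashed manifest, and an `icfilt` command-line tool
  (`synth`, `filter`, `kspace`, `reconstruct`, `compare`, `stats`).

## Worked example

```python
from icfilt import SyntheticSpec, compute_icf_image, generate

image = generate(SyntheticSpec("sphere", size=(64, 64)))
result = compute_icf_image(image)
```

Running `python examples/icf_of_phantom.py` prints:

```
phantom: 64x64 spherical light source, intensity 0..255
non-degenerate pixels: 2056 / 4096
E0  (before interpolation): [-73127.773, 73127.773]
EIN (after interpolation):  [-2934.370, 21355.184]
ICF dE = E0/EIN:            [-811.198, 442.498]
TF  = dE/f(0,0):            [-36.94097, 12.38771]
mean |dE| over active pixels: 17.1594
```

The 2056 active pixels are those whose neighbourhood carries curvature; on
the flat background the ICF is degenerate and set to zero, the expected null
response of a high-pass filter to constant input. `examples/` contains one
script per capability (filter identities, k-space high-pass demonstration,
PSO convergence, full pipeline, histogram summaries); each prints the
numbers it computes and what they mean. For instance
`python examples/kspace_highpass.py` shows the operational high-pass
statement: on a gradient-dominant phantom the central low-frequency band
holds 34.4% of the input's spectral energy but only 1.4% of the ICF map's
and 0.002% of the convolutional HPF's.

The same pipeline is available from the shell:

```sh
icfilt synth sphere phantom.tif --size 64
icfilt filter phantom.tif icf.tif --method icf
icfilt kspace icf.tif icf_k.tif
icfilt compare out/ --shape sphere --filters icf,traditional,pso
```

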