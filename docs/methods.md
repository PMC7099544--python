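# Methods

This note documents the models implemented in `icfilt`, the numerical and
design choices behind them, what the synthetic data does and does not
emulate, and the known limitations.

## The pixel model and the intensity-curvature terms

Each pixel is modelled by a bivariate cubic B-spline polynomial
h4(x, y) = f(0,0) + α3·A(s) + α2·B(s) with s = x + y, where
A(s) = s³/2 − s² + 2/3 and B(s) = −s³/6 + s² − 2s + 4/3, and
α2 = f(0,0) − f(+1/2,+1/2), α3 = f(0,0) − f(−1/2,−1/2) are diagonal
intensity differences. Because h4 depends on (x, y) only through s, its two
first partials coincide, as do all four second partials; the classic
curvature at the origin is −2α3 + 2α2 and must be non-null for the ICF to
exist at a pixel.

The intensity-curvature term before interpolation, E0, integrates
f(0,0) times the origin curvature over [0,x]×[0,y] (the integrand is
constant, so E0 = 4xy·f(0,0)(−2α3+2α2)); the term after interpolation, EIN,
integrates 4·h4·(sum of second partials) over the same domain. Indefinite
integrals in the source formulation are read as definite integrals from the
pixel origin with zero integration constant, which matches the printed
monomial antiderivatives. The ICF is ΔE = E0/EIN and the transfer function
TF = ΔE/f(0,0).

### Canonical vs printed closed forms

The published expansion of EIN and its component equations carry three
typographical slips, which we verified by symbolically integrating the
defining integral (sympy) and independently by adaptive 2D quadrature
(scipy.integrate.dblquad):

1. the quartic α-bracket ends in α2²/6, not α3²/6;
2. the cubic α-bracket's cross-coefficient is 16/3 (2 + 10/3), with 10/3
   arising from −s³/6·(3s) and s²·3s, not the printed 2 + 4/3;
3. the quartic monomial bracket's last term is +xy⁴/4, not −xy⁴/4.

`fidelity="canonical"` (default) implements the exact antiderivative;
`fidelity="printed"` reproduces the published component equations verbatim
for comparison. The ω block is assembled as 4·(e3·e4 + e5·e6 + e7·e8 +
e9·e10 + e11) — the pairing the full expansion requires — in both modes.

### Evaluation point

ΔE(x, y) is a polynomial ratio per pixel; producing one number per pixel
requires choosing an intra-pixel evaluation point. The default is
(x, y) = (1, 1): it spans unit pixel area, keeps e1 = e2 = 1 and all
monomials O(1), and makes the filter identities exact — the output equation
y[n] = x[n]e12 / [4(x[n]α3e1 + x[n]α2e2) + ω] equals ΔE at x[n] = f(0,0)
precisely when x·y = 1, because the e12 block omits the 4xy factor present
in E0. The same condition makes the decomposition
ΔE = f·ζ/(f·γ + λ), ζ = e12, γ = 4(α3e1 + α2e2), λ = ω, exact. Other
evaluation points are supported for the maps themselves.

### Neighbour sampling and boundaries

Half-pixel diagonal samples are taken from the nearest diagonal pixels by
default (`neighbor_mode="diagonal"`): f(+1/2,+1/2) → image[r+1, c+1]. A
`bilinear` mode interpolates at the true half-pixel offsets (mean of the
2×2 block). Diagonal differencing reproduces the gradient-like behaviour the
method relies on without resampling. Boundaries use one pixel of mirror
(reflect) padding, so flat borders yield zero coefficients. Of the eight
neighbours the model nominally lists, only the two at (±1/2, ±1/2) enter any
equation; the others are not sampled.

### Degenerate pixels

Pixels with |EIN| below tolerance (default 1e−12 × intensity range², since
EIN scales quadratically with intensity) have no curvature signal; ΔE is set
to 0 there and the pixel flagged, as is TF where |f(0,0)| is below
tolerance. Consequently ΔE is invariant under global intensity scaling at
non-degenerate pixels, and no NaN/Inf ever reaches an output map.

## Behaviour classification

ΔE = f·ζ/(f·γ + λ) is *image-like* where the intensity prevails over all
three α-driven components, and *gradient-like* (the high-pass regime) where
the α-components prevail. "Largely" smaller/bigger is |a| ≤ |b|/factor and
|a| ≥ factor·|b| on absolute values, with factor 10 by default (no threshold
is prescribed by the theory; 10 is one order of magnitude). The implemented
rules: image-like when ζ, γ, λ are all largely smaller than f(0,0), or when
ζ and γ largely exceed it while λ is largely smaller (ΔE then collapses to
the intensity-free ratio ζ/γ); gradient-like when ζ and γ both largely
exceed f(0,0) and λ is not largely smaller, or when all three comparisons
are determinate in any other pattern; indeterminate otherwise. Two exact
zeros compare as neither.

## Comparison filters

**Traditional HPF.** 3×3 zero-sum sharpening Laplacian (centre 8,
neighbours −1), mirror boundary, via scipy.ndimage. Any odd, zero-sum kernel
may be supplied. Its transfer-function map uses the same degenerate handling
as the ICF.

**PSO HPF.** One scalar swarm per pixel, vectorised over all pixels.
Particle positions are initialised as uniform draws rescaled so their sum
equals the pixel intensity (exactly); velocities — the high-pass candidates —
are initialised uniformly over ±(image intensity range) so the candidates
cover the attainable response scale. Updates follow the standard additive
rule: v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x), x ← x + v, with
w = 0.729, c1 = c2 = 1.494 (constriction-style defaults). The cost is the
squared difference between a particle's velocity and the target high-pass
response at that pixel; the target defaults to the traditional HPF output
but any map may be supplied. The output pixel is the globally best velocity
at termination. A fixed iteration budget (default 200) with optional early
stop (mean global-best improvement < tolerance over 10 iterations) bounds
the run; one seeded generator drives all draws, so runs are bit-reproducible.
Recorded cost history is the swarm-mean of per-pixel global-best costs,
which is non-increasing by construction. Premature convergence to the target
is possible and expected of this optimizer class; the filter is studied as a
baseline, not tuned for quality.

## Spectral analysis

Forward DFT unnormalised, inverse with 1/N² (numpy convention); DC shifted
to the grid centre. Magnitude is exported raw for analysis and as
log(1+magnitude) for display. "Reconstruction through" a filter map treats
the (real) map as centred k-space data and returns the modulus of its
inverse transform by default (`real_part` optional; which the original
figures used is not recoverable). The operational high-pass statement is
measured as the fraction of spectral energy in the central 1/8 × 1/8 band of
bins (DC included): a high-pass output holds strictly less than its input.

## Synthetic data

The generators emulate the study's theoretical inputs: a spherical light
source (hemispheric profile amplitude·sqrt(1 − (r/R)²)), a light torus
(Gaussian ring), an elliptical light (anisotropic hemisphere), and an
MRI-like vessel phantom (smooth tissue background plus bright, anti-aliased
sinusoidal tracks) standing in for brain-vasculature scans, plus impulse,
ramp and constant patterns for edge cases. Defaults are 128×128, amplitude
255, noise-free; optional zero-mean Gaussian noise is seeded and intensities
are clipped to [0, amplitude]. The exact parametric forms of the original
"calculated" light images are not published; these are qualitative
stand-ins, so tests demonstrate the method's mathematical contracts and
spectral behaviour, not equivalence with the original image set. Real MRI
features absent here: acquisition noise statistics (Rician), coil
inhomogeneity, anatomy-scale texture, partial-volume effects.

`gradient_dominant_variant` drives an image into the gradient-like regime by
amplifying every third row by (1 + gain), gain 100 by default. On the
unmodulated rows the diagonal neighbours then exceed the local intensity by
roughly the gain factor. No affine rescale/offset can do this: offsets
cancel in the differences and the ICF is scale-invariant. Constant images
are returned unchanged — gradients cannot be conjured from a flat field.

## Histogram summaries

Histograms span [min, max] with 256 bins by default; the mean uses the pixel
sample and the standard deviation the population convention (ddof = 0). The
summary curve at each bin centre is computed, by default, with the published
normalisation 1/√(2πσ) — σ inside the radical — for fidelity
(`fidelity="printed"`); `"standard"` gives the usual density 1/(σ√(2π)). The
source text is ambiguous between a density and a cumulative quantity, so a
`curve="cdf"` option provides the Gaussian CDF; outputs label which was
used. Constant images (σ = 0) are flagged and carry no curve values.

## Problem sizes and verification

Tests and the acceptance script use 64×64 phantoms for map-level identities,
16×16 for the swarm filter (30 particles, 200 iterations) and 100 randomized
coefficient draws for the integration oracles — sizes at which every
quantity is computed in seconds while leaving thousands of active pixels per
identity check. Oracles are independent of the code paths they check:
adaptive quadrature and sympy integration for the closed forms, central
finite differences for derivatives (step 1e−5 for first derivatives; 1e−3
for second differences, which are truncation-free on cubics), scalar loops
for vectorised maps, and Parseval/Hermitian identities for the spectra.

## Known limitations

- The ICF is unbounded and signed near EIN zero crossings; display exports
  min-max normalise, and analysis should use the raw maps with the
  degenerate mask.
- The published evaluation point, display scaling, and the exact PSO cost/
  target are not recoverable; the choices here are documented defaults, not
  claims about the original implementation.
- The filter identities are exact only for evaluation points with x·y = 1
  (see above).
- Per-pixel PSO is a baseline comparator: it approximates whatever target it
  is given and cannot outperform it.
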