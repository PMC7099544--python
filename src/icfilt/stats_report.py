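"""Histogram-based Gaussian summaries of filtered images and k-space maps.

For each image the histogram, the sample mean mu and the population standard
deviation sigma are computed, and the curve value f(x, mu, sigma) is
evaluated at every bin centre.  Two fidelity conventions exist for the
normalisation: ``"printed"`` keeps sigma inside the square root,
1/sqrt(2*pi*sigma) (as published), while ``"standard"`` is the usual Gaussian
density 1/(sigma*sqrt(2*pi)).  A ``curve="cdf"`` option evaluates the
Gaussian cumulative distribution instead of the density.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _st

__all__ = ["DistributionSummary", "gaussian_value", "summarize_image", "write_summary_csv"]


@dataclass(frozen=True)
class DistributionSummary:
    """Histogram + Gaussian-curve summary of one image.

    ``flagged`` marks constant images (sigma = 0), for which curve values are
    omitted.
    """

    mu: float
    sigma: float
    n_bins: int
    bin_centers: np.ndarray
    counts: np.ndarray
    values: Optional[np.ndarray]
    curve: str = "density"
    fidelity: str = "printed"
    flagged: bool = False


def gaussian_value(
    x, mu: float, sigma: float, fidelity: str = "printed", curve: str = "density"
):
    """Evaluate f(x, mu, sigma) for the summary curve.

    ``fidelity="printed"`` uses the normalisation 1/sqrt(2*pi*sigma) with
    sigma inside the radical; ``"standard"`` uses 1/(sigma*sqrt(2*pi)).
    ``curve="cdf"`` returns the Gaussian cumulative distribution instead.
    Requires sigma > 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    if curve == "cdf":
        out = _st.norm.cdf(x, loc=mu, scale=sigma)
    elif curve == "density":
        expo = np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
        if fidelity == "printed":
            out = expo / np.sqrt(2.0 * np.pi * sigma)
        elif fidelity == "standard":
            out = expo / (sigma * np.sqrt(2.0 * np.pi))
        else:
            raise ValueError(f"unknown fidelity: {fidelity!r}")
    else:
        raise ValueError(f"unknown curve: {curve!r}")
    return float(out) if out.ndim == 0 else out


def summarize_image(
    image: np.ndarray,
    n_bins: int = 256,
    fidelity: str = "printed",
    curve: str = "density",
) -> DistributionSummary:
    """Histogram an image over [min, max] and attach the Gaussian curve values.

    mu and sigma come from the pixel sample (population convention for
    sigma).  Constant images have sigma = 0 and are returned flagged with
    ``values=None``.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pixels = image.ravel()
    mu = float(pixels.mean())
    sigma = float(pixels.std())  # population (ddof=0)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        hi = lo + 1.0
        counts, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        return DistributionSummary(
            mu, 0.0, n_bins, centers, counts, None, curve, fidelity, flagged=True
        )
    counts, edges = np.histogram(pixels, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = gaussian_value(centers, mu, sigma, fidelity=fidelity, curve=curve)
    return DistributionSummary(mu, sigma, n_bins, centers, counts, values, curve, fidelity)


def write_summary_csv(summary: DistributionSummary, path) -> None:
    """Export one row per bin (bin_center, count, f_value) plus a trailing
    summary row (mu, sigma, n, mode flags)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_center", "count", "f_value"])
        values = summary.values
        for i in range(summary.n_bins):
            fval = "" if values is None else repr(float(values[i]))
            writer.writerow([repr(float(summary.bin_centers[i])), int(summary.counts[i]), fval])
        writer.writerow(["#summary", "", ""])
        writer.writerow(["mu", repr(summary.mu), ""])
        writer.writerow(["sigma", repr(summary.sigma), ""])
        writer.writerow(["n_bins", summary.n_bins, ""])
        writer.writerow(["curve", summary.curve, ""])
        writer.writerow(["fidelity", summary.fidelity, ""])
        writer.writerow(["flagged", int(summary.flagged), ""])
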