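"""k-space (2D Fourier) analysis of images and filter maps.

Conventions: forward DFT unnormalised, inverse carries the 1/N^2 factor
(numpy's default); the DC bin is shifted to the grid centre for display and
band analysis.  Filter maps are treated as real-valued k-space data when
"reconstructing through" a filter: the map is unshifted, inverse-transformed
and the modulus (or, optionally, the real part) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumGrid",
    "kspace_magnitude",
    "reconstruct",
    "difference_map",
    "low_frequency_energy_fraction",
]


@dataclass(frozen=True)
class SpectrumGrid:
    """Centred complex spectrum of an image with magnitude and
    log(1 + magnitude) companions (the latter for display)."""

    complex_spectrum: np.ndarray
    magnitude: np.ndarray
    log_magnitude: np.ndarray


def kspace_magnitude(image: np.ndarray) -> SpectrumGrid:
    """2D DFT of an image with the DC bin shifted to the centre."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    spec = np.fft.fftshift(np.fft.fft2(image))
    mag = np.abs(spec)
    return SpectrumGrid(spec, mag, np.log1p(mag))


def reconstruct(filter_image: np.ndarray, mode: str = "modulus") -> np.ndarray:
    """Treat a (real) filter map as centred k-space data and invert it.

    The map is unshifted, inverse-transformed, and returned as modulus
    (default) or real part.  Complex input is accepted, in which case the
    round trip with :func:`kspace_magnitude` is exact.
    """
    arr = np.asarray(filter_image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2D grid")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input must be finite")
    rec = np.fft.ifft2(np.fft.ifftshift(arr))
    if mode == "modulus":
        return np.abs(rec)
    if mode == "real_part":
        return rec.real
    raise ValueError(f"unknown reconstruct mode: {mode!r}")


def difference_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise difference a - b (shapes must match)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return a - b


def low_frequency_energy_fraction(
    image: np.ndarray, band_fraction: float = 1.0 / 8.0
) -> float:
    """Fraction of spectral energy inside the centred low-frequency band.

    The band is the central ``band_fraction`` of bins per axis (at least one
    bin, DC included).  A high-pass signal concentrates energy outside this
    band, so smaller values mean stronger high-pass character.
    """
    if not 0 < band_fraction <= 1:
        raise ValueError("band_fraction must lie in (0, 1]")
    grid = kspace_magnitude(image)
    energy = grid.magnitude**2
    total = energy.sum()
    if total == 0:
        raise ValueError("image has no spectral energy")
    n_r, n_c = energy.shape
    h_r = max(1, int(round(n_r * band_fraction))) // 2
    h_c = max(1, int(round(n_c * band_fraction))) // 2
    c_r, c_c = n_r // 2, n_c // 2
    band = energy[c_r - h_r: c_r + h_r + 1, c_c - h_c: c_c + h_c + 1]
    return float(band.sum() / total)
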