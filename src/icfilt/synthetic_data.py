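"""Synthetic test images: the three theoretical light sources (spherical,
toroidal, elliptical), an MRI-like vessel phantom, and elementary patterns.

These stand in for acquired scans so every stage of the pipeline is testable
without external data.  All generators are pure functions of the spec and
its seed.  Default images are 128x128 with amplitude 255 and no noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = ["SyntheticSpec", "generate", "gradient_dominant_variant", "PRESETS"]

SHAPES = ("sphere", "torus", "ellipse", "vessel_phantom", "impulse", "ramp", "constant")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic image.

    ``geometry`` carries shape-specific parameters (fractions of the grid
    size unless noted): sphere/ellipse ``radius`` or ``(radius_r, radius_c)``;
    torus ``ring_radius`` and ``ring_width``; vessel phantom ``n_vessels``
    and ``vessel_width`` (pixels).
    """

    shape_kind: str
    size: tuple = (128, 128)
    amplitude: float = 255.0
    geometry: Dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPES:
            raise ValueError(f"unknown shape_kind: {self.shape_kind!r}")
        if min(self.size) < 8:
            raise ValueError("size must be at least 8x8")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for key in ("radius", "radius_r", "radius_c", "ring_radius", "ring_width"):
            if self.geometry.get(key, 1.0) <= 0:
                raise ValueError(f"geometry[{key!r}] must be positive")


def _centered_grid(size) -> tuple:
    rows, cols = size
    r = np.arange(rows) - (rows - 1) / 2.0
    c = np.arange(cols) - (cols - 1) / 2.0
    return np.meshgrid(r, c, indexing="ij")

def _sphere(spec: SyntheticSpec) -> np.ndarray:
    rr, cc = _centered_grid(spec.size)
    radius = spec.geometry.get("radius", 0.4) * min(spec.size)
    rho2 = (rr**2 + cc**2) / radius**2
    return spec.amplitude * np.sqrt(np.clip(1.0 - rho2, 0.0, None))


def _ellipse(spec: SyntheticSpec) -> np.ndarray:
    rr, cc = _centered_grid(spec.size)
    rad_r = spec.geometry.get("radius_r", 0.25) * spec.size[0]
    rad_c = spec.geometry.get("radius_c", 0.45) * spec.size[1]
    rho2 = (rr / rad_r) ** 2 + (cc / rad_c) ** 2
    return spec.amplitude * np.sqrt(np.clip(1.0 - rho2, 0.0, None))


def _torus(spec: SyntheticSpec) -> np.ndarray:
    rr, cc = _centered_grid(spec.size)
    ring = spec.geometry.get("ring_radius", 0.3) * min(spec.size)
    width = spec.geometry.get("ring_width", 0.06) * min(spec.size)
    r = np.hypot(rr, cc)
    return spec.amplitude * np.exp(-((r - ring) ** 2) / (2.0 * width**2))


def _vessel_phantom(spec: SyntheticSpec) -> np.ndarray:
    """Smooth tissue-like background plus bright curvilinear tracks."""
    rows, cols = spec.size
    rr, cc = _centered_grid(spec.size)
    radius = 0.48 * min(spec.size)
    background = 0.35 * spec.amplitude * np.sqrt(
        np.clip(1.0 - (rr**2 + cc**2) / radius**2, 0.0, None)
    )
    n_vessels = int(spec.geometry.get("n_vessels", 4))
    width = float(spec.geometry.get("vessel_width", 1.5))
    rng = np.random.default_rng(spec.seed)
    col_idx = np.arange(cols)
    img = background
    for k in range(n_vessels):
        base = rng.uniform(0.15, 0.85) * rows
        amp = rng.uniform(0.05, 0.18) * rows
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(1.0, 2.5)
        center = base + amp * np.sin(2 * np.pi * freq * col_idx / cols + phase)
        dist = np.abs(np.arange(rows)[:, None] - center[None, :])
        track = np.exp(-(dist**2) / (2.0 * width**2))  # anti-aliased profile
        img = img + 0.65 * spec.amplitude * track
    return np.clip(img, 0.0, spec.amplitude)


def _impulse(spec: SyntheticSpec) -> np.ndarray:
    img = np.zeros(spec.size)
    img[spec.size[0] // 2, spec.size[1] // 2] = spec.amplitude
    return img


def _ramp(spec: SyntheticSpec) -> np.ndarray:
    rows, cols = spec.size
    ramp = np.add.outer(np.arange(rows), np.arange(cols)).astype(float)
    return spec.amplitude * ramp / ramp.max()


def _constant(spec: SyntheticSpec) -> np.ndarray:
    return np.full(spec.size, spec.amplitude)


_BUILDERS = {
    "sphere": _sphere,
    "ellipse": _ellipse,
    "torus": _torus,
    "vessel_phantom": _vessel_phantom,
    "impulse": _impulse,
    "ramp": _ramp,
    "constant": _constant,
}


def generate(spec: SyntheticSpec) -> np.ndarray:
    """Render a synthetic image from its spec (deterministic given the seed).

    Optional zero-mean Gaussian noise with ``noise_sigma`` is added after
    rendering; intensities are then clipped to [0, amplitude].
    """
    img = _BUILDERS[spec.shape_kind](spec)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, spec.amplitude)


#: Ready-made specs covering the pipeline's test conditions.
PRESETS: Dict[str, SyntheticSpec] = {
    "sphere": SyntheticSpec("sphere"),
    "torus": SyntheticSpec("torus"),
    "ellipse": SyntheticSpec("ellipse"),
    "vessel_phantom": SyntheticSpec("vessel_phantom"),
    "impulse": SyntheticSpec("impulse"),
    "ramp": SyntheticSpec("ramp"),
    "constant": SyntheticSpec("constant"),
}


def gradient_dominant_variant(image: np.ndarray, gain: float = 100.0) -> np.ndarray:
    """Deterministic variant whose diagonal differences dwarf the local
    intensity on most pixels, driving the ICF into its gradient-like
    (high-pass) regime.

    Every third row is amplified by (1 + gain); on the unmodulated rows the
    diagonal neighbours then exceed the local intensity by roughly the gain.
    No affine rescaling can achieve this (offsets cancel in the differences
    and the ICF is invariant under global scaling), hence the row
    modulation.  A constant image is returned unchanged: gradients cannot be
    conjured from a flat field.
    """
    image = np.asarray(image, dtype=float)
    if gain <= 0:
        raise ValueError("gain must be positive")
    if np.ptp(image) == 0:
        return image.copy()
    rows = np.arange(image.shape[0])
    factor = 1.0 + gain * (rows % 3 == 0).astype(float)
    return image * factor[:, None]
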