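"""Bivariate cubic B-spline pixel model.

Each pixel of an image is modelled by the polynomial

    h4(x, y) = f(0,0) + a3 * [(1/2) s^3 - s^2 + 2/3]
                      + a2 * [-(1/6) s^3 + s^2 - 2 s + 4/3],   s = x + y,

where (x, y) are intra-pixel coordinates measured from the pixel centre and
the two coefficients are diagonal intensity differences

    a2 = f(0,0) - f(+1/2, +1/2),    a3 = f(0,0) - f(-1/2, -1/2).

The polynomial depends on (x, y) only through s = x + y, so its first
partial derivatives with respect to x and y coincide, as do all four second
partials.  All functions below broadcast over numpy arrays, so coefficients
for a whole image can be pushed through at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "PixelNeighborhood",
    "SplineCoefficients",
    "EvaluationPoint",
    "compute_coefficients",
    "image_coefficients",
    "h4_eval",
    "h4_first_derivative",
    "h4_second_derivative",
]


@dataclass(frozen=True)
class PixelNeighborhood:
    """Sampled intensities for one pixel: the centre value and its two
    diagonal neighbours at (+1/2,+1/2) and (-1/2,-1/2)."""

    f00: ArrayLike
    f_plus: ArrayLike
    f_minus: ArrayLike
    row: int = 0
    col: int = 0


@dataclass(frozen=True)
class SplineCoefficients:
    """Diagonal-difference coefficients of the spline model."""

    alpha2: ArrayLike
    alpha3: ArrayLike


@dataclass(frozen=True)
class EvaluationPoint:
    """Intra-pixel coordinates at which per-pixel polynomials are read out.

    The default (1, 1) spans one pixel in each direction and keeps every
    monomial O(1); it also makes the filter transfer-function identity exact
    (see :mod:`icfilt.icf_engine`).
    """

    x: float = 1.0
    y: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("evaluation point must be finite")


def _require_finite(*values: ArrayLike) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("pixel intensities must be finite real numbers")


def compute_coefficients(nbhd: PixelNeighborhood) -> SplineCoefficients:
    """Diagonal differences a2 = f00 - f(+1/2,+1/2), a3 = f00 - f(-1/2,-1/2).

    Raises ``ValueError`` on non-finite input.  A constant neighbourhood
    yields (0, 0): the model reduces to the pixel value itself.
    """
    _require_finite(nbhd.f00, nbhd.f_plus, nbhd.f_minus)
    return SplineCoefficients(
        alpha2=np.subtract(nbhd.f00, nbhd.f_plus),
        alpha3=np.subtract(nbhd.f00, nbhd.f_minus),
    )


def image_coefficients(
    image: np.ndarray, neighbor_mode: str = "diagonal"
) -> SplineCoefficients:
    """Per-pixel spline coefficients over a whole image.

    The half-pixel diagonal samples are supplied from the discrete grid in
    one of two ways:

    - ``"diagonal"`` (default): nearest diagonal pixels,
      f_plus = image[r+1, c+1], f_minus = image[r-1, c-1];
    - ``"bilinear"``: bilinear interpolation at the true half-pixel offsets,
      i.e. the mean of the 2x2 block on each side.

    Boundaries use one pixel of mirror (reflect) padding, so coefficients on
    flat borders are exactly zero.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    _require_finite(image)
    p = np.pad(image, 1, mode="reflect") if min(image.shape) > 1 else np.pad(
        image, 1, mode="edge"
    )
    if neighbor_mode == "diagonal":
        f_plus = p[2:, 2:]
        f_minus = p[:-2, :-2]
    elif neighbor_mode == "bilinear":
        f_plus = 0.25 * (p[1:-1, 1:-1] + p[1:-1, 2:] + p[2:, 1:-1] + p[2:, 2:])
        f_minus = 0.25 * (p[1:-1, 1:-1] + p[1:-1, :-2] + p[:-2, 1:-1] + p[:-2, :-2])
    else:
        raise ValueError(f"unknown neighbor_mode: {neighbor_mode!r}")
    return SplineCoefficients(alpha2=image - f_plus, alpha3=image - f_minus)


def h4_eval(
    coeffs: SplineCoefficients, f00: ArrayLike, pt: EvaluationPoint
) -> ArrayLike:
    """Evaluate the spline model polynomial h4 at an intra-pixel point."""
    s = pt.x + pt.y
    bracket3 = 0.5 * s**3 - s**2 + 2.0 / 3.0
    bracket2 = -s**3 / 6.0 + s**2 - 2.0 * s + 4.0 / 3.0
    return f00 + coeffs.alpha3 * bracket3 + coeffs.alpha2 * bracket2


def h4_first_derivative(coeffs: SplineCoefficients, pt: EvaluationPoint) -> ArrayLike:
    """Common value of dh4/dx = dh4/dy at the evaluation point."""
    s = pt.x + pt.y
    return coeffs.alpha3 * (1.5 * s**2 - 2.0 * s) + coeffs.alpha2 * (
        -0.5 * s**2 + 2.0 * s - 2.0
    )


def h4_second_derivative(coeffs: SplineCoefficients, pt: EvaluationPoint) -> ArrayLike:
    """Common value of all four second partials of h4 at the evaluation point.

    At the pixel origin (0, 0) this is the classic curvature
    ``-2*alpha3 + 2*alpha2`` that must be non-null for the intensity-curvature
    functional to exist.
    """
    s = pt.x + pt.y
    return coeffs.alpha3 * (3.0 * s - 2.0) + coeffs.alpha2 * (2.0 - s)
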