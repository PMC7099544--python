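"""Intensity-curvature functional (ICF) engine.

The ICF of an image is the per-pixel ratio dE = E0 / EIN of two
intensity-curvature terms:

* E0  — integral over the pixel of the intensity times the classic
  curvature (sum of the four second partials of the spline model) evaluated
  at the pixel origin:  E0(x, y) = 4 x y f(0,0) (-2 a3 + 2 a2);
* EIN — the same integral with the resampled model in both factors:
  EIN(x, y) = int int 4 h4(u, v) [a3 (3(u+v) - 2) + a2 (2 - (u+v))] du dv
  over [0, x] x [0, y].

Interpreted as a digital filter, the pixel intensity f(0,0) is the input
function x[n], the ICF is the output y[n], and the transfer function is
TF = dE / f(0,0).  The closed-form denominator splits into the building
blocks e1..e12 and omega used by the input/output filter equations, and into
the three alpha-driven components zeta, gamma, lambda whose size relative to
f(0,0) decides whether the ICF looks like the image (intensity-dominated) or
like a high-pass response (gradient-dominated).

Two closed-form fidelity modes are provided.  ``"canonical"`` is the exact
antiderivative of the defining integral (cross-checked symbolically and by
adaptive quadrature).  ``"printed"`` reproduces the published component
equations verbatim, including their typographical slips (an alpha3^2 that
should read alpha2^2, a sign flip in one quartic monomial, and a 4/3
coefficient that should read 10/3); it exists only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import integrate

from .model_core import (
    EvaluationPoint,
    SplineCoefficients,
    h4_eval,
    image_coefficients,
)

ArrayLike = Union[float, np.ndarray]

IMAGE_LIKE = "image-like"
GRADIENT_LIKE = "gradient-like"
INDETERMINATE = "indeterminate"

__all__ = [
    "ETerms",
    "BehaviorDecomposition",
    "ICFResult",
    "compute_e_terms",
    "compute_E0",
    "compute_EIN",
    "compute_icf_image",
    "filter_output",
    "filter_input",
    "decompose",
    "classify_behavior",
    "classify_image",
    "IMAGE_LIKE",
    "GRADIENT_LIKE",
    "INDETERMINATE",
]


@dataclass(frozen=True)
class ETerms:
    """Closed-form building blocks of the EIN expansion.

    e1, e2, e4, e6, e8, e10 are monomial brackets in the evaluation point;
    e3, e5, e7, e9 are quadratic brackets in (alpha2, alpha3); e11 couples
    both; e12 = 4(-2 alpha3 + 2 alpha2) is the numerator block and
    omega = 4 (e3 e4 + e5 e6 + e7 e8 + e9 e10 + e11) the intensity-free part
    of the denominator.
    """

    e1: ArrayLike
    e2: ArrayLike
    e3: ArrayLike
    e4: ArrayLike
    e5: ArrayLike
    e6: ArrayLike
    e7: ArrayLike
    e8: ArrayLike
    e9: ArrayLike
    e10: ArrayLike
    e11: ArrayLike
    e12: ArrayLike
    omega: ArrayLike


@dataclass(frozen=True)
class BehaviorDecomposition:
    """The three alpha-driven components of dE = f00*zeta / (f00*gamma + lam)."""

    zeta: ArrayLike
    gamma: ArrayLike
    lam: ArrayLike


@dataclass(frozen=True)
class ICFResult:
    """Per-pixel intensity-curvature maps of one image.

    ``degenerate_mask`` flags pixels where |EIN| (for dE) or |f(0,0)| (for
    TF) fell below tolerance; their outputs are set to zero, matching a
    high-pass filter's null response to locally constant input.
    """

    E0_map: np.ndarray
    EIN_map: np.ndarray
    deltaE_map: np.ndarray
    TF_map: np.ndarray
    degenerate_mask: np.ndarray


def compute_e_terms(
    coeffs: SplineCoefficients,
    pt: EvaluationPoint = EvaluationPoint(),
    fidelity: str = "canonical",
) -> ETerms:
    """Evaluate the e1..e12 building blocks and omega.

    ``fidelity="canonical"`` uses the exact antiderivative coefficients;
    ``fidelity="printed"`` reproduces the published component equations
    verbatim (three known misprints included).
    """
    if fidelity not in ("canonical", "printed"):
        raise ValueError(f"unknown fidelity: {fidelity!r}")
    x, y = pt.x, pt.y
    a2, a3 = coeffs.alpha2, coeffs.alpha3
    sxy = x**2 * y / 2.0 + x * y**2 / 2.0
    e1 = 3.0 * sxy - 2.0 * x * y
    e2 = -sxy + 2.0 * x * y
    e4 = (
        x**5 * y / 5.0
        + 0.5 * x**4 * y**2
        + 2.0 * x**3 * y**3 / 3.0
        + 0.5 * x**2 * y**4
        + x * y**5 / 5.0
    )
    e8 = x**3 * y / 3.0 + x**2 * y**2 / 2.0 + x * y**3 / 3.0
    e10 = sxy
    if fidelity == "canonical":
        e3 = 1.5 * a3**2 - a3 * a2 + a2**2 / 6.0
        e5 = -4.0 * a3**2 + (16.0 / 3.0) * a3 * a2 - (4.0 / 3.0) * a2**2
        e6 = x**4 * y / 4.0 + x**3 * y**2 / 2.0 + x**2 * y**3 / 2.0 + x * y**4 / 4.0
    else:
        e3 = 1.5 * a3**2 - a3 * a2 + a3**2 / 6.0
        e5 = -4.0 * a3**2 + (10.0 / 3.0) * a3 * a2 - (4.0 / 3.0) * a2**2
        e6 = x**4 * y / 4.0 + x**3 * y**2 / 2.0 + x**2 * y**3 / 2.0 - x * y**4 / 4.0
    e7 = 2.0 * a3**2 - 10.0 * a3 * a2 + 4.0 * a2**2
    e9 = 2.0 * a3**2 + (22.0 / 3.0) * a3 * a2 - (16.0 / 3.0) * a2**2
    e11 = (
        -(4.0 / 3.0) * a3**2 - (4.0 / 3.0) * a3 * a2 + (8.0 / 3.0) * a2**2
    ) * (x * y)
    e12 = 4.0 * (-2.0 * a3 + 2.0 * a2)
    omega = 4.0 * (e3 * e4 + e5 * e6 + e7 * e8 + e9 * e10 + e11)
    return ETerms(e1, e2, e3, e4, e5, e6, e7, e8, e9, e10, e11, e12, omega)


def compute_E0(
    f00: ArrayLike,
    coeffs: SplineCoefficients,
    pt: EvaluationPoint = EvaluationPoint(),
) -> ArrayLike:
    """Intensity-curvature term before interpolation: 4xy f00 (-2a3 + 2a2)."""
    return 4.0 * pt.x * pt.y * np.asarray(f00, dtype=float) * (
        -2.0 * coeffs.alpha3 + 2.0 * coeffs.alpha2
    )


def _ein_integrand(u, v, f00, a2, a3):
    c = SplineCoefficients(alpha2=a2, alpha3=a3)
    curv = a3 * (3.0 * (u + v) - 2.0) + a2 * (2.0 - (u + v))
    return 4.0 * h4_eval(c, f00, EvaluationPoint(u, v)) * curv


def compute_EIN(
    f00: ArrayLike,
    coeffs: SplineCoefficients,
    pt: EvaluationPoint = EvaluationPoint(),
    mode: str = "closed",
    fidelity: str = "canonical",
) -> ArrayLike:
    """Intensity-curvature term after interpolation.

    ``mode="closed"`` evaluates the closed-form expansion under the chosen
    fidelity.  ``mode="integrated"`` numerically integrates the defining
    double integral over [0, x] x [0, y] with adaptive quadrature and serves
    as the ground-truth oracle (scalar inputs only).
    """
    if mode == "closed":
        t = compute_e_terms(coeffs, pt, fidelity=fidelity)
        return (
            4.0 * np.asarray(f00, dtype=float)
            * (coeffs.alpha3 * t.e1 + coeffs.alpha2 * t.e2)
            + t.omega
        )
    if mode == "integrated":
        f00 = float(f00)
        a2 = float(coeffs.alpha2)
        a3 = float(coeffs.alpha3)
        val, err = integrate.dblquad(
            lambda v, u: _ein_integrand(u, v, f00, a2, a3),
            0.0,
            pt.x,
            0.0,
            pt.y,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
            raise RuntimeError(f"quadrature did not converge (err={err})")
        return val
    raise ValueError(f"unknown mode: {mode!r}")


def _default_tol(image: np.ndarray) -> float:
    rng = float(np.ptp(image))
    return 1e-12 * rng**2 if rng > 0 else 1e-12


def compute_icf_image(
    image: np.ndarray,
    pt: EvaluationPoint = EvaluationPoint(),
    tol: float | None = None,
    neighbor_mode: str = "diagonal",
    fidelity: str = "canonical",
) -> ICFResult:
    """Per-pixel E0, EIN, dE = E0/EIN and TF = dE/f(0,0) over a whole image.

    Pixels with |EIN| below tolerance carry no curvature signal; their dE and
    TF are set to zero and flagged (likewise TF where |f(0,0)| is below
    tolerance).  The default tolerance is 1e-12 x (intensity range)^2,
    matching the quadratic intensity scaling of EIN.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2D image")
    if tol is None:
        tol = _default_tol(image)
    if tol <= 0:
        raise ValueError("tol must be positive")
    coeffs = image_coefficients(image, neighbor_mode=neighbor_mode)
    e0 = np.asarray(compute_E0(image, coeffs, pt))
    ein = np.asarray(compute_EIN(image, coeffs, pt, mode="closed", fidelity=fidelity))
    ein_bad = np.abs(ein) < tol
    f_bad = np.abs(image) < tol
    delta = np.zeros_like(image)
    np.divide(e0, ein, out=delta, where=~ein_bad)
    tf = np.zeros_like(image)
    np.divide(delta, image, out=tf, where=~(ein_bad | f_bad))
    return ICFResult(
        E0_map=e0,
        EIN_map=ein,
        deltaE_map=delta,
        TF_map=tf,
        degenerate_mask=ein_bad | f_bad,
    )


def filter_output(
    xn: ArrayLike, coeffs: SplineCoefficients, terms: ETerms
) -> Tuple[ArrayLike, ArrayLike]:
    """Filter output y[n] = x[n] e12 / [4 (x[n] a3 e1 + x[n] a2 e2) + omega].

    Returns ``(y, degenerate)``: where the denominator vanishes the signal is
    degenerate, y is set to 0 and flagged.  With x[n] = f(0,0) and an
    evaluation point satisfying x*y = 1, y[n] equals the ICF dE.
    """
    xn = np.asarray(xn, dtype=float)
    den = 4.0 * (xn * coeffs.alpha3 * terms.e1 + xn * coeffs.alpha2 * terms.e2) + terms.omega
    den = np.asarray(den, dtype=float)
    bad = np.abs(den) == 0.0
    y = np.zeros(np.broadcast(xn, den).shape)
    np.divide(xn * terms.e12, den, out=y, where=~bad)
    if y.ndim == 0:
        return float(y), bool(bad)
    return y, bad


def filter_input(
    yn: ArrayLike, coeffs: SplineCoefficients, terms: ETerms
) -> Tuple[ArrayLike, ArrayLike]:
    """Filter input x[n] = omega y[n] / [e12 - 4 y[n] (a3 e1 + a2 e2)].

    Algebraic inverse of :func:`filter_output`; a vanishing denominator is
    flagged as degenerate.
    """
    yn = np.asarray(yn, dtype=float)
    den = terms.e12 - 4.0 * yn * (coeffs.alpha3 * terms.e1 + coeffs.alpha2 * terms.e2)
    den = np.asarray(den, dtype=float)
    bad = np.abs(den) == 0.0
    x = np.zeros(np.broadcast(yn, den).shape)
    np.divide(terms.omega * yn, den, out=x, where=~bad)
    if x.ndim == 0:
        return float(x), bool(bad)
    return x, bad


def decompose(
    coeffs: SplineCoefficients, pt: EvaluationPoint = EvaluationPoint(),
    fidelity: str = "canonical",
) -> BehaviorDecomposition:
    """Split the ICF into zeta = e12, gamma = 4(a3 e1 + a2 e2), lambda = omega,
    so that dE = f00 * zeta / (f00 * gamma + lambda) wherever x*y = 1."""
    t = compute_e_terms(coeffs, pt, fidelity=fidelity)
    return BehaviorDecomposition(
        zeta=t.e12,
        gamma=4.0 * (coeffs.alpha3 * t.e1 + coeffs.alpha2 * t.e2),
        lam=t.omega,
    )


def _prevalence(a: np.ndarray, b: np.ndarray, factor: float) -> np.ndarray:
    """Three-valued comparison: -1 if |a| << |b|, +1 if |a| >> |b|, 0 otherwise.

    'Largely' means by at least ``factor``; two simultaneous zeros compare as
    neither.
    """
    a = np.abs(np.asarray(a, dtype=float))
    b = np.abs(np.asarray(b, dtype=float))
    out = np.zeros(np.broadcast(a, b).shape, dtype=np.int8)
    both_zero = (a == 0) & (b == 0)
    out[(factor * a <= b) & ~both_zero] = -1
    out[(a >= factor * b) & ~both_zero] = 1
    return out


def classify_behavior(
    f00: ArrayLike, decomp: BehaviorDecomposition, factor: float = 10.0
) -> np.ndarray:
    """Label each pixel's ICF regime from the prevalence of zeta, gamma and
    lambda over the pixel intensity f(0,0).

    The ICF looks image-like when the intensity dominates every component
    (or when zeta and gamma both dominate while lambda is negligible, in
    which case dE reduces to the intensity-free ratio zeta/gamma); it is
    gradient-like — a high-pass response — when the alpha-driven components
    prevail; mixed prevalence patterns are indeterminate.  ``factor`` (> 1)
    quantifies 'largely' smaller/bigger.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    z = _prevalence(decomp.zeta, f00, factor)
    g = _prevalence(decomp.gamma, f00, factor)
    l = _prevalence(decomp.lam, f00, factor)
    image_like = ((z == -1) & (g == -1) & (l == -1)) | ((z == 1) & (g == 1) & (l == -1))
    gradient_like = ((z == 1) & (g == 1) & (l != -1)) | (
        (z != 0) & (g != 0) & (l != 0) & ~image_like
    )
    labels = np.full(z.shape, INDETERMINATE, dtype=object)
    labels[gradient_like] = GRADIENT_LIKE
    labels[image_like] = IMAGE_LIKE
    return labels


def classify_image(
    image: np.ndarray,
    pt: EvaluationPoint = EvaluationPoint(),
    factor: float = 10.0,
    neighbor_mode: str = "diagonal",
) -> np.ndarray:
    """Per-pixel regime labels for a whole image."""
    image = np.asarray(image, dtype=float)
    coeffs = image_coefficients(image, neighbor_mode=neighbor_mode)
    return classify_behavior(image, decompose(coeffs, pt), factor=factor)
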