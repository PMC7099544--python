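"""Tests of the intensity-curvature terms, the ICF maps, the filter
input/output equations and the behavior classifier.

The closed-form EIN is validated against two independent oracles: adaptive
2D quadrature of the defining integral, and a sympy symbolic integration
performed from the model polynomial alone.
"""

import numpy as np
import pytest

from icfilt.icf_engine import (
    GRADIENT_LIKE,
    IMAGE_LIKE,
    INDETERMINATE,
    BehaviorDecomposition,
    classify_behavior,
    classify_image,
    compute_E0,
    compute_EIN,
    compute_e_terms,
    compute_icf_image,
    decompose,
    filter_input,
    filter_output,
)
from icfilt.model_core import EvaluationPoint, SplineCoefficients, image_coefficients

PT11 = EvaluationPoint(1.0, 1.0)


# ---------------------------------------------------------------- E0 / e-terms

@pytest.mark.parametrize(
    "f00,a2,a3,pt,expected",
    [
        (1.0, 1.0, 0.0, EvaluationPoint(1, 1), 8.0),
        (9.0, 4.0, 4.0, EvaluationPoint(0.3, 0.8), 0.0),
        (2.0, 0.0, 1.0, EvaluationPoint(0.5, 0.5), -4.0),
    ],
)
def test_E0_closed_form(f00, a2, a3, pt, expected):
    assert compute_E0(f00, SplineCoefficients(a2, a3), pt) == pytest.approx(expected)


def test_E0_matches_double_integral_of_origin_curvature(rng):
    """E0's closed form equals the definite double integral of
    f00 * 4 * (-2 a3 + 2 a2) over [0,x] x [0,y] (the integrand is constant)."""
    for _ in range(20):
        f00, a2, a3 = rng.normal(0, 10, 3)
        x, y = rng.uniform(0.1, 2.0, 2)
        exact = 4.0 * x * y * f00 * (-2 * a3 + 2 * a2)
        got = compute_E0(f00, SplineCoefficients(a2, a3), EvaluationPoint(x, y))
        assert got == pytest.approx(exact, rel=1e-15, abs=1e-12)


def test_e_terms_point_values():
    t = compute_e_terms(SplineCoefficients(0.3, -0.2), PT11)
    assert t.e1 == pytest.approx(1.0)
    assert t.e2 == pytest.approx(1.0)
    t2 = compute_e_terms(SplineCoefficients(1.0, 0.0), PT11)
    assert t2.e12 == pytest.approx(8.0)
    t3 = compute_e_terms(SplineCoefficients(0.0, 0.0), PT11)
    assert t3.omega == 0.0


def test_omega_is_quadratic_in_alphas(rng):
    for _ in range(10):
        a2, a3, k = rng.normal(0, 3, 3)
        w1 = compute_e_terms(SplineCoefficients(a2, a3), PT11).omega
        wk = compute_e_terms(SplineCoefficients(k * a2, k * a3), PT11).omega
        assert wk == pytest.approx(k**2 * w1, rel=1e-12, abs=1e-12)


# ------------------------------------------------------------------ EIN oracle

def test_EIN_closed_matches_quadrature(rng):
    """Canonical closed form vs adaptive 2D quadrature of the defining
    integral, at randomized coefficients and evaluation points."""
    for _ in range(25):
        f00, a2, a3 = rng.normal(0, 5, 3)
        x, y = rng.uniform(0.2, 1.5, 2)
        pt = EvaluationPoint(x, y)
        c = SplineCoefficients(a2, a3)
        closed = compute_EIN(f00, c, pt, mode="closed")
        integ = compute_EIN(f00, c, pt, mode="integrated")
        assert closed == pytest.approx(integ, rel=1e-6, abs=1e-9)


def test_EIN_regression_values():
    """Frozen values computed from the quadrature oracle (exact fractions
    confirmed symbolically): EIN(1,1,1)@(1,1) = 488/45, EIN(1,1,0) = 242/45."""
    assert compute_EIN(1.0, SplineCoefficients(1.0, 1.0), PT11) == pytest.approx(488 / 45)
    assert compute_EIN(1.0, SplineCoefficients(1.0, 0.0), PT11) == pytest.approx(242 / 45)


def test_EIN_closed_matches_sympy_symbolic_integral():
    """Independent symbolic oracle: integrate 4*h4*(sum of second partials)
    with sympy from the model polynomial alone and compare."""
    sp = pytest.importorskip("sympy")
    u, v = sp.symbols("u v")
    f00s, a2s, a3s = sp.Rational(3, 2), sp.Rational(-2, 3), sp.Rational(5, 7)
    s = u + v
    h4 = (
        f00s
        + a3s * (s**3 / 2 - s**2 + sp.Rational(2, 3))
        + a2s * (-s**3 / 6 + s**2 - 2 * s + sp.Rational(4, 3))
    )
    curv = a3s * (3 * s - 2) + a2s * (2 - s)
    x0, y0 = sp.Rational(4, 5), sp.Rational(7, 6)
    exact = sp.integrate(sp.integrate(4 * h4 * curv, (u, 0, x0)), (v, 0, y0))
    got = compute_EIN(
        float(f00s),
        SplineCoefficients(float(a2s), float(a3s)),
        EvaluationPoint(float(x0), float(y0)),
        mode="closed",
    )
    assert got == pytest.approx(float(exact), rel=1e-12)


def test_EIN_vanishes_for_flat_neighborhood():
    assert compute_EIN(7.0, SplineCoefficients(0.0, 0.0), PT11) == 0.0


def test_printed_fidelity_reproduces_published_component_equations():
    """The printed mode keeps the published misprints, so it deviates from the
    canonical form by exactly the three documented term differences."""
    a2, a3, x, y = 1.3, -0.7, 1.0, 1.0
    c = SplineCoefficients(a2, a3)
    can = compute_e_terms(c, PT11, fidelity="canonical")
    pr = compute_e_terms(c, PT11, fidelity="printed")
    assert pr.e3 - can.e3 == pytest.approx((a3**2 - a2**2) / 6.0)
    assert pr.e5 - can.e5 == pytest.approx(-2.0 * a3 * a2)
    assert pr.e6 - can.e6 == pytest.approx(-x * y**4 / 2.0)
    # and the printed closed form deviates from the quadrature ground truth
    closed_printed = compute_EIN(1.0, c, PT11, mode="closed", fidelity="printed")
    integ = compute_EIN(1.0, c, PT11, mode="integrated")
    assert closed_printed != pytest.approx(integ, rel=1e-6)


# ------------------------------------------------------------------- ICF maps

def test_constant_image_is_fully_degenerate():
    res = compute_icf_image(np.full((8, 8), 5.0))
    assert np.all(res.deltaE_map == 0)
    assert np.all(res.degenerate_mask)


def test_impulse_image_only_activates_diagonal_neighborhood():
    img = np.zeros((9, 9))
    img[4, 4] = 10.0
    res = compute_icf_image(img)
    active = ~res.degenerate_mask
    rows, cols = np.nonzero(active)
    assert len(rows) > 0
    assert np.all(np.abs(rows - 4) <= 1) and np.all(np.abs(cols - 4) <= 1)


def _icf_scalar_oracle(image, pt):
    """Loop-based per-pixel evaluation of dE via the raw closed forms."""
    img = np.asarray(image, dtype=float)
    pad = np.pad(img, 1, mode="reflect")
    out = np.zeros_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            f00 = img[r, c]
            a2 = f00 - pad[r + 2, c + 2]
            a3 = f00 - pad[r, c]
            coeffs = SplineCoefficients(a2, a3)
            e0 = compute_E0(f00, coeffs, pt)
            ein = compute_EIN(f00, coeffs, pt, mode="closed")
            out[r, c] = e0 / ein if abs(ein) >= 1e-12 else 0.0
    return out


def test_icf_image_matches_scalar_loop_oracle():
    img = np.add.outer(np.arange(8.0), np.arange(8.0))
    res = compute_icf_image(img, tol=1e-12)
    expected = _icf_scalar_oracle(img, PT11)
    np.testing.assert_allclose(res.deltaE_map, expected, rtol=1e-12, atol=1e-12)


def test_icf_maps_share_shape_and_are_finite(sphere64):
    res = compute_icf_image(sphere64)
    for m in (res.E0_map, res.EIN_map, res.deltaE_map, res.TF_map):
        assert m.shape == sphere64.shape
        assert np.all(np.isfinite(m))
    nd = ~res.degenerate_mask
    np.testing.assert_allclose(
        res.deltaE_map[nd], res.E0_map[nd] / res.EIN_map[nd], rtol=1e-12
    )
    np.testing.assert_allclose(
        res.TF_map[nd], res.deltaE_map[nd] / sphere64[nd], rtol=1e-12
    )


def test_icf_is_invariant_under_global_intensity_scaling(sphere64):
    res1 = compute_icf_image(sphere64, tol=1e-9)
    res2 = compute_icf_image(7.5 * sphere64, tol=1e-9 * 7.5**2)
    nd = ~(res1.degenerate_mask | res2.degenerate_mask)
    assert nd.sum() > 100
    np.testing.assert_allclose(res1.deltaE_map[nd], res2.deltaE_map[nd], rtol=1e-9)


def test_icf_image_input_validation():
    with pytest.raises(ValueError):
        compute_icf_image(np.zeros((0, 4)))
    with pytest.raises(ValueError):
        compute_icf_image(np.ones((4, 4)), tol=-1.0)


# --------------------------------------------------------- filter i/o identity

def test_filter_output_equals_icf_at_pixel_intensity(sphere64):
    coeffs = image_coefficients(sphere64)
    terms = compute_e_terms(coeffs, PT11)
    res = compute_icf_image(sphere64)
    y, _ = filter_output(sphere64, coeffs, terms)
    nd = ~res.degenerate_mask
    np.testing.assert_allclose(y[nd], res.deltaE_map[nd], rtol=1e-12, atol=1e-12)


def test_filter_output_degenerate_for_flat_signal():
    c = SplineCoefficients(0.0, 0.0)
    t = compute_e_terms(c, PT11)
    y, bad = filter_output(3.0, c, t)
    assert bad and y == 0.0


def test_filter_roundtrip_recovers_input(rng):
    """filter_input(filter_output(x)) == x on randomized non-degenerate input."""
    checked = 0
    while checked < 100:
        f00, a2, a3 = rng.normal(0, 10, 3)
        x, y_pt = rng.uniform(0.3, 1.5, 2)
        c = SplineCoefficients(a2, a3)
        t = compute_e_terms(c, EvaluationPoint(x, y_pt))
        yn, bad_y = filter_output(f00, c, t)
        if bad_y or t.omega == 0:
            continue
        xn, bad_x = filter_input(yn, c, t)
        if bad_x:
            continue
        assert xn == pytest.approx(f00, rel=1e-9, abs=1e-9)
        checked += 1


def test_filter_input_zero_maps_to_zero():
    c = SplineCoefficients(1.0, 0.0)
    t = compute_e_terms(c, PT11)
    x, bad = filter_input(0.0, c, t)
    assert not bad and x == 0.0


# ----------------------------------------------------------- decomposition

def test_decomposition_identity(sphere64):
    """f00*zeta / (f00*gamma + lambda) reproduces E0/EIN at non-degenerate
    pixels for the unit-area evaluation point."""
    coeffs = image_coefficients(sphere64)
    d = decompose(coeffs, PT11)
    res = compute_icf_image(sphere64)
    nd = ~res.degenerate_mask
    den = sphere64 * d.gamma + d.lam
    recon = np.zeros_like(sphere64)
    np.divide(sphere64 * d.zeta, den, out=recon, where=den != 0)
    np.testing.assert_allclose(recon[nd], res.deltaE_map[nd], rtol=1e-9, atol=1e-12)


@pytest.mark.parametrize(
    "f00,zeta,gamma,lam,expected",
    [
        (1000.0, 1.0, 1.0, 1.0, IMAGE_LIKE),
        (1.0, 1000.0, 1000.0, 1.0, GRADIENT_LIKE),
        (1.0, 2.0, 2.0, 2.0, INDETERMINATE),
        (1.0, 1000.0, 1000.0, 0.01, IMAGE_LIKE),   # zeta/gamma ratio regime
        (1.0, 1000.0, 0.01, 1000.0, GRADIENT_LIKE),
        (1.0, 0.01, 1000.0, 1000.0, GRADIENT_LIKE),
        (1.0, 1000.0, 1000.0, 1000.0, GRADIENT_LIKE),
    ],
)
def test_behavior_classifier_regimes(f00, zeta, gamma, lam, expected):
    d = BehaviorDecomposition(zeta=zeta, gamma=gamma, lam=lam)
    assert classify_behavior(f00, d, factor=10.0).item() == expected


def test_classifier_rejects_unit_factor():
    with pytest.raises(ValueError):
        classify_behavior(1.0, BehaviorDecomposition(1.0, 1.0, 1.0), factor=1.0)


def test_classify_image_returns_per_pixel_labels(sphere64):
    labels = classify_image(sphere64)
    assert labels.shape == sphere64.shape
    assert set(np.unique(labels)) <= {IMAGE_LIKE, GRADIENT_LIKE, INDETERMINATE}
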