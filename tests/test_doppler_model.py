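"""Unit and property tests for the Doppler forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy.special import j1

import specklemotion as sm
from specklemotion.doppler_model import gaussian_decay_rate
from specklemotion.exceptions import GridError, ParameterError

from conftest import WAVELENGTH, CHI_S_HIGHSPEED, build_spectrum

LAM = WAVELENGTH


# ---------------------------------------------------------------------------
# density functions


@pytest.mark.parametrize("family,shape", [
    ("semicircular", 0.01),
    ("semicircular", 0.03),
    ("gaussian", 26.5e-4),
    ("gaussian", 5e-3),
])
def test_density_unit_integral_and_nonnegative(family, shape):
    spread = sm.WavevectorSpread(family, shape)
    grid = sm.default_u_grid(spread)
    vals = sm.wavevector_density(spread, grid)
    assert np.all(vals >= 0)
    assert abs(np.trapezoid(vals, grid) - 1.0) < 1e-6


def test_semicircular_support_is_chi():
    spread = sm.WavevectorSpread("semicircular", 0.01)
    grid = np.linspace(-0.02, 0.02, 4001)
    vals = sm.wavevector_density(spread, grid)
    assert np.all(vals[np.abs(grid) > 0.01] == 0.0)
    assert vals[np.abs(grid) < 0.009].min() > 0


def test_semicircular_second_moment_is_quarter_chi_squared():
    # closed-form moment of the semicircle checked by numeric quadrature
    chi = 0.03
    spread = sm.WavevectorSpread("semicircular", chi)
    grid = np.linspace(-2 * chi, 2 * chi, 32001)
    vals = sm.wavevector_density(spread, grid)
    m2 = np.trapezoid(vals * grid**2, grid)
    # trapezoid converges slowly at the sqrt edge; 1e-5 reflects the grid
    assert m2 == pytest.approx(chi**2 / 4, rel=1e-5)


@pytest.mark.parametrize("family", ["semicircular", "gaussian"])
def test_zero_shape_is_delta_at_origin(family):
    spread = sm.WavevectorSpread(family, 0.0)
    grid = np.linspace(-0.01, 0.01, 101)
    vals = sm.wavevector_density(spread, grid)
    assert np.count_nonzero(vals) == 1
    assert vals[np.argmin(np.abs(grid))] > 0
    assert abs(np.trapezoid(vals, grid) - 1.0) < 1e-6


def test_density_input_validation():
    with pytest.raises(ParameterError):
        sm.WavevectorSpread("semicircular", -0.1)
    with pytest.raises(ParameterError):
        sm.WavevectorSpread("triangular", 0.1)
    spread = sm.WavevectorSpread("gaussian", 0.01)
    with pytest.raises(GridError):
        sm.wavevector_density(spread, np.array([0.0, 0.1, 0.3]))  # non-uniform
    with pytest.raises(GridError):
        sm.wavevector_density(spread, np.linspace(-0.01, 0.02, 31))  # asymmetric
    with pytest.raises(GridError):
        sm.wavevector_density(spread, np.array([0.0]))


# ---------------------------------------------------------------------------
# Doppler distribution and PSD


def test_convolution_with_delta_is_identity():
    grid = np.linspace(-0.02, 0.02, 2001)
    p_delta = sm.wavevector_density(sm.WavevectorSpread("semicircular", 0.0), grid)
    p_s = sm.wavevector_density(sm.WavevectorSpread("semicircular", 0.01), grid)
    spec = sm.doppler_distribution(p_delta, p_s, grid, 5e-3, LAM)
    center = np.interp(grid, spec.u_grid, spec.amplitude)
    assert np.abs(center - p_s).max() < 1e-6


def test_gaussian_convolution_matches_analytic_width():
    # densities exp(-(u/sigma)^2) have variance sigma^2/2; the convolution is
    # Gaussian with variance (sigma_i^2 + sigma_s^2)/2
    s_i, s_s = 2e-3, 3e-3
    grid = np.linspace(-0.03, 0.03, 4097)
    p_i = sm.wavevector_density(sm.WavevectorSpread("gaussian", s_i), grid)
    p_s = sm.wavevector_density(sm.WavevectorSpread("gaussian", s_s), grid)
    spec = sm.doppler_distribution(p_i, p_s, grid, 5e-3, LAM)
    var = (s_i**2 + s_s**2) / 2
    exact = np.exp(-spec.u_grid**2 / (2 * var)) / np.sqrt(2 * np.pi * var)
    assert np.abs(spec.amplitude - exact).max() < 1e-6
    assert spec.moment(2) == pytest.approx(var, rel=1e-6)


def test_semicircular_pair_distribution_symmetric_with_summed_support():
    chi = 0.01
    spec = build_spectrum("semicircular", chi, chi, 5e-3)
    assert abs(spec.moment(1)) < 1e-12
    assert np.abs(spec.amplitude - spec.amplitude[::-1]).max() < 1e-9
    outside = np.abs(spec.u_grid) > 2 * chi * (1 + 1e-9)
    assert np.all(spec.amplitude[outside] < 1e-12)


def test_psd_of_delta_is_delta_and_gaussian_width_scales_sqrt2():
    spec_delta = build_spectrum("semicircular", 0.0, 0.0, 0.0)
    psd = sm.power_spectral_density(spec_delta)
    assert np.count_nonzero(psd.amplitude > 1e-9 * psd.amplitude.max()) <= 3

    sigma = 3e-3
    spec = build_spectrum("gaussian", 0.0, sigma, 5e-3)
    psd = sm.power_spectral_density(spec)
    assert psd.moment(2) == pytest.approx(2 * spec.moment(2), rel=1e-6)
    # support of the self-convolved semicircular pair doubles
    chi = 0.01
    pair = build_spectrum("semicircular", chi, chi, 5e-3)
    psd2 = sm.power_spectral_density(pair)
    inside = np.abs(psd2.u_grid) < 4 * chi * (1 - 1e-6)
    outside = np.abs(psd2.u_grid) > 4 * chi * (1 + 1e-9)
    assert np.all(psd2.amplitude[outside] < 1e-12)
    assert psd2.amplitude[inside & (np.abs(psd2.u_grid) > 3.9 * chi)].max() >= 0


# ---------------------------------------------------------------------------
# correlation curves


def test_g2_numeric_delta_spectrum_is_constant_two():
    psd = sm.power_spectral_density(build_spectrum("semicircular", 0.0, 0.0, 5e-3))
    lags = np.linspace(0, 0.1, 50)
    # the resolution warning is expected: a delta spectrum has no bandwidth
    with pytest.warns(sm.ResolutionWarning):
        curve = sm.g2_numeric(psd, lags)
    assert np.abs(curve.values - 2.0).max() < 1e-9


@pytest.mark.parametrize("family", ["semicircular", "gaussian"])
def test_g2_numeric_matches_closed_form(family):
    speed, shape_s = 5e-3, CHI_S_HIGHSPEED
    spec = build_spectrum(family, 0.0, shape_s, speed)
    psd = sm.power_spectral_density(spec)
    if family == "gaussian":
        a = gaussian_decay_rate(speed, LAM, 0.0, shape_s)
        lags = np.linspace(0, 3 * math.sqrt(2 / a), 250)
        closed = sm.g2_gaussian_closed(lags, speed, LAM, 0.0, shape_s)
    else:
        b_s = LAM / (2 * np.pi * speed * shape_s)
        lags = np.linspace(0, 3 * 1.93 * b_s, 250)
        closed = sm.g2_semicircular_closed(lags, speed, LAM, 0.0, shape_s)
    numeric = sm.g2_numeric(psd, lags)
    assert np.abs(numeric.values - closed.values).max() < 1e-3


def test_closed_forms_pedestal_and_range():
    lags = np.linspace(0, 0.5, 20000)
    for curve in (
        sm.g2_semicircular_closed(lags, 5e-3, LAM, 0.0, CHI_S_HIGHSPEED),
        sm.g2_gaussian_closed(lags, 5e-3, LAM, 0.0, CHI_S_HIGHSPEED),
    ):
        assert curve.values[0] == 2.0
        assert np.all(curve.values >= 1.0) and np.all(curve.values <= 2.0)
        assert curve.values[-1] < 1.001


def test_semicircular_first_zero_at_bessel_root():
    # with chi_i = 0, g2 - 1 first touches 0 at tau = j_{1,1} * b_s
    speed, chi_s = 5e-3, CHI_S_HIGHSPEED
    b_s = LAM / (2 * np.pi * speed * chi_s)

    def excess(tau):
        curve = sm.g2_semicircular_closed(np.array([0.0, tau]), speed, LAM, 0.0, chi_s)
        return curve.values[1] - 1.0

    root = optimize.brentq(lambda t: 2 * b_s * j1(t / b_s) / t, 3.0 * b_s, 4.5 * b_s)
    assert root / b_s == pytest.approx(3.8317, abs=1e-3)
    assert excess(root) < 1e-12


def test_curve_depends_only_on_speed_shape_product():
    lags = np.linspace(0, 0.05, 200)
    ref = sm.g2_semicircular_closed(lags, 5e-3, LAM, 0.0, CHI_S_HIGHSPEED)
    scaled = sm.g2_semicircular_closed(lags, 10e-3, LAM, 0.0, CHI_S_HIGHSPEED / 2)
    np.testing.assert_allclose(ref.values, scaled.values, rtol=1e-12)


def test_gaussian_closed_decays_to_inverse_e_at_sqrt_two_over_a():
    speed, sigma_s = 5e-3, CHI_S_HIGHSPEED
    a = gaussian_decay_rate(speed, LAM, 0.0, sigma_s)
    tau = math.sqrt(2.0 / a)
    curve = sm.g2_gaussian_closed(np.array([0.0, tau]), speed, LAM, 0.0, sigma_s)
    assert curve.values[1] - 1.0 == pytest.approx(math.exp(-1), rel=1e-12)


def test_degenerate_zero_spreads_warn_and_return_constant():
    lags = np.linspace(0, 0.01, 10)
    with pytest.warns(UserWarning):
        curve = sm.g2_semicircular_closed(lags, 5e-3, LAM, 0.0, 0.0)
    assert np.all(curve.values == 2.0)


# ---------------------------------------------------------------------------
# contrast


def test_contrast_static_limit_is_one():
    assert sm.contrast_numeric(lambda tau: 1.0, 0.01) == pytest.approx(1.0, rel=1e-9)
    assert sm.contrast_semicircular(0.0, LAM, 0.0, 5e-3, 0.01) == 1.0
    assert sm.contrast_gaussian(0.0, LAM, 0.0, 5e-3, 0.01) == 1.0


def test_contrast_gaussian_closed_matches_quadrature():
    for speed in (1e-3, 5e-3, 10e-3, 30e-3):
        for sigma_s in (1e-3, 2.65e-3, 5e-3):
            for exposure in (5e-3, 10e-3, 25e-3):
                a = gaussian_decay_rate(speed, LAM, 0.0, sigma_s)
                closed = sm.contrast_gaussian(speed, LAM, 0.0, sigma_s, exposure)
                numeric = sm.contrast_numeric(
                    lambda tau: math.exp(-0.5 * a * tau * tau), exposure
                )
                assert abs(closed - numeric) / numeric < 1e-6


def test_contrast_gaussian_highspeed_value():
    # V=5 mm/s, sigma_i=0, sigma_s=26.5e-4, T=10 ms; frozen from the
    # quadrature of the exposure integral
    c = sm.contrast_gaussian(5e-3, LAM, 0.0, 26.5e-4, 10e-3)
    assert c == pytest.approx(0.9429, abs=5e-4)


def test_contrast_semicircular_matches_numeric_oracle():
    speed, chi_s, T = 10e-3, 5e-3, 10e-3
    b_s = LAM / (2 * np.pi * speed * chi_s)

    def g1_sq(tau):
        if tau == 0:
            return 1.0
        return (2 * b_s * j1(tau / b_s) / tau) ** 2

    direct = sm.contrast_numeric(g1_sq, T, points=[b_s, 4 * b_s, 16 * b_s])
    assert sm.contrast_semicircular(speed, LAM, 0.0, chi_s, T) == pytest.approx(direct, rel=1e-9)


def test_contrast_asymptotic_inverse_sqrt_speed():
    # once |g1|^2 decays much faster than T, C scales as 1/sqrt(V)
    ref = 5e-2
    c10 = sm.contrast_gaussian(10 * ref, LAM, 0.0, 26.5e-4, 10e-3)
    c40 = sm.contrast_gaussian(40 * ref, LAM, 0.0, 26.5e-4, 10e-3)
    assert c10 / c40 == pytest.approx(2.0, rel=0.05)
    s10 = sm.contrast_semicircular(10 * ref, LAM, 0.0, 26.5e-4, 10e-3)
    s40 = sm.contrast_semicircular(40 * ref, LAM, 0.0, 26.5e-4, 10e-3)
    assert s10 / s40 == pytest.approx(2.0, rel=0.05)


def test_contrast_monotone_in_speed_spread_and_exposure():
    speeds = np.array([0.0, 2e-3, 5e-3, 10e-3, 20e-3, 30e-3])
    model = sm.ContrastModel("gaussian", 0.0, 26.5e-4, LAM, 10e-3)
    curve = sm.contrast_curve(speeds, model)
    assert np.all(np.diff(curve.contrast) < 0)
    for param in ("shape_i", "shape_s"):
        values = [
            sm.contrast_gaussian(5e-3, LAM,
                                 s if param == "shape_i" else 0.0,
                                 s if param == "shape_s" else 26.5e-4,
                                 10e-3)
            for s in (1e-3, 3e-3, 8e-3)
        ]
        assert values[0] > values[1] > values[2]
    exposures = [sm.contrast_gaussian(5e-3, LAM, 0.0, 26.5e-4, T)
                 for T in (5e-3, 10e-3, 25e-3)]
    assert exposures[0] > exposures[1] > exposures[2]


def test_contrast_ordering_in_illumination_spread():
    # wider illumination spread (longer fiber-to-diffuser distance) lowers contrast
    values = [sm.contrast_semicircular(10e-3, LAM, chi_i, 5e-3, 10e-3)
              for chi_i in (0.0081, 0.0216, 0.0337)]
    assert values[0] > values[1] > values[2]


def test_contrast_curve_dispatch_and_family_proximity():
    speeds = np.linspace(0, 30e-3, 7)
    semi = sm.contrast_curve(speeds, sm.ContrastModel("semicircular", 0.0, 5e-3, LAM, 10e-3))
    gauss = sm.contrast_curve(speeds, sm.ContrastModel("gaussian", 0.0, 5e-3, LAM, 10e-3))
    assert semi.contrast[0] == 1.0
    # at equal shape the Gaussian density is effectively wider (second moment
    # sigma^2/2 vs chi^2/4), so the families differ by up to ~0.08 in contrast
    diff = np.abs(semi.contrast - gauss.contrast)
    assert diff.max() < 0.1
    assert np.all(gauss.contrast[1:] < semi.contrast[1:])


def test_beta_scales_pedestal_and_contrast():
    lags = np.linspace(0, 0.05, 100)
    curve = sm.g2_gaussian_closed(lags, 5e-3, LAM, 0.0, 26.5e-4, beta=0.6)
    assert curve.values[0] == pytest.approx(1.6, rel=1e-12)
    c_full = sm.contrast_gaussian(5e-3, LAM, 0.0, 26.5e-4, 10e-3)
    c_part = sm.contrast_gaussian(5e-3, LAM, 0.0, 26.5e-4, 10e-3, beta=0.6)
    assert c_part == pytest.approx(math.sqrt(0.6) * c_full, rel=1e-12)


# ---------------------------------------------------------------------------
# property-based invariants


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(["semicircular", "gaussian"]),
    shape_i=st.one_of(st.just(0.0), st.floats(1e-4, 0.05)),
    shape_s=st.floats(1e-4, 0.05),
)
def test_spectrum_normalization_property(family, shape_i, shape_s):
    spec = build_spectrum(family, shape_i, shape_s, 5e-3)
    assert abs(np.trapezoid(spec.amplitude, spec.u_grid) - 1.0) < 1e-6
    psd = sm.power_spectral_density(spec)
    assert abs(np.trapezoid(psd.amplitude, psd.u_grid) - 1.0) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.25, 4.0),
    speed=st.floats(1e-3, 3e-2),
    chi_s=st.floats(1e-3, 1e-2),
)
def test_contrast_scale_invariance_property(scale, speed, chi_s):
    # contrast depends on speed and spread only through their product
    base = sm.contrast_semicircular(speed, LAM, 0.0, chi_s, 10e-3)
    scaled = sm.contrast_semicircular(speed * scale, LAM, 0.0, chi_s / scale, 10e-3)
    assert scaled == pytest.approx(base, rel=1e-7)
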