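"""Doppler-shift forward model for translation-induced speckle decorrelation.

When a rigid scattering object translates at speed ``V`` under coherent
illumination at wavelength ``lambda``, every pair of illumination wavevector
``k_i`` and detection wavevector ``k_s`` contributes an optical Doppler shift
``omega_D = v . (k_s - k_i)``.  The spreads of the two wavevector cones are
described by probability densities over the dimensionless normalized frequency

    u = omega_D * lambda / (2 pi V),

one density for the illumination side and one for the detection side.  The
distribution of Doppler shifts ``A(u)`` is the convolution of the two
densities, the power spectral density ``P(u)`` is the self-convolution of
``A``, and the normalized intensity autocorrelation follows from the
Wiener-Khinchin theorem,

    g2(tau) = 1 + beta * F^-1{P}(tau) / F^-1{P}(0),

with coherence factor ``beta = 1`` for fully developed speckle.  The contrast
of speckle intensity integrated over an exposure ``T`` is

    C^2 = (2/T) * int_0^T (1 - tau/T) |g1(tau)|^2 dtau,

with the Siegert relation ``|g1|^2 = g2 - 1``.

Two density families are provided.  For semicircular densities of half-widths
``chi_i`` and ``chi_s`` the field correlation is a product of Bessel kernels
(characteristic function of the Wigner semicircle),

    g2(tau) = 1 + [ 2 b_i J1(tau/b_i)/tau * 2 b_s J1(tau/b_s)/tau ]^2,
    b_{i,s} = lambda / (2 pi V chi_{i,s}),

and the exposure integral is evaluated numerically.  For Gaussian densities of
widths ``sigma_i`` and ``sigma_s``,

    g2(tau) = 1 + exp(-a tau^2 / 2),   a = (2 pi V / lambda)^2 (sigma_i^2 + sigma_s^2),

and the contrast has the closed form

    C^2 = (2/T) [ sqrt(pi/(2a)) erf(T sqrt(a/2)) + (exp(-a T^2/2) - 1)/(a T) ].

A zero shape parameter denotes a Dirac-delta spread (plane/spherical-wave
illumination or pinhole detection) and is handled through analytic limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .exceptions import GridError, ParameterError, ResolutionWarning

__all__ = [
    "FAMILIES",
    "WavevectorSpread",
    "DopplerSpectrum",
    "CorrelationCurve",
    "ContrastModel",
    "ContrastCurve",
    "default_u_grid",
    "wavevector_density",
    "doppler_distribution",
    "doppler_spectrum",
    "power_spectral_density",
    "g2_numeric",
    "g2_semicircular_closed",
    "g2_gaussian_closed",
    "contrast_numeric",
    "contrast_semicircular",
    "contrast_gaussian",
    "contrast_curve",
]

FAMILIES = ("semicircular", "gaussian")

#: Default number of grid points; odd so that u = 0 is an exact grid point,
#: which keeps delta spreads and even symmetry exact under discrete convolution.
DEFAULT_GRID_POINTS = 4097

#: Grids span 1.2x the support of the convolved distribution.
DEFAULT_SPAN_FACTOR = 1.2

#: Effective half-support assigned to a Gaussian density, in units of sigma.
_GAUSSIAN_SUPPORT_SIGMAS = 5.0

_NORM_TOL = 1e-6


def _as_grid(u_grid) -> tuple[np.ndarray, float]:
    """Validate a uniform grid symmetric about zero; return (grid, step)."""
    u = np.asarray(u_grid, dtype=float)
    if u.ndim != 1 or u.size < 3:
        raise GridError("u_grid must be a 1-D array with at least 3 points")
    steps = np.diff(u)
    du = steps[0]
    if du <= 0 or not np.allclose(steps, du, rtol=1e-9, atol=0.0):
        raise GridError("u_grid must be uniformly spaced and increasing")
    if abs(u[0] + u[-1]) > 1e-9 * max(1.0, abs(u[0])):
        raise GridError("u_grid must be symmetric about u = 0")
    return u, du


@dataclass(frozen=True)
class WavevectorSpread:
    """One side's wavevector spread: a density family plus a shape parameter.

    ``shape`` is the dimensionless width (chi for the semicircular family, sigma
    for the Gaussian family); ``shape = 0`` is the Dirac-delta limit of a plane
    or spherical illumination wave, or pinhole detection.
    """

    family: str
    shape: float
    role: str = "detection"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown density family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.role not in ("illumination", "detection"):
            raise ParameterError(f"unknown role {self.role!r}")
        if not math.isfinite(self.shape) or self.shape < 0:
            raise ParameterError("shape parameter must be a finite nonnegative real")

    @property
    def support(self) -> float:
        """Effective half-support of the induced density over u."""
        if self.shape == 0:
            return 0.0
        if self.family == "semicircular":
            return self.shape
        return _GAUSSIAN_SUPPORT_SIGMAS * self.shape


@dataclass(frozen=True, eq=False)
class DopplerSpectrum:
    """A distribution over normalized Doppler frequency u = omega lambda/(2 pi V).

    ``speed`` (m/s) and ``wavelength`` (m) convert u to angular frequency via
    omega = u * 2 pi V / lambda.  The amplitude integrates to 1 (trapezoid rule)
    within 1e-6; use :meth:`from_amplitude` to renormalize raw values.
    """

    u_grid: np.ndarray
    amplitude: np.ndarray
    speed: float
    wavelength: float

    def __post_init__(self):
        u, _ = _as_grid(self.u_grid)
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.shape != u.shape:
            raise GridError("amplitude and u_grid must have the same shape")
        if np.any(amp < -1e-12):
            raise ParameterError("spectrum amplitude must be nonnegative")
        object.__setattr__(self, "u_grid", u)
        object.__setattr__(self, "amplitude", np.clip(amp, 0.0, None))
        if self.speed < 0 or self.wavelength <= 0:
            raise ParameterError("speed must be >= 0 and wavelength > 0")
        total = np.trapezoid(self.amplitude, self.u_grid)
        if abs(total - 1.0) > _NORM_TOL:
            raise ParameterError(
                f"spectrum integrates to {total:.8g}, not 1; "
                "construct via DopplerSpectrum.from_amplitude"
            )

    @classmethod
    def from_amplitude(cls, u_grid, amplitude, speed, wavelength) -> "DopplerSpectrum":
        u, _ = _as_grid(u_grid)
        amp = np.clip(np.asarray(amplitude, dtype=float), 0.0, None)
        total = np.trapezoid(amp, u)
        if total <= 0:
            raise ParameterError("amplitude has zero integral; cannot normalize")
        return cls(u, amp / total, float(speed), float(wavelength))

    @property
    def du(self) -> float:
        return float(self.u_grid[1] - self.u_grid[0])

    @property
    def omega_scale(self) -> float:
        """rad/s per unit of u."""
        return 2.0 * math.pi * self.speed / self.wavelength

    @property
    def omega_grid(self) -> np.ndarray:
        return self.u_grid * self.omega_scale

    def moment(self, order: int) -> float:
        """Raw moment of u under the distribution (trapezoid rule)."""
        return float(np.trapezoid(self.amplitude * self.u_grid**order, self.u_grid))


@dataclass(frozen=True, eq=False)
class CorrelationCurve:
    """Correlation values on a lag axis starting at zero.

    ``kind`` is one of ``g1_abs`` (|g1|), ``g1_sq`` (|g1|^2), ``g2``.
    """

    lags: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.kind not in ("g1_abs", "g1_sq", "g2"):
            raise ParameterError(f"unknown correlation kind {self.kind!r}")
        if lags.ndim != 1 or lags.size < 1 or lags[0] != 0.0:
            raise ParameterError("lags must be 1-D and start at 0")
        if np.any(np.diff(lags) <= 0):
            raise ParameterError("lags must be strictly increasing")
        if values.shape != lags.shape:
            raise ParameterError("values and lags must have the same shape")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ContrastModel:
    """Model descriptor for contrast-vs-speed predictions.

    ``shape_i``/``shape_s`` are chi (semicircular) or sigma (Gaussian) for the
    illumination and detection spreads; ``exposure`` in seconds; ``beta`` is a
    scalar coherence factor multiplying g2 - 1 (1 for fully developed speckle).
    """

    family: str
    shape_i: float
    shape_s: float
    wavelength: float
    exposure: float
    beta: float = 1.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown density family {self.family!r}")
        if self.shape_i < 0 or self.shape_s < 0:
            raise ParameterError("shape parameters must be nonnegative")
        if self.wavelength <= 0 or self.exposure <= 0:
            raise ParameterError("wavelength and exposure must be positive")
        if not 0 < self.beta <= 1:
            raise ParameterError("beta must lie in (0, 1]")

    def spread_i(self) -> WavevectorSpread:
        return WavevectorSpread(self.family, self.shape_i, "illumination")

    def spread_s(self) -> WavevectorSpread:
        return WavevectorSpread(self.family, self.shape_s, "detection")


@dataclass(frozen=True, eq=False)
class ContrastCurve:
    """Predicted (or measured) contrast per applied speed."""

    speeds: np.ndarray
    contrast: np.ndarray
    model: ContrastModel

    def __post_init__(self):
        speeds = np.asarray(self.speeds, dtype=float)
        contrast = np.asarray(self.contrast, dtype=float)
        if np.any(speeds < 0):
            raise ParameterError("speeds must be nonnegative")
        if contrast.shape != speeds.shape:
            raise ParameterError("contrast and speeds must have the same shape")
        object.__setattr__(self, "speeds", speeds)
        object.__setattr__(self, "contrast", contrast)


# ---------------------------------------------------------------------------
# densities and spectra


def default_u_grid(
    *spreads: WavevectorSpread,
    n_points: int = DEFAULT_GRID_POINTS,
    span_factor: float = DEFAULT_SPAN_FACTOR,
) -> np.ndarray:
    """Uniform grid symmetric about 0 covering the combined spread support."""
    span = span_factor * sum(s.support for s in spreads)
    if span == 0.0:
        span = 1.0  # pure delta: any grid carries the single spike
    return np.linspace(-span, span, n_points)


def wavevector_density(spread: WavevectorSpread, u_grid) -> np.ndarray:
    """Evaluate the spread's density on the grid, renormalized to unit integral.

    The semicircular family has support |u| <= chi; the Gaussian family is
    exp(-(u/sigma)^2).  A zero shape returns a discrete delta: all mass on the
    grid point nearest u = 0.
    """
    u, du = _as_grid(u_grid)
    if spread.shape == 0.0:
        vals = np.zeros_like(u)
        vals[int(np.argmin(np.abs(u)))] = 1.0 / du
        return vals
    if spread.family == "semicircular":
        chi = spread.shape
        arg = chi * chi - u * u
        vals = np.sqrt(np.clip(arg, 0.0, None))
        vals[np.abs(u) > chi] = 0.0
    else:
        vals = np.exp(-((u / spread.shape) ** 2))
    total = np.trapezoid(vals, u)
    if total <= 0:
        raise GridError("grid does not resolve the density support")
    return vals / total


def _convolve_on_grid(p_a, p_b, u_grid) -> tuple[np.ndarray, np.ndarray]:
    u, du = _as_grid(u_grid)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != u.shape or p_b.shape != u.shape:
        raise GridError("densities must live on the provided grid")
    conv = np.convolve(p_a, p_b, mode="full") * du
    n = u.size
    u_out = (np.arange(2 * n - 1) - (n - 1)) * du + (u[0] + u[-1])
    return u_out, conv


def doppler_distribution(p_i, p_s, u_grid, speed, wavelength) -> DopplerSpectrum:
    """Distribution of Doppler shifts: convolution of the two side densities.

    Both densities must be sampled on the same uniform grid and integrate to 1.
    The result lives on an extended grid whose support is the sum of the input
    supports, renormalized to unit integral.
    """
    u_out, conv = _convolve_on_grid(p_i, p_s, u_grid)
    return DopplerSpectrum.from_amplitude(u_out, conv, speed, wavelength)


def doppler_spectrum(
    spread_i: WavevectorSpread,
    spread_s: WavevectorSpread,
    speed: float,
    wavelength: float,
    n_points: int = DEFAULT_GRID_POINTS,
    span_factor: float = DEFAULT_SPAN_FACTOR,
) -> DopplerSpectrum:
    """Build the Doppler distribution directly from two spreads."""
    grid = default_u_grid(spread_i, spread_s, n_points=n_points, span_factor=span_factor)
    p_i = wavevector_density(spread_i, grid)
    p_s = wavevector_density(spread_s, grid)
    return doppler_distribution(p_i, p_s, grid, speed, wavelength)


def power_spectral_density(spectrum: DopplerSpectrum) -> DopplerSpectrum:
    """Self-convolution of the Doppler distribution (even-symmetric)."""
    u_out, conv = _convolve_on_grid(spectrum.amplitude, spectrum.amplitude, spectrum.u_grid)
    return DopplerSpectrum.from_amplitude(u_out, conv, spectrum.speed, spectrum.wavelength)


# ---------------------------------------------------------------------------
# correlation functions


def _check_lags(lags) -> np.ndarray:
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or lags.size < 1 or lags[0] != 0.0:
        raise ParameterError("lags must be a 1-D array starting at 0")
    return lags


def g2_numeric(spectrum: DopplerSpectrum, lags, beta: float = 1.0) -> CorrelationCurve:
    """g2(tau) from a power spectral density via the inverse Fourier transform.

    Evaluates F^-1{P} by trapezoid quadrature at each requested lag and pins
    g2(0) to 1 + beta.  ``spectrum`` should be the power spectral density (the
    self-convolution of the Doppler distribution).
    """
    lags = _check_lags(lags)
    kappa = spectrum.omega_scale
    du = spectrum.du
    if lags[-1] * kappa * du > 0.5:
        warnings.warn(
            "lag range under-resolved by the frequency grid; increase n_points",
            ResolutionWarning,
            stacklevel=2,
        )
    phase = np.exp(1j * np.outer(lags * kappa, spectrum.u_grid))
    ift = np.trapezoid(phase * spectrum.amplitude, dx=du, axis=1)
    scale = ift[0].real
    if abs(ift.imag).max() > 1e-9 * abs(scale):
        warnings.warn(
            "non-negligible imaginary residue; spectrum may be asymmetric",
            ResolutionWarning,
            stacklevel=2,
        )
    excess = np.abs(ift.real) / scale
    return CorrelationCurve(lags, 1.0 + beta * excess, "g2")


def _jinc(x: np.ndarray) -> np.ndarray:
    """2 J1(x) / x, with its series limit 1 - x^2/8 near the origin."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    out[small] = 1.0 - x[small] ** 2 / 8.0
    xs = x[~small]
    out[~small] = 2.0 * special.j1(xs) / xs
    return out


def _b_scale(speed: float, wavelength: float, chi: float) -> float:
    return wavelength / (2.0 * math.pi * speed * chi)


def _check_model_params(speed, wavelength, shape_i, shape_s):
    if speed <= 0:
        raise ParameterError("speed must be positive for a closed-form curve")
    if wavelength <= 0:
        raise ParameterError("wavelength must be positive")
    if shape_i < 0 or shape_s < 0:
        raise ParameterError("shape parameters must be nonnegative")


def g2_semicircular_closed(
    lags, speed, wavelength, chi_i, chi_s, beta: float = 1.0
) -> CorrelationCurve:
    """Closed-form g2 for semicircular wavevector densities.

    g2(tau) = 1 + beta [2 b_i J1(tau/b_i)/tau]^2 [2 b_s J1(tau/b_s)/tau]^2 with
    b = lambda/(2 pi V chi); a zero chi removes its Bessel factor (delta-spread
    limit), and tau = 0 evaluates to exactly 1 + beta by the series limit.
    """
    lags = _check_lags(lags)
    _check_model_params(speed, wavelength, chi_i, chi_s)
    if chi_i == 0.0 and chi_s == 0.0:
        warnings.warn("both spreads are zero: static speckle, g2 is constant", stacklevel=2)
        return CorrelationCurve(lags, np.full_like(lags, 1.0 + beta), "g2")
    g1 = np.ones_like(lags)
    for chi in (chi_i, chi_s):
        if chi > 0.0:
            g1 = g1 * _jinc(lags / _b_scale(speed, wavelength, chi))
    return CorrelationCurve(lags, 1.0 + beta * g1**2, "g2")


def gaussian_decay_rate(speed, wavelength, sigma_i, sigma_s) -> float:
    """a = (2 pi V / lambda)^2 (sigma_i^2 + sigma_s^2), in 1/s^2."""
    return (2.0 * math.pi * speed / wavelength) ** 2 * (sigma_i**2 + sigma_s**2)


def g2_gaussian_closed(
    lags, speed, wavelength, sigma_i, sigma_s, beta: float = 1.0
) -> CorrelationCurve:
    """Closed-form g2 for Gaussian wavevector densities: 1 + beta exp(-a tau^2/2)."""
    lags = _check_lags(lags)
    _check_model_params(speed, wavelength, sigma_i, sigma_s)
    if sigma_i == 0.0 and sigma_s == 0.0:
        warnings.warn("both spreads are zero: static speckle, g2 is constant", stacklevel=2)
        return CorrelationCurve(lags, np.full_like(lags, 1.0 + beta), "g2")
    a = gaussian_decay_rate(speed, wavelength, sigma_i, sigma_s)
    return CorrelationCurve(lags, 1.0 + beta * np.exp(-0.5 * a * lags**2), "g2")


# ---------------------------------------------------------------------------
# exposure-integrated contrast


def contrast_numeric(g1_sq, exposure: float, beta: float = 1.0, points=None) -> float:
    """Contrast from C^2 = beta (2/T) int_0^T (1 - tau/T) |g1|^2 dtau.

    ``g1_sq`` is a callable tau -> |g1(tau)|^2 with g1_sq(0) = 1; adaptive
    quadrature at relative tolerance 1e-8.  ``points`` marks interior decay
    scales for the subdivision (useful when |g1|^2 decays much faster than T).
    """
    if exposure <= 0:
        raise ParameterError("exposure must be positive")
    if abs(g1_sq(0.0) - 1.0) > 1e-6:
        raise ParameterError("g1_sq(0) must equal 1")
    if points is not None:
        points = [p for p in points if 0.0 < p < exposure]
        points = points or None
    val, err = integrate.quad(
        lambda tau: (1.0 - tau / exposure) * g1_sq(tau),
        0.0,
        exposure,
        epsabs=1e-14,
        epsrel=1e-8,
        limit=500,
        points=points,
    )
    if not math.isfinite(val) or err > max(1e-6 * abs(val), 1e-12):
        raise ParameterError("quadrature did not converge for the contrast integral")
    return math.sqrt(max(beta * 2.0 / exposure * val, 0.0))


def contrast_semicircular(
    speed, wavelength, chi_i, chi_s, exposure, beta: float = 1.0
) -> float:
    """Numeric exposure integral for the semicircular family (no closed form)."""
    if speed < 0:
        raise ParameterError("speed must be nonnegative")
    if speed == 0.0 or (chi_i == 0.0 and chi_s == 0.0):
        return math.sqrt(beta)
    _check_model_params(speed, wavelength, chi_i, chi_s)
    scales = [_b_scale(speed, wavelength, chi) for chi in (chi_i, chi_s) if chi > 0.0]

    def g1_sq(tau):
        out = 1.0
        for b in scales:
            out *= _jinc(np.asarray([tau / b])).item()
        return out * out

    b_min = min(scales)
    marks = [m * b_min for m in (1.0, 4.0, 16.0, 64.0, 256.0)]
    return contrast_numeric(g1_sq, exposure, beta=beta, points=marks)


def contrast_gaussian(
    speed, wavelength, sigma_i, sigma_s, exposure, beta: float = 1.0
) -> float:
    """Closed-form contrast for the Gaussian family.

    Uses C^2 = (2/T)[sqrt(pi/(2a)) erf(T sqrt(a/2)) + (exp(-aT^2/2)-1)/(aT)]
    (verified against quadrature of the exposure integral), with the Taylor
    limit C^2 = 1 - aT^2/12 + a^2T^4/120 for a T^2 -> 0.
    """
    if speed < 0:
        raise ParameterError("speed must be nonnegative")
    if exposure <= 0:
        raise ParameterError("exposure must be positive")
    if speed == 0.0 or (sigma_i == 0.0 and sigma_s == 0.0):
        return math.sqrt(beta)
    _check_model_params(speed, wavelength, sigma_i, sigma_s)
    a = gaussian_decay_rate(speed, wavelength, sigma_i, sigma_s)
    T = exposure
    x = a * T * T
    if x < 1e-6:
        c_sq = 1.0 - x / 12.0 + x * x / 120.0
    else:
        c_sq = (2.0 / T) * (
            math.sqrt(math.pi / (2.0 * a)) * math.erf(T * math.sqrt(a / 2.0))
            + (math.exp(-0.5 * x) - 1.0) / (a * T)
        )
    return math.sqrt(max(beta * c_sq, 0.0))


def contrast_at_speed(model: ContrastModel, speed: float) -> float:
    """Single-speed dispatch to the family-specific contrast."""
    if speed < 0:
        raise ParameterError("speed must be nonnegative")
    if speed == 0.0:
        return math.sqrt(model.beta)
    if model.family == "semicircular":
        return contrast_semicircular(
            speed, model.wavelength, model.shape_i, model.shape_s, model.exposure, model.beta
        )
    return contrast_gaussian(
        speed, model.wavelength, model.shape_i, model.shape_s, model.exposure, model.beta
    )


def contrast_curve(speeds, model: ContrastModel) -> ContrastCurve:
    """Predicted contrast for each applied speed (m/s)."""
    speeds = np.atleast_1d(np.asarray(speeds, dtype=float))
    values = np.array([contrast_at_speed(model, v) for v in speeds])
    return ContrastCurve(speeds, values, model)
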