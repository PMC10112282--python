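"""Estimators on speckle stacks: g1, g2, correlation time, speckle diameter.

Correlation curves are estimated against the first frame with spatial
averaging: |g1(tau_k)| = |<E_0 E_k*>| / sqrt(<|E_0|^2><|E_k|^2>) and
g2(tau_k) = <I_0 I_k> / (<I_0><I_k>).  The correlation time tau_c is the lag
at which the excess falls to 1/e of its zero-lag value (linearly interpolated
between bracketing lags); speckle diameter is the FWHM of the
background-subtracted, peak-normalized spatial autocovariance of intensity,
averaged over the two axes.
"""

from __future__ import annotations

import math

import numpy as np

from .doppler_model import CorrelationCurve
from .exceptions import DecayNotReachedError, ParameterError, StackError
from .speckle_sim import SpeckleStack

__all__ = [
    "field_correlation_series",
    "intensity_correlation_series",
    "correlation_time",
    "speckle_diameter",
]


def field_correlation_series(stack: SpeckleStack, all_pairs: bool = False) -> CorrelationCurve:
    """|g1| per lag from a complex-field stack.

    Default estimator references frame 0; ``all_pairs`` averages over all frame
    pairs at each lag for lower variance (at the cost of mixing reference
    states).
    """
    if stack.kind != "field":
        raise StackError("field_correlation_series expects a field stack")
    if stack.n_frames < 2:
        raise StackError("at least 2 frames are required")
    frames = stack.frames.reshape(stack.n_frames, -1)
    powers = np.mean(np.abs(frames) ** 2, axis=1)
    n = stack.n_frames
    values = np.empty(n)
    if all_pairs:
        for k in range(n):
            cross = np.mean(frames[: n - k] * np.conj(frames[k:]), axis=1)
            norm = np.sqrt(powers[: n - k] * powers[k:])
            values[k] = np.mean(np.abs(cross) / norm)
    else:
        ref = frames[0]
        cross = np.abs(np.mean(ref[None, :] * np.conj(frames), axis=1))
        values = cross / np.sqrt(powers[0] * powers)
    return CorrelationCurve(stack.lags, values, "g1_abs")


def intensity_correlation_series(stack: SpeckleStack, all_pairs: bool = False) -> CorrelationCurve:
    """g2 per lag from an intensity stack (spatial-mean estimator)."""
    if stack.kind != "intensity":
        raise StackError("intensity_correlation_series expects an intensity stack")
    if stack.n_frames < 2:
        raise StackError("at least 2 frames are required")
    frames = stack.frames.reshape(stack.n_frames, -1)
    means = frames.mean(axis=1)
    if np.any(means <= 0):
        raise StackError("a frame has zero mean intensity; g2 undefined")
    n = stack.n_frames
    if all_pairs:
        values = np.empty(n)
        for k in range(n):
            num = np.mean(frames[: n - k] * frames[k:], axis=1)
            values[k] = np.mean(num / (means[: n - k] * means[k:]))
    else:
        ref = frames[0]
        values = np.mean(ref[None, :] * frames, axis=1) / (means[0] * means)
    return CorrelationCurve(stack.lags, values, "g2")


def correlation_time(curve: CorrelationCurve) -> float:
    """Lag at which the correlation excess falls to 1/e of its lag-0 value.

    For g2 curves the threshold applies to the normalized excess
    (g2 - 1)/(g2(0) - 1), which makes the result invariant to a constant
    coherence factor; for |g1| and |g1|^2 curves it is the absolute 1/e level
    of the value itself.  The crossing is linearly interpolated; a curve that
    starts at or below the threshold returns 0; one that never crosses raises
    :class:`DecayNotReachedError` carrying the last available lag.
    """
    if curve.kind == "g2":
        excess = curve.values - 1.0
        if excess[0] <= 0:
            raise ParameterError("no correlation excess at lag 0")
        y = excess / excess[0]
    else:
        y = curve.values.copy()
    threshold = 1.0 / math.e
    if y[0] <= threshold:
        return 0.0
    below = np.nonzero(y <= threshold)[0]
    if below.size == 0:
        raise DecayNotReachedError(float(curve.lags[-1]))
    j = int(below[0])
    frac = (y[j - 1] - threshold) / (y[j - 1] - y[j])
    return float(curve.lags[j - 1] + frac * (curve.lags[j] - curve.lags[j - 1]))


def _profile_fwhm(profile: np.ndarray, center: int) -> float:
    """FWHM of a peak-normalized 1-D profile, sub-pixel by linear interpolation."""

    def half_crossing(values):
        # values[0] is the peak (1.0); walk outward to the first drop below 0.5
        for i in range(1, len(values)):
            if values[i] < 0.5:
                frac = (values[i - 1] - 0.5) / (values[i - 1] - values[i])
                return (i - 1) + frac
        raise ParameterError("autocovariance never falls below half maximum")

    right = half_crossing(profile[center:])
    left = half_crossing(profile[center::-1])
    return left + right


def speckle_diameter(image) -> float:
    """Speckle diameter (px) from the spatial autocovariance of an intensity image.

    The mean is subtracted (background removal), the circular autocovariance is
    computed by FFT and peak-normalized, and the FWHM of the central row and
    column profiles is averaged.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D")
    fluct = img - img.mean()
    if not np.any(fluct):
        raise ParameterError("flat image: speckle diameter undefined")
    acov = np.fft.ifft2(np.abs(np.fft.fft2(fluct)) ** 2).real
    acov = np.fft.fftshift(acov)
    r0, c0 = img.shape[0] // 2, img.shape[1] // 2
    acov = acov / acov[r0, c0]
    return 0.5 * (_profile_fwhm(acov[r0, :], c0) + _profile_fwhm(acov[:, c0], r0))
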