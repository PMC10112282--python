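"""Phasor-sum simulation of time-varying speckle.

Each pixel carries ``N`` unit phasors (default 50) with independent uniform
phases on [-pi, pi] and angular frequencies drawn from the Doppler
distribution; the complex field is

    E(x, y, t) = (1/sqrt(N)) * sum_n exp(i (omega_n(x,y) t + phi_n(x,y))),

so each speckle occupies one pixel, the mean intensity is 1 by construction,
and a single frame is fully developed speckle (contrast ~ 1).  Frequencies and
phases are drawn once per pixel and held constant over the stack.  Exposure
integration is a plain average of consecutive frames times the exposure time;
there is no camera noise or quantization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .doppler_model import DopplerSpectrum
from .exceptions import ParameterError, StackError

__all__ = [
    "SpeckleStack",
    "SimConfig",
    "sample_doppler_frequencies",
    "simulate_field_stack",
    "intensity_stack",
    "integrate_exposure",
    "spatial_contrast",
]


@dataclass(frozen=True, eq=False)
class SpeckleStack:
    """Time-ordered frames with a fixed frame interval.

    ``kind`` is ``field`` (complex amplitudes) or ``intensity`` (nonnegative).
    """

    frames: np.ndarray
    frame_interval: float
    kind: str

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise StackError("frames must be a 3-D (time, rows, cols) array")
        if self.frame_interval <= 0:
            raise StackError("frame_interval must be positive")
        if self.kind not in ("field", "intensity"):
            raise StackError(f"unknown stack kind {self.kind!r}")
        if self.kind == "intensity" and np.any(frames.real < 0):
            raise StackError("intensity frames must be nonnegative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one dynamic-speckle stack."""

    doppler: DopplerSpectrum
    duration: float
    shape: tuple[int, int] = (100, 100)
    phasor_count: int = 50
    frame_rate: float = 10_000.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ParameterError("shape must be (rows, cols) with positive sizes")
        if self.phasor_count < 2:
            raise ParameterError("phasor_count must be at least 2")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ParameterError("frame_rate and duration must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def sample_doppler_frequencies(
    spectrum: DopplerSpectrum, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw angular frequencies (rad/s) weighted by the Doppler distribution.

    Inverse-CDF sampling on the spectrum's grid with uniform jitter inside each
    bin; jitter is suppressed when the spectrum is a single-bin delta so the
    delta limit samples its frequency exactly.  Reproducible for a given
    generator state.
    """
    if count < 1:
        raise ParameterError("count must be at least 1")
    weights = spectrum.amplitude
    total = weights.sum()
    if total <= 0:
        raise ParameterError("spectrum amplitude has zero mass; cannot sample")
    cdf = np.cumsum(weights) / total
    idx = np.searchsorted(cdf, rng.random(count), side="left")
    u = spectrum.u_grid[idx]
    if np.count_nonzero(weights) > 1:
        u = u + (rng.random(count) - 0.5) * spectrum.du
    return u * spectrum.omega_scale


def simulate_field_stack(cfg: SimConfig) -> SpeckleStack:
    """Generate the complex-field stack for a simulation configuration.

    Deterministic for a given seed: identical configs give bit-identical
    stacks.
    """
    n_frames = cfg.n_frames
    if n_frames < 2:
        raise StackError(
            f"duration {cfg.duration:g} s at {cfg.frame_rate:g} Hz yields "
            f"{n_frames} frame(s); at least 2 are required"
        )
    rows, cols = cfg.shape
    npix = rows * cols
    n = cfg.phasor_count
    rng = np.random.default_rng(cfg.seed)
    omega = sample_doppler_frequencies(cfg.doppler, npix * n, rng).reshape(npix, n)
    phases = rng.uniform(-math.pi, math.pi, size=(npix, n))
    dt = 1.0 / cfg.frame_rate

    # advance each phasor by a per-frame rotation instead of re-evaluating
    # exp(i omega t); unit-modulus drift over the stack is O(n_frames * eps)
    phasors = np.exp(1j * phases) / math.sqrt(n)
    step = np.exp(1j * omega * dt)
    frames = np.empty((n_frames, rows, cols), dtype=np.complex128)
    for k in range(n_frames):
        frames[k] = phasors.sum(axis=1).reshape(rows, cols)
        if k < n_frames - 1:
            phasors *= step
    return SpeckleStack(frames, dt, "field")


def intensity_stack(stack: SpeckleStack) -> SpeckleStack:
    """|E|^2 per voxel; converts a field stack to an intensity stack."""
    if stack.kind != "field":
        raise StackError("intensity_stack expects a field stack")
    return SpeckleStack(np.abs(stack.frames) ** 2, stack.frame_interval, "intensity")


def integrate_exposure(stack: SpeckleStack, exposure: float) -> np.ndarray:
    """Time-integrated intensity over [0, T]: frame average times T.

    T must not exceed the stack duration; a T that is not a whole number of
    frame intervals is truncated with a warning.
    """
    if stack.kind != "intensity":
        raise StackError("integrate_exposure expects an intensity stack")
    if exposure <= 0:
        raise ParameterError("exposure must be positive")
    if exposure > stack.duration * (1 + 1e-9):
        raise ParameterError(
            f"exposure {exposure:g} s exceeds stack duration {stack.duration:g} s"
        )
    n_int = exposure * stack.frame_rate
    n = int(round(n_int))
    if abs(n_int - n) > 1e-6:
        n = int(n_int)
        warnings.warn(
            "exposure is not a whole number of frame intervals; truncating",
            stacklevel=2,
        )
    n = max(n, 1)
    return stack.frames[:n].mean(axis=0) * exposure


def spatial_contrast(image, window: tuple[int, int] | None = None) -> float:
    """Spatial contrast sigma/mean of a time-integrated intensity image.

    ``window`` crops a centered (rows, cols) region first (e.g. the 90 x 90
    analysis window); ``None`` uses the full image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D")
    if np.any(img < 0):
        raise ParameterError("image must be nonnegative")
    if window is not None:
        wr, wc = window
        rows, cols = img.shape
        if wr > rows or wc > cols or min(wr, wc) < 2:
            raise ParameterError(f"window {window} does not fit image {img.shape}")
        r0 = (rows - wr) // 2
        c0 = (cols - wc) // 2
        img = img[r0 : r0 + wr, c0 : c0 + wc]
    mean = img.mean()
    if mean <= 0:
        raise ParameterError("window mean is zero; contrast undefined")
    return float(img.std(ddof=1) / mean)
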