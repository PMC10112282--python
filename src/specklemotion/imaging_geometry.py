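"""Single-lens imaging geometry: shape parameters, Fresnel number, pupil filter.

The detection-side spread equals the aperture half-angle seen from the object,
chi_s = a_s / z1; scrambled-wave illumination through a diffuser at distance d
from the fiber tip gives chi_i = d * NA_fiber / z1.  The aperture radius
follows from the f-number as a_s = f / (2 N).  The Fresnel number
N_F = a_s^2 / (lambda z1) indicates the near-field regime when >~ 1, under
which the lens transfer function reduces to pure phase terms plus the pupil
low-pass; only the latter affects speckle size, so simulated speckle can be
generated directly on the image screen and low-pass filtered with the pupil
mask.  A centered square aperture is used in the frequency domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import ParameterError

__all__ = ["LensSystem", "GeometryDerived", "derive_geometry", "pupil_filter"]


@dataclass(frozen=True)
class LensSystem:
    """Instrument description; lengths in meters, all optional except wavelength.

    Give the aperture either as ``aperture_radius`` or via ``f_number`` (with
    ``focal_length``), not both.
    """

    wavelength: float
    z1: float | None = None
    z2: float | None = None
    focal_length: float | None = None
    aperture_radius: float | None = None
    f_number: float | None = None
    fiber_distance: float | None = None
    fiber_na: float | None = None

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ParameterError("wavelength must be positive")
        if self.aperture_radius is not None and self.f_number is not None:
            raise ParameterError(
                "give at most one of aperture_radius and f_number; the other is derived"
            )
        for name in ("z1", "z2", "focal_length", "aperture_radius", "f_number",
                     "fiber_distance", "fiber_na"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ParameterError(f"{name} must be positive when given")


@dataclass(frozen=True)
class GeometryDerived:
    """Derived parameters; fields are None when their inputs were not given."""

    aperture_radius: float
    numerical_aperture: float | None
    fresnel_number: float | None
    chi_s: float | None
    chi_i: float
    magnification_check: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def derive_geometry(system: LensSystem) -> GeometryDerived:
    """Map a lens system to model shape parameters and diagnostics.

    a_s = f/(2 N_f) when the f-number is given; NA = a_s/z2; chi_s = a_s/z1;
    chi_i = d * NA_fiber / z1 when a diffuser distance is given, else 0;
    N_F = a_s^2/(lambda z1); magnification_check = z2/z1 (reported, not
    enforced against a measured magnification).
    """
    if system.aperture_radius is not None:
        a_s = system.aperture_radius
    elif system.f_number is not None:
        if system.focal_length is None:
            raise ParameterError(
                "aperture radius needs either aperture_radius, or f_number "
                "together with focal_length"
            )
        a_s = system.focal_length / (2.0 * system.f_number)
    else:
        raise ParameterError(
            "aperture radius needs either aperture_radius, or f_number "
            "together with focal_length"
        )

    z1, z2 = system.z1, system.z2
    na = a_s / z2 if z2 is not None else None
    chi_s = a_s / z1 if z1 is not None else None
    fresnel = a_s**2 / (system.wavelength * z1) if z1 is not None else None
    mag = z2 / z1 if (z1 is not None and z2 is not None) else None

    chi_i = 0.0
    if system.fiber_distance is not None:
        if system.fiber_na is None or z1 is None:
            raise ParameterError("chi_i needs fiber_distance, fiber_na and z1")
        chi_i = system.fiber_distance * system.fiber_na / z1

    return GeometryDerived(a_s, na, fresnel, chi_s, chi_i, mag)


def pupil_filter(frame, aperture_halfwidth_px: int) -> np.ndarray:
    """Low-pass a complex field frame with a centered square pupil mask.

    The frame is Fourier transformed, multiplied by a centered square mask of
    side 2*halfwidth pixels (DC bin included), and transformed back.  Energy
    outside the mask is removed, so the output speckle grain size is inversely
    proportional to the mask side.  A mask at least as large as the grid is an
    identity (with a warning when strictly larger).
    """
    f = np.asarray(frame)
    if f.ndim != 2:
        raise ParameterError("frame must be 2-D")
    hw = int(aperture_halfwidth_px)
    if hw < 1:
        raise ParameterError("aperture_halfwidth_px must be at least 1")
    rows, cols = f.shape
    side = 2 * hw
    if side >= rows and side >= cols:
        if side > max(rows, cols):
            warnings.warn(
                "pupil mask larger than the frequency grid; returning input",
                stacklevel=2,
            )
        return np.array(f, dtype=np.complex128)

    spec = np.fft.fftshift(np.fft.fft2(f))
    mask = np.zeros((rows, cols))
    r0, c0 = rows // 2, cols // 2
    mask[max(r0 - hw, 0) : r0 + hw, max(c0 - hw, 0) : c0 + hw] = 1.0
    return np.fft.ifft2(np.fft.ifftshift(spec * mask))
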