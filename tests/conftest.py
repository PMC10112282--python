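import numpy as np
import pytest

import specklemotion as sm

WAVELENGTH = 671e-9
CHI_S_HIGHSPEED = 26.5e-4


def build_spectrum(family, shape_i, shape_s, speed, wavelength=WAVELENGTH, **kw):
    return sm.doppler_spectrum(
        sm.WavevectorSpread(family, shape_i, "illumination"),
        sm.WavevectorSpread(family, shape_s, "detection"),
        speed,
        wavelength,
        **kw,
    )


@pytest.fixture(scope="session")
def gaussian_field_stack():
    """128x128 stack, Gaussian model sigma_i=0, sigma_s=26.5e-4, V=5 mm/s, 10 kHz."""
    speed = 5e-3
    a = (2 * np.pi * speed / WAVELENGTH) ** 2 * CHI_S_HIGHSPEED**2
    tau_c = np.sqrt(2.0 / a)
    spectrum = build_spectrum("gaussian", 0.0, CHI_S_HIGHSPEED, speed)
    cfg = sm.SimConfig(doppler=spectrum, duration=2.5 * tau_c, shape=(128, 128), seed=20260924)
    return sm.simulate_field_stack(cfg), speed, a


@pytest.fixture(scope="session")
def static_frame_90px():
    """Single fully developed 90x90 speckle field frame (static phasor sum)."""
    spectrum = build_spectrum("semicircular", 0.0, 0.0, 0.0)
    cfg = sm.SimConfig(doppler=spectrum, duration=2e-4, shape=(90, 90), seed=7)
    return sm.simulate_field_stack(cfg).frames[0]
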