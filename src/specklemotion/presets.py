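"""Named experiment presets and reproducible end-to-end drivers.

Two instrument configurations are covered: a high-speed setup (671 nm laser,
0.8 mm aperture, z2 = 34.3 mm, z1 = 15.1 cm for the matte surface and
15.4 cm for the Delrin plate, 10 kHz camera) and a low-framerate LSCI setup
(f = 16 mm objective at f-number 8, hence a 1 mm aperture radius, z1 = 20 cm,
50 Hz camera, 10 ms exposure).  Scrambled-wave illumination through a diffuser
at distance d from the fiber tip (fiber NA 0.12) sets the illumination spread
chi_i = d NA / z1; planar or spherical illumination sets chi_i = 0.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as smio
from .doppler_model import (
    ContrastModel,
    contrast_curve,
    doppler_spectrum,
    g2_gaussian_closed,
    g2_semicircular_closed,
)
from .exceptions import ParameterError
from .imaging_geometry import LensSystem, derive_geometry
from .speckle_sim import (
    SimConfig,
    integrate_exposure,
    intensity_stack,
    simulate_field_stack,
    spatial_contrast,
)

__all__ = ["ExperimentPreset", "PRESETS", "run_preset"]

#: Sampling rate (Hz) used to resolve intensity dynamics within one exposure.
SIM_FRAME_RATE = 10_000.0


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    medium: str
    illumination: str  # planar | spherical | scrambled
    family: str
    wavelength: float
    aperture_radius: float
    z1: float
    z2: float | None
    camera_frame_rate: float
    exposure: float
    speeds_mm_s: tuple[float, ...]
    fiber_distance: float | None = None
    fiber_na: float | None = None
    grid: tuple[int, int] = (100, 100)
    window: tuple[int, int] = (90, 90)
    seed: int = 0
    beta: float = 1.0

    def lens_system(self) -> LensSystem:
        return LensSystem(
            wavelength=self.wavelength,
            z1=self.z1,
            z2=self.z2,
            aperture_radius=self.aperture_radius,
            fiber_distance=self.fiber_distance,
            fiber_na=self.fiber_na,
        )

    def resolve(self) -> dict:
        """Full resolved parameter set: inputs plus derived shape parameters."""
        derived = derive_geometry(self.lens_system())
        out = dataclasses.asdict(self)
        out.update(
            chi_i=derived.chi_i,
            chi_s=derived.chi_s,
            numerical_aperture=derived.numerical_aperture,
            fresnel_number=derived.fresnel_number,
            sim_frame_rate=SIM_FRAME_RATE,
        )
        return out

    def model(self) -> ContrastModel:
        derived = derive_geometry(self.lens_system())
        return ContrastModel(
            family=self.family,
            shape_i=derived.chi_i,
            shape_s=derived.chi_s,
            wavelength=self.wavelength,
            exposure=self.exposure,
            beta=self.beta,
        )


_HS = dict(
    wavelength=671e-9,
    aperture_radius=0.4e-3,
    z2=34.3e-3,
    camera_frame_rate=10_000.0,
    exposure=10e-3,
    speeds_mm_s=(0.0, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0),
)
_LF = dict(
    wavelength=671e-9,
    aperture_radius=1.0e-3,  # f = 16 mm at f-number 8
    z1=200e-3,
    z2=None,
    camera_frame_rate=50.0,
    exposure=10e-3,
    speeds_mm_s=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
)

PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in [
        ExperimentPreset(
            name="highspeed-matte-spherical",
            description="High-speed imaging, matte surface, spherical illumination",
            medium="matte",
            illumination="spherical",
            family="semicircular",
            z1=151e-3,
            **_HS,
        ),
        ExperimentPreset(
            name="highspeed-delrin-spherical",
            description="High-speed imaging, Delrin plate, spherical illumination",
            medium="delrin",
            illumination="spherical",
            family="semicircular",
            z1=154e-3,
            **_HS,
        ),
        ExperimentPreset(
            name="lowframerate-matte-planar",
            description="Low-framerate LSCI, matte surface, planar illumination",
            medium="matte",
            illumination="planar",
            family="semicircular",
            **_LF,
        ),
        ExperimentPreset(
            name="lowframerate-delrin-planar",
            description="Low-framerate LSCI, Delrin plate, planar illumination",
            medium="delrin",
            illumination="planar",
            family="semicircular",
            **_LF,
        ),
        ExperimentPreset(
            name="lowframerate-matte-scrambled-d13.5",
            description="Low-framerate LSCI, matte, diffuser 13.5 mm from fiber tip",
            medium="matte",
            illumination="scrambled",
            family="semicircular",
            fiber_distance=13.5e-3,
            fiber_na=0.12,
            **_LF,
        ),
        ExperimentPreset(
            name="lowframerate-matte-scrambled-d36",
            description="Low-framerate LSCI, matte, diffuser 36 mm from fiber tip",
            medium="matte",
            illumination="scrambled",
            family="semicircular",
            fiber_distance=36e-3,
            fiber_na=0.12,
            **_LF,
        ),
        ExperimentPreset(
            name="lowframerate-matte-scrambled-d56.1",
            description="Low-framerate LSCI, matte, diffuser 56.1 mm from fiber tip",
            medium="matte",
            illumination="scrambled",
            family="semicircular",
            fiber_distance=56.1e-3,
            fiber_na=0.12,
            **_LF,
        ),
    ]
}


def _theory_g2(model: ContrastModel, speed: float, n_lags: int = 200):
    """Closed-form g2 over three decay times at the given speed."""
    if model.family == "gaussian":
        from .doppler_model import gaussian_decay_rate

        a = gaussian_decay_rate(speed, model.wavelength, model.shape_i, model.shape_s)
        tau_c = math.sqrt(2.0 / a)
        lags = np.linspace(0.0, 3.0 * tau_c, n_lags)
        return g2_gaussian_closed(
            lags, speed, model.wavelength, model.shape_i, model.shape_s, model.beta
        )
    b_s = model.wavelength / (2.0 * math.pi * speed * model.shape_s)
    lags = np.linspace(0.0, 3.0 * 1.93 * b_s, n_lags)
    return g2_semicircular_closed(
        lags, speed, model.wavelength, model.shape_i, model.shape_s, model.beta
    )


def run_preset(
    name: str,
    output_dir,
    overrides: dict | None = None,
    simulate: bool = False,
    n_seeds: int = 10,
    force: bool = False,
) -> dict:
    """Run a named preset: theory curves, optional simulation, metadata.

    Writes ``contrast_theory.csv``, ``g2_theory.csv`` and ``metadata.json`` to
    ``output_dir``; with ``simulate=True`` additionally simulates speckle
    stacks per speed (averaging spatial contrast over ``n_seeds`` seeds),
    writes ``contrast_simulated.csv`` and a sample intensity stack
    ``stack_v{max}.tif``.  Returns the resolved metadata dict.
    """
    if name not in PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    preset = PRESETS[name]
    if overrides:
        preset = dataclasses.replace(preset, **overrides)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = ["contrast_theory.csv", "g2_theory.csv", "metadata.json"]
    if simulate:
        targets.append("contrast_simulated.csv")
    existing = [t for t in targets if (out / t).exists()]
    if existing and not force:
        raise ParameterError(
            f"output files {existing} already exist in {out}; use force to overwrite"
        )

    resolved = preset.resolve()
    model = preset.model()
    meta = {
        "preset": preset.name,
        "family": model.family,
        "chi_i" if model.family == "semicircular" else "sigma_i": model.shape_i,
        "chi_s" if model.family == "semicircular" else "sigma_s": model.shape_s,
        "wavelength_m": model.wavelength,
        "exposure_s": model.exposure,
        "beta": model.beta,
    }

    speeds = np.array(preset.speeds_mm_s) * 1e-3
    theory = contrast_curve(speeds, model)
    smio.write_curve_csv(
        out / "contrast_theory.csv",
        {"speed_m_per_s": theory.speeds, "contrast": theory.contrast},
        meta,
    )

    ref_speed = float(np.median(speeds[speeds > 0])) if np.any(speeds > 0) else 5e-3
    g2 = _theory_g2(model, ref_speed)
    smio.write_curve_csv(
        out / "g2_theory.csv",
        {"lag_s": g2.lags, "g2": g2.values},
        {**meta, "speed_m_per_s": ref_speed},
    )

    sim_results = None
    if simulate:
        sim_means = []
        for v in speeds:
            contrasts = []
            for k in range(n_seeds):
                seed = (preset.seed * 100_003 + int(round(v * 1e6)) * 13 + k) % (2**31)
                spectrum = doppler_spectrum(
                    model.spread_i(), model.spread_s(), max(v, 0.0), model.wavelength
                )
                cfg = SimConfig(
                    doppler=spectrum,
                    duration=model.exposure,
                    shape=preset.grid,
                    frame_rate=SIM_FRAME_RATE,
                    seed=seed,
                )
                field = simulate_field_stack(cfg)
                image = integrate_exposure(intensity_stack(field), model.exposure)
                contrasts.append(spatial_contrast(image, preset.window))
            sim_means.append(float(np.mean(contrasts)))
        sim_results = np.array(sim_means)
        smio.write_curve_csv(
            out / "contrast_simulated.csv",
            {"speed_m_per_s": speeds, "contrast": sim_results},
            {**meta, "n_seeds": n_seeds, "base_seed": preset.seed},
        )
        v_max = float(speeds.max())
        spectrum = doppler_spectrum(
            model.spread_i(), model.spread_s(), v_max, model.wavelength
        )
        cfg = SimConfig(
            doppler=spectrum,
            duration=model.exposure,
            shape=preset.grid,
            frame_rate=SIM_FRAME_RATE,
            seed=preset.seed,
        )
        stack = intensity_stack(simulate_field_stack(cfg))
        smio.write_stack_tiff(out / f"stack_v{v_max * 1e3:g}mmps.tif", stack)

    metadata = {
        "preset": preset.name,
        **resolved,
        "outputs": targets,
        "n_seeds": n_seeds if simulate else 0,
    }
    smio.write_json(out / "metadata.json", metadata)
    return metadata
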