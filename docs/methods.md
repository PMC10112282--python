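# Methods

## Physical model

A rigid object of high scattering level translates at constant speed `V` in
its own plane under coherent illumination (wavelength λ). Each illumination
wavevector `k_i` and detection wavevector `k_s` pair contributes an optical
Doppler shift `ω_D = v·(k_s − k_i)`. Because intensity fluctuations are driven
by *differences* between Doppler shifts, only the spreads of the wavevector
cones matter, not their absolute tilt. Both spreads are modeled as probability
densities over the dimensionless normalized frequency `u = ω_D λ/(2πV)`:

* `semicircular`, half-width χ: `p(u) ∝ √(1 − (u/χ)²)` on |u| ≤ χ;
* `gaussian`, width σ: `p(u) ∝ exp(−(u/σ)²)` (note the variance is σ²/2).

Zero shape is the delta limit: planar or spherical illumination (a single
`k_i` per point) or pinhole detection.

The Doppler distribution is the convolution `A = p_i * p_s`, the power
spectral density is the self-convolution `P = A * A`, and Wiener–Khinchin
gives `g²(τ) − 1 = β·F⁻¹{P}(τ)/F⁻¹{P}(0)`. With the standard Siegert relation
`|g¹|² = g² − 1`, the contrast of intensity integrated over an exposure `T` is

    C² = β (2/T) ∫₀ᵀ (1 − τ/T) |g¹(τ)|² dτ.

Closed forms follow from the characteristic functions of the densities: the
Wigner semicircle gives `2J₁(x)/x` factors with `x = τ/b`, `b = λ/(2πVχ)`; the
Gaussian gives `exp(−aτ²/2)` with `a = (2πV/λ)²(σ_i² + σ_s²)` and the erf-form
contrast. The Gaussian closed form is verified against adaptive quadrature of
the exposure integral to relative 1e−6 in the test suite; the semicircular
contrast has no closed form and is always evaluated by quadrature.

Key consequences, all asserted as tests: `g²(0) = 2` exactly (β = 1) and
`g² ∈ [1, 2]`; `C(V=0) = 1`; `C` strictly decreasing in `V`, in each spread,
and in `T`; every correlation/contrast output depends on `V` and the spreads
only through the products `V·χ` (equivalently `V·σ`) at fixed λ and T; and
`C ∝ 1/√V` once the decorrelation is much faster than the exposure.

## Scope and assumptions

The model holds for translation over media of effectively infinite scattering
level under any of the treated illumination types, and for finite-scattering
media (e.g. an acetal/Delrin phantom) under planar illumination only — for
spherical or scrambled illumination on finite-scattering media the range of
light-injection positions per detection point requires Monte-Carlo photon
transport, which is out of scope. Rotation and tilt of wavefronts, dynamic
(perfused) media, and fitting of experimental perfusion data are likewise out
of scope. Partially developed speckle (residual specular reflection) is
represented only by the scalar coherence factor β ∈ (0, 1] multiplying
`g² − 1`; with β < 1 the zero-speed contrast is √β.

## Numerical choices

* **Frequency grids.** Densities and spectra live on uniform grids symmetric
  about u = 0 with 4097 points by default (odd, so u = 0 is a grid point —
  needed for exact delta spreads and even symmetry), spanning 1.2× the
  combined support (a Gaussian is assigned 5σ of support). Convolutions are
  discrete linear convolutions rescaled by the grid step and renormalized to
  unit integral (tolerance 1e−6); renormalization also makes the densities'
  printed normalization constants irrelevant.
* **Delta spreads** (shape = 0) are never represented as numerically narrow
  densities in the closed forms; their Bessel/Gaussian factor is removed
  analytically. On a grid a delta is a single spike of weight 1/Δu at u = 0.
* **g² via Fourier.** `g2_numeric` evaluates F⁻¹{P} by trapezoid quadrature at
  the requested lags and pins g²(0) to 1 + β; a warning is emitted when
  `max(lag)·(2πV/λ)·Δu > 0.5` (grid too coarse for the lag range).
* **Quadrature.** The contrast integral uses adaptive Gauss–Kronrod with
  relative tolerance 1e−8; the integrand's τ→0 limit is supplied analytically
  (`2J₁(x)/x → 1 − x²/8`), and interior break points at multiples of the
  shortest decay scale `b` guide the subdivision when decay is much faster
  than T. For `aT² < 1e−6` the Gaussian contrast uses the Taylor limit
  `C² = 1 − aT²/12 + a²T⁴/120` to avoid cancellation.
* **Correlation time.** τ_c is the linearly interpolated first crossing of the
  1/e level — of the normalized excess `(g²−1)/(g²(0)−1)` for g² curves
  (invariant to β), of the value itself for |g¹|-type curves. A curve that
  never crosses raises an error carrying the last available lag.
* **Speckle diameter.** FWHM of the mean-subtracted, peak-normalized circular
  spatial autocovariance (FFT-based), averaged over the central row and
  column, sub-pixel by linear interpolation. FWHM is used because the
  half-maximum criterion is the standard, robust width measure for
  autocorrelation peaks.

## Simulator

Each pixel is an independent speckle: `N = 50` unit phasors with phases
uniform on [−π, π] and angular frequencies drawn from `A` by inverse-CDF
sampling with uniform within-bin jitter (jitter is suppressed for a
single-bin delta spectrum so the static limit is exact). Frequencies and
phases are drawn once per pixel and held fixed; frames advance each phasor by
a per-frame rotation `exp(iωΔt)` (Δt = 1/10 kHz by default), which is exact up
to accumulated float roundoff of order `n_frames·ε`. The mean intensity is 1
by construction and a single frame is fully developed speckle with contrast
`√(1 − 1/N) ≈ 0.99` — the ~0.01 finite-phasor bias visible in all simulated
contrasts. Exposure integration is the average of the first `⌊T·f⌋` frames
times T (e.g. 100 frames for 10 ms at 10 kHz); there is no intra-frame motion
blur, camera noise, or quantization. Stacks are bit-reproducible for a given
seed.

Because speckles are generated directly on the detector at one pixel per
speckle, spatial diffraction does not enter the temporal statistics; the
single-lens pupil is applied, when wanted, as a centered square low-pass mask
on the shifted 2-D FFT of each frame (the lens transfer function's pure-phase
terms are omitted since they do not affect contrast). The grain diameter of
the filtered speckle scales as ~80/m pixels for mask side m on a 90-px grid
(Fourier reciprocity): 46 px → ≈2 px grains, matching the reference
instrument's measured grain; 4 px → ≈20 px grains.

### What the simulator does and does not emulate

It emulates fully developed, polarized, unit-mean dynamic speckle whose
temporal statistics follow exactly the Doppler distribution fed in — that is
the point: theory (closed forms) and simulation (phasor sums + estimators)
share only `A`, so their agreement validates the derivation of the g² and C
formulas, not the Doppler hypothesis itself. It does not emulate detector
noise, finite pixel fill, partially developed speckle, speckle larger than a
pixel during acquisition, vibration, or media with finite scattering depth;
passing tests therefore bound the mathematics, not every experimental
imperfection.

## Estimators

`g¹` and `g²` are spatial-average estimators against frame 0 (an all-pairs
variant exists behind a flag for variance reduction but is not the default,
to keep the reference-frame semantics). At 128×128 px the single-seed
estimator noise is ~0.015 and the finite-N bias at lag 0 is `−1/N ≈ −0.02`,
so theory/simulation agreement is asserted at 0.05 (g² curves, 3-seed
averages) and 0.02 (contrast vs speed, 10-seed averages over a 90×90 window).

## Problem sizes

Validation runs use 128×128 px stacks over 2.5 decay times for correlation
curves, and 100×100 px, 100-frame stacks (10 ms at 10 kHz) for contrast, with
a 90×90 analysis window — large enough that estimator noise sits well inside
the asserted tolerances while keeping the full sweep (2 families × 4
illumination spreads × 7 speeds × 10 seeds) comfortably reproducible on a
single CPU.

## Known limitations

* The semicircular family's contrast requires quadrature; extremely small
  `V·χ` products (decay times ≫ T) are handled by the Taylor/static limits,
  but intermediate regimes rely on the quadrature tolerance.
* The reference-frame g² estimator is biased low at lag 0 by the finite phasor
  count and noisy at large lags for small grids; use more seeds or the
  all-pairs variant for quantitative tails.
* Geometry outputs that lack inputs (e.g. NA without z2) are reported as
  `None` rather than raising, so partial configurations can still be derived;
  the measured magnification is reported as z2/z1 but never enforced.
* The pupil filter uses a square aperture (as in the reference instrument
  analysis); no circular/Airy pupil, aberrations, or full Fresnel propagation.
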