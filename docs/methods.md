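# Methods

## Model

Two non-interfering beams of the same wavelength are focused coaxially and
confocally to a shared waist `w0` at the focal plane: a TEM00 Gaussian
carrying power `P_G` and an LG01 donut carrying `P_D`.  Non-interference is
the physical assumption that lets the model work entirely with average
intensities (experimentally it would be enforced with opposite circular
polarizations); the donut's helical phase `e^{iθ}` is implemented in
`donut_field_amplitude` for completeness but enters no downstream result.

Both intensities are sinusoidally modulated at angular frequency ω with a
π-radian phase offset between them:

    I_G(r,t) = I_G(r) [1 + m cos ωt],   I_D(r,t) = I_D(r) [1 − m cos ωt].

The absorbed power density is `μ_a` times the total intensity; its Fourier
component at ω — the part that drives the detected photoacoustic pressure
in a lock-in scheme — has spatial amplitude `μ_a m |I_G(r) − I_D(r)|`.
This is the *effective excitation profile*.  The model is linear
throughout: no absorption saturation, no thermal nonlinearity, and the
acoustic propagation itself is not solved — only the proportionality of
the pressure amplitude to the local absorbed AC energy is used, which holds
under thermal and stress confinement in a homogeneous medium.

In the reduced coordinate `x = 2r²/w0²` and with `P_D = 1`, `P_G = γ`, the
effective profile is `(2 μ_a m / π w0²) |γ − x| e^{−x}`.  All metrics are
computed in `x` (exact, grid-free) and converted to radius only at the
boundary:

- central peak `γ` at `x = 0`; zero crossing at `x = γ`;
- half-max root of `(γ − x) e^{−x} = γ/2`, bracketed on `[0, γ]` (the
  function is monotone there since its derivative `−e^{−x}(1 + γ − x)` is
  negative for `x < 1 + γ`), solved by Brent's method with `xtol = 1e−12`;
  FWHM `= 2 w0 √(x/2)`;
- side lobe at `x = 1 + γ` with value `e^{−(1+γ)}`, hence side-lobe ratio
  `e^{−(1+γ)}/γ` — derived by differentiating `(x − γ) e^{−x}`, and
  cross-checked numerically in the tests.

The *optimal* power ratio is operationalized as the smallest γ on the
sweep grid whose side-lobe ratio does not exceed a threshold (default
0.10): the side lobe falls and the FWHM rises monotonically with γ, so the
smallest admissible γ maximizes confinement subject to artifact
suppression.  The default grid 0.60–2.00 in steps of 0.01 (141 points)
makes the 10%-threshold optimum land at γ = 1.16.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `gamma` | power ratio P_G/P_D | 1.16 | smallest ratio with side lobe ≤ 10% |
| `m` | modulation depth | 1.0 | perfect modulation; configurable to study m ≈ 0.95 hardware |
| `mu_a` | absorption scale | 1.0 | pure scale factor; metrics are scale-invariant |
| `w0` | beam waist | 1.0 (normalized) | physical mode derives w0 = λ/(π NA) |
| `λ, NA` | optics | 532 nm, 1.4 | green excitation through an oil-immersion objective; gives w0 = 121 nm, Gaussian FWHM 142 nm |
| `α` | thermal diffusivity | 1.3e−7 m²/s | typical soft tissue |
| sweep grid | γ range/step | 0.6–2.0 / 0.01 | covers the studied trade-off range; 1.16 is a grid point |
| map grid | extent / samples | ±3 w0 / 501² | captures > 99.99% of both beams' power; resolves the ring at r ≈ 1.04 w0 |
| kernel truncation | PSF half-width | 3 w0 | same coverage argument; enforced ≥ 3 |
| kernel sampling | pixel size | 10 nm (≤ w0/5 enforced) | ≥ 10 samples across the 100 nm central lobe |
| peak prominence | resolvability test | 0.05 of max | counts a visible dip, ignores discretization ripple |

The focused-waist convention `w0 = λ/(π NA)` is the adopted reading of the
Gaussian-focus reference: it reproduces the 142 nm diffraction-limited FWHM
at 532 nm / NA 1.4 (1.17741 · 532/(π·1.4) = 142.4 nm).

## SNR model

Signal generation is assumed confined to the 1/e region of each excitation
profile, and the noise spectral density at the modulation frequency is
assumed independent of the excitation profile (lock-in detection), so the
SNR ratio reduces to the ratio of absorbed energies.  For the Gaussian,
`S_G = P_G (1 − 1/e)` inside `r_{1/e} = w0/√2`.  For the difference
profile, the energy inside reduced radius `x_Δ` is

    S_Δ = P_D ∫₀^{x_Δ} (γ − x) e^{−x} dx = P_D [(γ − 1) + (x_Δ + 1 − γ) e^{−x_Δ}],

verified against quadrature to 1e−9 in the tests.  `x_Δ` follows the
adopted definition — the Gaussian 1/e coordinate (x = 1) scaled by the
squared resolution-improvement factor, `x_Δ = 1/enhancement² ≈ 0.496` at
γ = 1.16 — rather than the difference profile's own 1/e point (x ≈ 0.475);
the latter is exposed via `use_true_one_over_e=True` for sensitivity
analysis and changes the ratio by under 3%.  The dB penalty uses the
20·log₁₀ amplitude convention, the only one under which a ratio of 0.50
maps to the stated ≈ 6 dB; a self-test pins 0.5 → 6.021 dB.

## Thermal confinement

Under harmonic heating the diffusion length per cycle is
`L = √(α/(π f))`.  The unit contract is fixed at (m²/s, nm, MHz), under
which `f ≈ 4.14×10⁴ / L(nm)²` MHz for soft tissue.  `is_confined` applies
a default safety factor of 5 (confinement only holds loosely at the
equality frequency; practical systems run at 20 MHz and above for ~100 nm
spots).  The heat equation itself is not solved and no hardware
modulation-depth roll-off is modelled.

## Synthetic phantom

The phantom generator emulates the *statistical character* of a
microvascular network — curvilinear vessels of varying width (default
60–300 nm), occasional branches at 20–60° — plus one **deterministic
calibrated bifurcation**: two 60 nm-wide branches that separate over a
300 nm transition and then run parallel at a configurable center-to-center
separation (default 120 nm) for 500 nm before diverging.  A test line
perpendicular to the parallel run (length 480 nm, centered mid-run inside
a 1.12 μm region of interest) provides the two-point resolution readout.
Random vessels are rejection-sampled away from the region of interest so
they cannot contaminate that readout.  Rasterization paints each
centerline as an anti-aliased tube (soft edge over ~2 pixels, nearest
centerline distance via a k-d tree) and combines vessels by maximum.
Identical seed and spec reproduce the image bitwise.

What this phantom does *not* emulate: 3-D structure, absorption
heterogeneity, acoustic detection bandwidth, and noise — the imaging
simulation is noise-free by design, so passing tests demonstrate the
optical confinement mechanism, not robustness of the method on real,
noisy data.

Image formation is 2-D convolution with a unit-sum PSF kernel (the
proportionality constant μ_a m is absorbed by the normalization — image
contrast, not absolute pressure, is simulated).  Reflective boundary
handling avoids dark rims in small fields; the implementation pads,
FFT-convolves, and crops, clipping at zero against round-off.  Line
profiles use bilinear interpolation and are peak-normalized; peaks are
counted with relative prominence ≥ 0.05.

## Numerical choices and degenerate inputs

- Root-finding: Brent bisection, `xtol = 1e−12` in `x`; reported values
  are unrounded.
- Power-conservation checks integrate to 8 w0 by adaptive quadrature
  (relative tolerance 1e−9); the truncation error beyond 8 w0 is below
  1e−13 of the total power.
- The Fourier-extraction check uses the periodic trapezoid rule (256
  samples/period), exact to rounding for the band-limited integrand.
- `m = 0` yields an identically zero effective profile (valid, no signal);
  `modulation_depth_map` assigns 0 with a warning at pixels of zero total
  intensity; `select_optimal_ratio` raises "not attainable on grid" when
  no γ meets the threshold; kernels reject pixel sizes above w0/5 and
  truncation below 3 w0; phantom widths below 2 pixels are rejected.
- Two-point threshold sweeps run at 5 nm/pixel on a 1.6 μm field
  (320×320), separations 80–160 nm in 10 nm steps — small enough to run in
  seconds, fine enough that discretization cannot move a threshold by more
  than one step.  The default imaging demonstration uses a 5.12 μm field
  at 10 nm/pixel (512×512).

## Known limitations

- Focal-plane only: no axial behavior, no vector-diffraction or high-NA
  depolarization corrections, no aberrations, no beam misalignment or
  waist mismatch between the two beams.
- The side-lobe ring is retained in simulated images (no deconvolution
  post-processing).
- The SNR model quantifies absorbed-energy ratios only; no noise process
  or integration-time trade-off is simulated.
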