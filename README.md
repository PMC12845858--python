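# psexcite

Numerical model of **phase-shifted dual-beam excitation** for
frequency-domain photoacoustic microscopy (FD-PAM).

A focused TEM00 Gaussian beam and a co-aligned Laguerre–Gaussian (LG01)
donut beam, both intensity-modulated at the same frequency but **π radians
out of phase**, generate a photoacoustic signal whose amplitude at the
modulation frequency scales with the *absolute intensity difference*

$$p(r) \propto \mu_a\, m\, \lvert I_G(r) - I_D(r)\rvert,$$

where at the focal plane

$$I_G(r) = \frac{2P_G}{\pi w_0^2}\, e^{-2r^2/w_0^2},\qquad
  I_D(r) = \frac{4P_D}{\pi w_0^4}\, r^2\, e^{-2r^2/w_0^2}.$$

In the reduced coordinate $x = 2r^2/w_0^2$ the effective profile is
$\lvert\gamma - x\rvert\,e^{-x}$ with power ratio $\gamma = P_G/P_D$ — a
central lobe substantially narrower than the Gaussian focus itself, with a
weak ring (side lobe) beyond the radius where the two intensities are
equal.  The package quantifies the resulting trade-offs:

- **Resolution**: the beam-waist-normalized FWHM drops from 1.177 to
  0.828 at γ = 1.16, a ~1.42× lateral-resolution gain.
- **Side-lobe suppression**: the ring peaks at $e^{-(1+\gamma)}/\gamma$ of
  the central peak; γ = 1.16 is the smallest ratio on a 0.01 grid keeping
  it below 10%.
- **SNR**: confining the excitation costs signal — the absorbed-energy
  ratio within the 1/e region is ≈ 0.50, a ≈ 6 dB penalty (20·log₁₀
  convention).
- **Thermal confinement**: the modulation frequency must stay well above
  $f = \alpha/(\pi L^2)$ ≈ 4.14 MHz for a 100 nm spot in soft tissue.
- **Imaging**: convolving a synthetic microvasculature phantom with the
  physical-unit PSFs (λ = 532 nm, NA = 1.4, w₀ = λ/(πNA)) shows a 120 nm
  vessel bifurcation merging into one peak under Gaussian excitation but
  resolving into two under phase-shifted excitation.

## Worked example

```bash
psexcite psf --gamma 1.16 --outdir out
```

prints (and writes to `out/psf_metrics.json`):

```
fwhm_w0 = 0.8280399446284668
gaussian_fwhm_w0 = 1.1774100225154747
enhancement = 1.421924183915749
sidelobe_ratio = 0.0994182077914332
zero_crossing_w0 = 0.7615773105863908
```

The effective excitation FWHM is 0.828 w₀ versus 1.177 w₀ for the Gaussian
focus (the 1.42× enhancement); the ring artifact is 9.94% of the central
peak, and the two beam intensities cross at r = 0.762 w₀.  The SNR and
thermal calculators:

```bash
psexcite snr --gamma 1.16      # ratio = 0.496…, penalty_db = 6.08…
psexcite thermal --length 100  # f_min_MHz = 4.138…, f_recommended_MHz = 20.7
```

Other subcommands: `psexcite sweep` (FWHM/side-lobe trade-off over
γ ∈ [0.6, 2] and the optimal ratio), `psexcite snapshots` (total-intensity
maps over the modulation cycle), and `psexcite image` (the full phantom
imaging simulation with junction line profiles).  Each run writes a
`manifest.json` sufficient to reproduce its outputs bitwise.

Library use mirrors the CLI:

```python
from psexcite import ExcitationConfig, measure_psf, enhancement_factor

cfg = ExcitationConfig(gamma=1.16)
measure_psf(cfg).fwhm          # 0.8280399446284668  (w0 units)
enhancement_factor(cfg)        # 1.421924183915749
```

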