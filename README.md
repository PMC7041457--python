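# brispec

Denoising and estimation for low-SNR Brillouin microspectroscopy.

Spontaneous Brillouin scattering probes the mechanical properties of
matter: the frequency shift Ω of the Stokes/anti-Stokes doublet is
proportional to the acoustic phonon velocity, and the linewidth Γ (FWHM)
to the phonon lifetime, hence viscosity.  The signal is intrinsically
weak — in fibre-based or in-vivo settings the spectra arrive with
signal-to-noise ratios of order 1–10, where straightforward multi-peak
Lorentzian fitting becomes unreliable.  `brispec` is for spectroscopists
and imaging groups who want to push estimation into that regime with
purely computational tools, and to know quantitatively what bias and
precision they are getting.

## What is inside

- **Maximum-entropy reconstruction (MER).**  Among all positive spectra
  f consistent with the data, select the one maximizing the Shannon
  entropy S = −Σ pᵢ log pᵢ (p = f/Σf), subject to the χ² constraint
  χ² = (1/N) Σⱼ ((Rf)ⱼ − dⱼ)²/σⱼ² = χ₀² ≈ 1, solved via the Lagrangian
  Q = S − λ(χ² − χ₀²) with conjugate-gradient ascent and a Wolfe line
  search.  Approximate peak knowledge enters as a relative-entropy
  default model; saturated regions are excluded with a pixel mask.
- **Wavelet shrinkage (WA).**  DWT → soft-threshold the detail
  coefficients at the universal threshold T = σ̂√(2 ln N) → inverse DWT.
- **Lorentzian fitting.**  Trust-region least squares of a Rayleigh line
  plus symmetric (±Ω) or free Brillouin pairs, with analytic Jacobian;
  plus the conversion v = Ωλ₀/(2n sin(θ/2)) to the speed of sound.
- **Cramér–Rao lower bound** on the shift precision,
  σ_Ω² ≥ πΔ(αΓ+γ)³(1+2I)²/(4X²·SNR²·α²·I²), as the benchmark reference.
- **Monte-Carlo benchmark** tabulating bias/std of Ω̂ and Γ̂ per
  (SNR, method) against the CRLB, on a synthetic 120-pixel spectrometer
  (60 GHz band, Rayleigh 10⁴ / Brillouin 10³ counts at ±10 GHz, 1 GHz
  widths, white Gaussian noise with σ = Brillouin amplitude / SNR).

The MER and WA denoisers are scikit-learn-style transformers
(`MaximumEntropyReconstruction`, `WaveletDenoiser`) operating on
`(n_spectra, n_pixels)` arrays, so they compose with sklearn pipelines;
plain functions (`mer_reconstruct`, `wa_denoise`, `fit_spectrum`, …)
cover single-spectrum work, and a `brispec` CLI wraps everything.

## Worked example

```python
import brispec as b

model = b.build_spectrometer()          # 120 px, 60 GHz, 6.5 um pitch
peaks = b.PeakSet()                     # Rayleigh 1e4; Brillouin 1e3 @ +/-10 GHz
noisy = b.add_noise(b.synth_truth(peaks, model), snr=5, seed=1)

rec = b.mer_reconstruct(noisy, model, b.MEROptions(prior=peaks))
print(f"chi^2 = {rec.chi_sq:.3f}, converged = {rec.converged}")

fit = b.fit_spectrum(noisy.with_intensity(rec.f))
print(f"shift = {fit.shift_ghz:.3f} GHz, linewidth = {fit.linewidth_ghz:.3f} GHz")

raw = b.fit_spectrum(noisy)
print(f"raw fit: shift = {raw.shift_ghz:.3f} GHz, linewidth = {raw.linewidth_ghz:.3f} GHz")
```

prints

```
chi^2 = 0.458, converged = True
shift = 10.044 GHz, linewidth = 0.949 GHz
raw fit: shift = 10.065 GHz, linewidth = 0.822 GHz
```

The reconstruction is statistically consistent with the data (χ² below
the χ₀² = 1 confidence target), and fitting the denoised spectrum
recovers the true shift (10 GHz) and width (1 GHz) to within a few
percent at an SNR of only 5.  Over an ensemble, MER-denoised linewidths
stay near 1.08 GHz where wavelet shrinkage broadens them to ~2.4 GHz —
the cost of soft thresholding on sharp peaks.

Same thing from the shell:

```sh
brispec simulate --snr 5 --seed 1 -o s.csv
brispec denoise --method mer -i s.csv -o r.csv --report r.json
brispec fit -i r.csv
brispec speed-of-sound --shift-ghz 7.07 --wavelength-nm 561 --n 1.33 --angle-deg 180
```

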