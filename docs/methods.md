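# Methods

## The estimation problem

Brillouin microspectroscopy measures the frequency shift Ω and linewidth Γ
(FWHM) of the Stokes/anti-Stokes doublet scattered off acoustic phonons.
Both are extracted from a pixelated intensity spectrum that also contains a
much stronger elastic (Rayleigh) line and additive broadband noise.  At
signal-to-noise ratios below ~10 the conventional approach — nonlinear
least-squares fitting of a sum of Lorentzians — degrades rapidly, so the
package provides two denoising front-ends (maximum-entropy reconstruction
and wavelet shrinkage), a fitting back-end, the Cramér–Rao lower bound as
the precision reference, and a Monte-Carlo harness that measures bias and
precision of every pipeline variant under controlled synthetic conditions.

## Synthetic instrument and data generator

The generator (`brispec.spectrum`) emulates a dispersive spectrometer:

- detector: N = 120 pixels of Δ = 6.5 µm pitch spanning a 60 GHz band,
  i.e. 0.5 GHz per pixel and a linear dispersion α = 13 µm/GHz.  The
  frequency axis is the offset from the Rayleigh line and contains an
  exact zero, so the Rayleigh peak sits on a pixel centre; the detector
  width carried into the precision bound is X = NΔ.
- ground truth: Rayleigh amplitude 10⁴ counts and the Brillouin doublet at
  ±10 GHz with amplitude 10³ counts, all with 1 GHz FWHM; Lorentzians are
  evaluated at pixel centres (a pixel-bin–integrated mode using the
  arctan antiderivative is available behind a flag).
- instrument response: identity by default (γ = 0); otherwise a
  row-normalized discretized Lorentzian of FWHM γ.
- noise: i.i.d. zero-mean Gaussian with σ = A_B / SNR, where A_B is the
  Brillouin peak amplitude.  Anchoring the SNR to the Brillouin amplitude
  (rather than the Rayleigh) is a deliberate choice: the Brillouin peaks
  are the estimation target, and only this convention makes direct
  fitting behave sensibly at SNR ≈ 10 while becoming hopeless at SNR ≈ 1,
  the regime of interest.  A Rayleigh-referenced mode is available.

What the generator does **not** emulate: Poisson/shot-noise statistics
(all noise is Gaussian), detector saturation and clipping (handled only
through the pixel mask), dark/read-noise decomposition, and coloured or
structured noise.  Conclusions drawn from passing tests therefore apply to
the additive-white-Gaussian regime; real spectrometers with saturated
Rayleigh lines need the masking path, and strongly shot-noise-limited data
would need the level-dependent threshold variant or a pre-whitening step
that is out of scope.

## Maximum-entropy reconstruction

Among all strictly positive spectra f consistent with the data d, MER
selects the one maximizing the Shannon entropy of the normalized
distribution p = f/Σf, with consistency enforced through
χ² = (1/N′) Σ_j ((Rf)_j − d_j)²/σ_j² over the N′ unmasked pixels.  The
working objective is the Lagrangian Q = S − λ(χ² − χ0²), with χ0² = 1
(≈95% confidence for Gaussian noise).

Numerical choices:

- **Normalization.** Entropy is computed on p = f/Σf so its argument is
  dimensionless and λ's useful range does not drift with the intensity
  scale; internally the data are rescaled to unit total intensity, making
  the optimizer's gradients O(1) and the reconstruction exactly scale
  invariant.
- **Optimizer.** Polak–Ribière conjugate-gradient ascent (nonnegative-β
  restart variant, restart to steepest ascent whenever the direction is
  not an ascent direction) with a strong-Wolfe line search (c₁ = 10⁻⁴,
  c₂ = 0.9, ≤30 bracketing evaluations).  If the line search fails along
  the conjugate direction it is retried along steepest ascent, then by
  bounded step-halving; repeated failure yields a non-convergent result,
  never an exception.
- **Positivity.** Enforced by flooring at 10⁻¹² × mean(f) after each
  update.  A log-parameterization was considered and rejected: flooring
  keeps the published update structure and the floor is never active in
  practice because the entropy gradient diverges at the boundary.
- **Termination.** ½‖∇S/|∇S| − ∇χ²/|∇χ²|‖² < 0.01: at the constrained
  optimum ∇S = λ∇χ², so the unit gradients align and the metric vanishes.
  If both gradients are numerically zero (perfect data with a perfect
  prior — an interior optimum) the run counts as converged with metric 0.
- **λ schedule.** The solution is insensitive to λ over a broad range, so
  a fixed λ per SNR suffices.  The default table
  (0.5→0.47, 1→0.37, 2→0.38, 3→0.39, 5→0.36, 7→0.34, 10→0.30, 20→0.21,
  log-interpolated, clamped at the ends) was calibrated once on the
  canonical synthetic instrument, without a prior, by bisecting λ until
  the ensemble-mean converged χ² reached χ0²; it is not revisited.  An
  optional outer bisection (`tune_lambda`) drives each individual
  reconstruction to χ² = χ0² exactly; it is off by default.
- **Prior.** Approximate knowledge of the peaks enters as a default
  model: S_m = −Σ p_i log(p_i/m_i) with m the normalized Lorentzian sum
  built from a supplied `PeakSet`.  The amplitudes of the prior peaks are
  used along with positions and widths: in practice rough amplitudes are
  always available from the observed spectrum, and an equal-amplitude
  model would distort the Rayleigh-to-Brillouin weighting for no physical
  reason.  A uniform m recovers the plain entropy.
- **Existence.** If the uniform spectrum carrying the total observed
  intensity already satisfies χ² ≤ χ0², the constraint region contains
  the unconstrained entropy maximum and the data are too noisy for a
  meaningful reconstruction; `me_solution_exists` then returns False and
  the solver returns the input unprocessed with `exists=False`.
- **Masking.** Saturated or suppressed regions (typically the Rayleigh
  line) are excluded from χ² through the per-pixel mask; masked pixels
  provably do not influence the result.

## Wavelet shrinkage

Multilevel DWT (PyWavelets), soft thresholding of the detail levels,
inverse transform.  Defaults: `sym8`, 4 levels (auto-reduced to the
maximum decomposable — 3 for N = 120), symmetric boundary extension, and
the level-independent universal threshold T = σ̂ √(2 ln N) with σ̂ the
median absolute finest-detail coefficient divided by Φ⁻¹(0.75).  The
universal threshold is sometimes printed in the dimensionally inconsistent
form n·2ln(N)/N; that variant is available behind `literal_dialect` but
the standard Donoho–Johnstone form is the default, since it is what the
underlying theory proves and what standard tooling applies.  A
`universal_per_level` rule re-estimates σ̂ per level for noise whose scale
varies across frequency bands.  Soft thresholding shrinks every surviving
coefficient by T, so sharp strong features (the Rayleigh line) are
biased; the method is used for the Brillouin doublet, and the linewidth
it yields is systematically broadened — this is a property of the method,
visible in the benchmark, not an implementation artifact.

## Lorentzian fitting

Trust-region least squares (`scipy.optimize.least_squares`) with an
analytic Jacobian.  The model is an optional Rayleigh Lorentzian fixed at
the line centre plus one or more Brillouin pairs; the default constrains
each pair to ±Ω with shared width and amplitude (physical Stokes/
anti-Stokes symmetry, halving the parameter count where noise hurts
most), while the `symmetric_pair=False` mode fits both sides freely and
defines the conventional "unconstrained fitting" baseline.  Starting
values come from peak picking on a 5-pixel median-smoothed copy
(strongest non-central maxima seed ±Ω; width seeded at two pixel
spacings), falling back to generic guesses, with the fallback flagged.
A fit is reported as `success` only if the optimizer succeeded, no
parameter is pinned at a user bound, and the solution is physical:
positive shift and width, both within the detector band.  Unphysical
free-pair solutions (e.g. a linewidth wider than the whole detector) are
thereby excluded from ensemble moments and counted separately.  The
Rayleigh component is included only when the central pixels are unmasked.

`speed_of_sound` implements v = Ωλ₀/(2n sin(θ/2)).

## Cramér–Rao bound

The closed form implemented is

σ_Ω² = π Δ (αΓ + γ)³ (1 + 2I)² / (4 X² SNR² α² I²),

with the per-pixel SNR = I∞Δ/(Xσ) and I the Brillouin/Rayleigh intensity
ratio.  The typeset grouping of this expression is ambiguous in parts of
the literature; the grouping above is fixed by dimensional analysis
(µm⁴·GHz²/µm⁴ → GHz²) and validated in the test suite against a
brute-force Fisher-information computation on the pixelated model
(J = Σ (∂g_i/∂Ω)²/σ²), with which it agrees to ~15% under the canonical
conditions — the residual difference reflects the Rayleigh term and pixel
sampling that the closed form neglects.  The bound applies to unbiased
estimators, and the benchmarked estimators are not exactly unbiased, so
the bound-dominance check in the benchmark is a logged soft check, not an
assertion.

## Monte-Carlo benchmark

Each (SNR, method) cell generates `n_realisations` spectra (default 500;
chosen so each MER cell completes in well under a minute while keeping
the sampling error of an ensemble std near 1/√(2(n−1)) ≈ 3%), pipes them
through the selected denoiser, fits, and tabulates bias b_Ω = ⟨Ω̂⟩ − Ω
and std σ_Ω of the shift (in GHz and in percent of the 10 GHz true
shift), the linewidth moments, the ME-failure rate, and the CRLB.  Trials
are seeded from (seed, SNR, method, index), so results are independent of
execution order.  Realisations without an ME solution are replaced by
fresh draws until the ensemble is full (the failure fraction is
recorded); a no-regeneration mode reports statistics over successes
only.  Failed fits are excluded from moments and counted.  Percent
figures are referenced to the 10 GHz shift, not the 20 GHz peak
separation.

## Known limitations

- The λ table is calibrated for the canonical instrument; markedly
  different geometries or non-Gaussian noise call for `tune_lambda` or a
  user-supplied λ.
- With a highly informative prior the converged χ² can fall well below
  χ0² (the prior already explains the data); the χ²-band property holds
  for the uniform-prior configuration the schedule was calibrated on.
- The universal threshold assumes white Gaussian noise; at SNR ≲ 3 the
  wavelet path distorts peak shapes noticeably and its linewidths are
  biased upward by design.
- No Voigt/DHO lineshapes, no instrument-response deconvolution inside
  the fit (the response is handled by MER), no translation-invariant
  (cycle-spinning) wavelet variant, no MLE estimator.
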