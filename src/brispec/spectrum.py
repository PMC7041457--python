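"""Data model and synthetic generator for pixelated Brillouin spectra.

A Brillouin spectrum, as recorded by a dispersive spectrometer, is a vector
of intensities on a pixelated detector.  The frequency axis is expressed as
an offset in GHz from the elastic (Rayleigh) line; the absolute optical
carrier (~534 THz for 561 nm light) is provenance metadata only.  The
synthetic generator emulates a realistic instrument: a strong Rayleigh peak
flanked by the weaker Stokes/anti-Stokes Brillouin doublet, an optional
Lorentzian instrument response, and additive white Gaussian noise whose
standard deviation is set by the requested signal-to-noise ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrometerModel",
    "PeakSet",
    "Spectrum",
    "lorentzian",
    "build_spectrometer",
    "synth_truth",
    "add_noise",
]


def lorentzian(omega: ArrayLike, center: float, fwhm: float, amplitude: float) -> NDArray[np.float64]:
    """Lorentzian line shape ``A * (G/2)^2 / ((w - w0)^2 + (G/2)^2)``.

    Parameterized by its full width at half maximum, so that the value at
    ``center +/- fwhm/2`` is exactly ``amplitude / 2``.
    """
    omega = np.asarray(omega, dtype=float)
    half = 0.5 * fwhm
    return amplitude * half**2 / ((omega - center) ** 2 + half**2)


def _lorentzian_pixel_integrated(
    omega: NDArray[np.float64], spacing: float, center: float, fwhm: float, amplitude: float
) -> NDArray[np.float64]:
    # mean over the pixel bin, via the closed-form antiderivative
    # A*(G/2)*arctan((w-w0)/(G/2))
    half = 0.5 * fwhm
    lo = (omega - 0.5 * spacing - center) / half
    hi = (omega + 0.5 * spacing - center) / half
    return amplitude * half * (np.arctan(hi) - np.arctan(lo)) / spacing


@dataclass(frozen=True)
class SpectrometerModel:
    """Geometry and response of a dispersive spectrometer with a pixelated detector.

    Parameters
    ----------
    n_pixels : int
        Number of detector pixels ``N`` spanning the spectral band.
    pixel_pitch_um : float
        Pixel size ``Delta`` in micrometres.
    bandwidth_ghz : float
        Total spectral band imaged onto the detector, GHz.
    response_fwhm_ghz : float
        FWHM ``gamma`` of the (Lorentzian) instrument response; 0 means an
        ideal instrument whose response matrix is the identity.
    """

    n_pixels: int
    pixel_pitch_um: float
    bandwidth_ghz: float
    response_fwhm_ghz: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pixels < 4:
            raise ValueError(f"n_pixels must be >= 4, got {self.n_pixels}")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.bandwidth_ghz <= 0:
            raise ValueError("bandwidth_ghz must be positive")
        if self.response_fwhm_ghz < 0:
            raise ValueError("response_fwhm_ghz must be >= 0")

    @property
    def frequency_spacing_ghz(self) -> float:
        """GHz per pixel."""
        return self.bandwidth_ghz / self.n_pixels

    @property
    def dispersion_um_per_ghz(self) -> float:
        """Linear dispersion ``alpha`` relating detector position to frequency."""
        return self.pixel_pitch_um / self.frequency_spacing_ghz

    @property
    def detector_width_um(self) -> float:
        """Active detector width ``X = N * Delta`` in micrometres."""
        return self.n_pixels * self.pixel_pitch_um

    @property
    def frequency_axis_ghz(self) -> NDArray[np.float64]:
        """Pixel-centre frequencies as offsets from the Rayleigh line.

        The axis contains an exact zero (the Rayleigh line sits on a pixel
        centre), spans the full bandwidth, and is uniformly spaced.
        """
        n = self.n_pixels
        return (np.arange(n) - n // 2) * self.frequency_spacing_ghz

    @property
    def response(self) -> NDArray[np.float64]:
        """Row-normalized N x N response matrix ``R``; identity for gamma = 0."""
        n = self.n_pixels
        if self.response_fwhm_ghz == 0.0:
            return np.eye(n)
        axis = self.frequency_axis_ghz
        diffs = axis[:, None] - axis[None, :]
        r = lorentzian(diffs, 0.0, self.response_fwhm_ghz, 1.0)
        return r / r.sum(axis=1, keepdims=True)

    def apply_response(self, f: ArrayLike) -> NDArray[np.float64]:
        """Apply ``R`` to a spectrum without materializing the identity."""
        f = np.asarray(f, dtype=float)
        if self.response_fwhm_ghz == 0.0:
            return f.copy()
        return self.response @ f


@dataclass(frozen=True)
class PeakSet:
    """Ground-truth peak description: a Rayleigh line plus a Brillouin doublet.

    ``brillouin_shift_ghz`` is the magnitude of the Stokes/anti-Stokes offset
    from the Rayleigh line; the doublet is symmetric with equal amplitude and
    width on both sides.
    """

    brillouin_shift_ghz: float = 10.0
    brillouin_amplitude: float = 1.0e3
    brillouin_fwhm_ghz: float = 1.0
    rayleigh_amplitude: float = 1.0e4
    rayleigh_fwhm_ghz: float = 1.0
    rayleigh_center_ghz: float = 0.0

    def __post_init__(self) -> None:
        if self.brillouin_shift_ghz <= 0:
            raise ValueError("brillouin_shift_ghz must be positive")
        if self.brillouin_amplitude < 0 or self.rayleigh_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.brillouin_fwhm_ghz <= 0 or self.rayleigh_fwhm_ghz <= 0:
            raise ValueError("FWHM values must be positive")

    def components(self) -> list[tuple[float, float, float]]:
        """(center, fwhm, amplitude) triples of the three Lorentzians."""
        c = self.rayleigh_center_ghz
        return [
            (c, self.rayleigh_fwhm_ghz, self.rayleigh_amplitude),
            (c + self.brillouin_shift_ghz, self.brillouin_fwhm_ghz, self.brillouin_amplitude),
            (c - self.brillouin_shift_ghz, self.brillouin_fwhm_ghz, self.brillouin_amplitude),
        ]

    def evaluate(self, omega: ArrayLike) -> NDArray[np.float64]:
        """Sum of the three Lorentzians at frequencies ``omega`` (GHz)."""
        omega = np.asarray(omega, dtype=float)
        out = np.zeros_like(omega)
        for center, fwhm, amp in self.components():
            out += lorentzian(omega, center, fwhm, amp)
        return out


@dataclass
class Spectrum:
    """A pixel-indexed intensity spectrum with its noise scale and mask."""

    frequency_ghz: NDArray[np.float64]
    intensity: NDArray[np.float64]
    noise_sigma: NDArray[np.float64] | float = 0.0
    mask: NDArray[np.bool_] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency_ghz = np.asarray(self.frequency_ghz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.frequency_ghz.size
        if self.intensity.size != n:
            raise ValueError("frequency axis and intensity lengths differ")
        if n >= 2:
            d = np.diff(self.frequency_ghz)
            if np.any(d <= 0):
                raise ValueError("frequency axis must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise ValueError("frequency axis must be uniformly spaced")
        if np.ndim(self.noise_sigma) > 0:
            self.noise_sigma = np.asarray(self.noise_sigma, dtype=float)
            if self.noise_sigma.size != n:
                raise ValueError("noise_sigma length differs from spectrum length")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.size != n:
                raise ValueError("mask length differs from spectrum length")

    def __len__(self) -> int:
        return int(self.frequency_ghz.size)

    @property
    def sigma_vector(self) -> NDArray[np.float64]:
        """Per-pixel noise standard deviation, broadcast from a scalar if needed."""
        if np.ndim(self.noise_sigma) == 0:
            return np.full(len(self), float(self.noise_sigma))
        return self.noise_sigma  # type: ignore[return-value]

    def copy(self) -> "Spectrum":
        return Spectrum(
            frequency_ghz=self.frequency_ghz.copy(),
            intensity=self.intensity.copy(),
            noise_sigma=(self.noise_sigma.copy() if np.ndim(self.noise_sigma) else self.noise_sigma),
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )

    def with_intensity(self, intensity: ArrayLike, **meta: Any) -> "Spectrum":
        """New spectrum sharing axis/sigma/mask but with different intensities."""
        out = self.copy()
        out.intensity = np.asarray(intensity, dtype=float)
        if out.intensity.size != len(self):
            raise ValueError("replacement intensity has wrong length")
        out.meta.update(meta)
        return out

    def mask_frequency_range(self, lo_ghz: float, hi_ghz: float) -> "Spectrum":
        """Return a copy with pixels in [lo, hi] GHz excluded from constraints."""
        out = self.copy()
        sel = (self.frequency_ghz >= lo_ghz) & (self.frequency_ghz <= hi_ghz)
        out.mask = out.mask & ~sel
        return out


def build_spectrometer(
    n_pixels: int = 120,
    bandwidth_ghz: float = 60.0,
    pixel_pitch_um: float = 6.5,
    response_fwhm_ghz: float = 0.0,
) -> SpectrometerModel:
    """Construct a :class:`SpectrometerModel` from keyed parameters.

    The defaults describe the simulated instrument used throughout: 120
    pixels of 6.5 um pitch covering a 60 GHz band (0.5 GHz per pixel,
    dispersion 13 um/GHz), with an ideal (identity) response.
    """
    return SpectrometerModel(
        n_pixels=n_pixels,
        pixel_pitch_um=pixel_pitch_um,
        bandwidth_ghz=bandwidth_ghz,
        response_fwhm_ghz=response_fwhm_ghz,
    )


def synth_truth(
    peaks: PeakSet,
    model: SpectrometerModel,
    pixel_integrated: bool = False,
) -> Spectrum:
    """Noiseless ground-truth spectrum of ``peaks`` seen by ``model``.

    The three Lorentzians are evaluated at pixel-centre frequencies (or
    averaged over each pixel bin when ``pixel_integrated``), then convolved
    with the instrument response.  Peaks whose tails extend beyond the
    detector band are truncated with a logged warning.
    """
    axis = model.frequency_axis_ghz
    span = (axis[0], axis[-1])
    for center, fwhm, _ in peaks.components():
        if not (span[0] <= center <= span[1]):
            logger.warning(
                "peak at %.3f GHz lies outside the detector band [%.3f, %.3f]; tails truncated",
                center, span[0], span[1],
            )
    if pixel_integrated:
        clean = np.zeros_like(axis)
        for center, fwhm, amp in peaks.components():
            clean += _lorentzian_pixel_integrated(
                axis, model.frequency_spacing_ghz, center, fwhm, amp
            )
    else:
        clean = peaks.evaluate(axis)
    observed = model.apply_response(clean)
    return Spectrum(
        frequency_ghz=axis,
        intensity=observed,
        noise_sigma=0.0,
        meta={"peaks": peaks, "spectrometer": model, "noiseless": True},
    )


def add_noise(
    spectrum: Spectrum,
    snr: float,
    seed: int | np.random.SeedSequence,
    snr_reference: str = "brillouin",
) -> Spectrum:
    """Add i.i.d. Gaussian noise at a given signal-to-noise ratio.

    The SNR is the ratio of a reference peak amplitude to the noise standard
    deviation.  By default the reference is the Brillouin (Stokes) peak
    amplitude -- the quantity the whole estimation problem is about -- so
    ``sigma = brillouin_amplitude / snr`` on every pixel.  Set
    ``snr_reference="rayleigh"`` to reference the elastic line instead.

    Deterministic given ``seed``; ``snr=inf`` returns an identical copy.
    """
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    peaks = spectrum.meta.get("peaks")
    if peaks is None:
        raise ValueError("spectrum has no generator peak metadata; cannot anchor the SNR")
    if snr_reference == "brillouin":
        ref = peaks.brillouin_amplitude
    elif snr_reference == "rayleigh":
        ref = peaks.rayleigh_amplitude
    else:
        raise ValueError(f"unknown snr_reference {snr_reference!r}")
    if np.isinf(snr):
        out = spectrum.copy()
        out.meta.update(snr=snr, snr_reference=snr_reference)
        return out
    sigma = ref / snr
    rng = np.random.default_rng(seed)
    noisy = spectrum.intensity + rng.normal(0.0, sigma, len(spectrum))
    out = spectrum.copy()
    out.intensity = noisy
    out.noise_sigma = sigma
    seed_repr = seed if isinstance(seed, (int, np.integer)) else "seedsequence"
    out.meta.update(snr=float(snr), snr_reference=snr_reference, seed=seed_repr, noiseless=False)
    return out
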