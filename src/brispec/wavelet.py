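"""Wavelet-shrinkage denoising of spectra.

The spectrum is decomposed with a discrete wavelet transform, the detail
coefficients are soft-thresholded (shrunk toward zero), and the inverse
transform yields the denoised spectrum.  For white Gaussian noise a single
level-independent "universal" threshold ``T = sigma * sqrt(2 ln N)``
(Donoho-Johnstone) suffices; the noise scale sigma is estimated robustly
from the finest detail level via the median absolute deviation.  A
level-dependent variant re-estimates the noise per level, useful when the
noise spectrum is not flat (e.g. residual shot-noise structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np
import pywt
from numpy.typing import ArrayLike, NDArray

from .spectrum import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "WAOptions",
    "WaveletDecomposition",
    "decompose",
    "reconstruct",
    "estimate_noise",
    "universal_threshold",
    "soft_threshold",
    "wa_denoise",
    "WaveletDenoiser",
]

_MAD_TO_SIGMA = 0.6744897501960817  # Phi^{-1}(0.75): MAD of a unit Gaussian

_LEVEL_WARNINGS: set[tuple[int, str, int]] = set()  # warn once per configuration


@dataclass
class WaveletDecomposition:
    """A multilevel DWT: approximation plus per-level detail coefficients."""

    wavelet_name: str
    levels: int
    coeffs: list[NDArray[np.float64]]  # [approx, detail_L, ..., detail_1]
    boundary_mode: str
    n_samples: int


@dataclass
class WAOptions:
    """Configuration of the wavelet denoiser.

    The defaults (sym8, 4 levels, symmetric extension, universal soft
    threshold) are a conventional choice for smooth spectra in broadband
    noise; all are configurable.
    """

    wavelet_name: str = "sym8"
    levels: int = 4
    threshold_rule: str = "universal"  # universal | universal_per_level | manual
    noise_level: float | None = None
    threshold: float | None = None
    soft: bool = True
    boundary_mode: str = "symmetric"
    literal_dialect: bool = False  # use n*2ln(N)/N instead of sigma*sqrt(2 ln N)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_rule not in ("universal", "universal_per_level", "manual"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.threshold_rule == "manual" and self.threshold is None:
            raise ValueError("manual threshold rule requires an explicit threshold")


def decompose(
    data: ArrayLike,
    wavelet_name: str = "sym8",
    levels: int = 4,
    boundary_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Multilevel DWT of a 1-D signal; levels auto-reduced if the signal is short."""
    data = np.asarray(data, dtype=float)
    wavelet = pywt.Wavelet(wavelet_name)
    max_levels = pywt.dwt_max_level(data.size, wavelet.dec_len)
    if max_levels < 1:
        raise ValueError(f"signal of length {data.size} too short for wavelet {wavelet_name}")
    if levels > max_levels:
        key = (data.size, wavelet_name, levels)
        if key not in _LEVEL_WARNINGS:
            _LEVEL_WARNINGS.add(key)
            logger.warning("requested %d levels, signal supports %d; reducing", levels, max_levels)
        levels = max_levels
    coeffs = pywt.wavedec(data, wavelet, level=levels, mode=boundary_mode)
    return WaveletDecomposition(
        wavelet_name=wavelet_name,
        levels=levels,
        coeffs=[np.asarray(c, dtype=float) for c in coeffs],
        boundary_mode=boundary_mode,
        n_samples=data.size,
    )


def reconstruct(decomp: WaveletDecomposition) -> NDArray[np.float64]:
    """Inverse DWT, trimmed to the original signal length."""
    out = pywt.waverec(decomp.coeffs, pywt.Wavelet(decomp.wavelet_name), mode=decomp.boundary_mode)
    return np.asarray(out[: decomp.n_samples], dtype=float)


def estimate_noise(decomp: WaveletDecomposition) -> float:
    """Robust noise-sigma estimate: ``median(|finest detail|) / 0.6745``.

    The finest detail level of a smooth signal is essentially pure noise,
    and for Gaussian noise the median absolute coefficient divided by the
    normal MAD constant estimates sigma without being dragged by the few
    large coefficients carrying genuine spectral features.
    """
    if len(decomp.coeffs) < 2 or decomp.coeffs[-1].size == 0:
        raise ValueError("decomposition has no detail coefficients")
    return float(np.median(np.abs(decomp.coeffs[-1])) / _MAD_TO_SIGMA)


def universal_threshold(
    noise_level: float, n_samples: int, literal_dialect: bool = False
) -> float:
    """Level-independent universal threshold for white Gaussian noise.

    Default form ``T = sigma * sqrt(2 ln N)`` (Donoho-Johnstone).  The
    ``literal_dialect`` variant ``T = sigma * 2 ln(N) / N`` is provided for
    comparison with sources that print the rule in that form.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if noise_level == 0 or n_samples == 1:
        return 0.0
    if literal_dialect:
        return float(noise_level * 2.0 * np.log(n_samples) / n_samples)
    return float(noise_level * np.sqrt(2.0 * np.log(n_samples)))


def soft_threshold(coeffs: ArrayLike, threshold: float, soft: bool = True) -> NDArray[np.float64]:
    """Shrink coefficients: ``sign(c) * max(|c| - T, 0)`` (or hard-zero below T)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    c = np.asarray(coeffs, dtype=float)
    if soft:
        return np.sign(c) * np.maximum(np.abs(c) - threshold, 0.0)
    return np.where(np.abs(c) < threshold, 0.0, c)


def _denoise_array(data: NDArray[np.float64], options: WAOptions) -> NDArray[np.float64]:
    decomp = decompose(data, options.wavelet_name, options.levels, options.boundary_mode)
    details = decomp.coeffs[1:]
    if options.threshold_rule == "manual":
        thresholds = [float(options.threshold)] * len(details)
    elif options.threshold_rule == "universal":
        sigma = options.noise_level if options.noise_level is not None else estimate_noise(decomp)
        t = universal_threshold(sigma, data.size, options.literal_dialect)
        thresholds = [t] * len(details)
    else:  # universal_per_level
        thresholds = []
        for c in details:
            sigma = float(np.median(np.abs(c)) / _MAD_TO_SIGMA) if c.size else 0.0
            thresholds.append(universal_threshold(sigma, data.size, options.literal_dialect))
    decomp.coeffs = [decomp.coeffs[0]] + [
        soft_threshold(c, t, options.soft) for c, t in zip(details, thresholds)
    ]
    return reconstruct(decomp)


def wa_denoise(spectrum: Spectrum, options: WAOptions | None = None) -> Spectrum:
    """Wavelet-denoise a spectrum; axis, mask and noise scale are preserved."""
    options = options or WAOptions()
    out = _denoise_array(spectrum.intensity, options)
    result = spectrum.with_intensity(out, denoised="wa")
    return result


class WaveletDenoiser:
    """Scikit-learn style transformer: row-wise wavelet shrinkage.

    Stateless in the sklearn sense (fit only validates shape), so it can sit
    in a pipeline in front of any downstream estimator.
    """

    def __init__(
        self,
        wavelet_name: str = "sym8",
        levels: int = 4,
        threshold_rule: str = "universal",
        noise_level: float | None = None,
        threshold: float | None = None,
        soft: bool = True,
        boundary_mode: str = "symmetric",
    ) -> None:
        self.wavelet_name = wavelet_name
        self.levels = levels
        self.threshold_rule = threshold_rule
        self.noise_level = noise_level
        self.threshold = threshold
        self.soft = soft
        self.boundary_mode = boundary_mode

    _param_names = (
        "wavelet_name", "levels", "threshold_rule", "noise_level",
        "threshold", "soft", "boundary_mode",
    )

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params: Any) -> "WaveletDenoiser":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _options(self) -> WAOptions:
        return WAOptions(
            wavelet_name=self.wavelet_name,
            levels=self.levels,
            threshold_rule=self.threshold_rule,
            noise_level=self.noise_level,
            threshold=self.threshold,
            soft=self.soft,
            boundary_mode=self.boundary_mode,
        )

    def fit(self, X: ArrayLike, y: Any = None) -> "WaveletDenoiser":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: ArrayLike) -> NDArray[np.float64]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        options = self._options()
        return np.vstack([_denoise_array(row, options) for row in X])

    def fit_transform(self, X: ArrayLike, y: Any = None) -> NDArray[np.float64]:
        return self.fit(X).transform(X)
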