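"""Multi-Lorentzian least-squares fitting of Brillouin spectra.

The estimation target is the Brillouin shift Omega (the offset of the
Stokes/anti-Stokes doublet from the Rayleigh line) and the linewidth Gamma
(FWHM).  The fitted model is an optional Rayleigh Lorentzian at the line
centre plus one or more Brillouin pairs, either constrained to physical
Stokes/anti-Stokes symmetry (+/-Omega, shared width and amplitude) or left
free per side.  Fitting is trust-region nonlinear least squares with an
analytic Jacobian.

Also provides the standard conversion from Brillouin shift to the acoustic
(phonon) speed of sound, v = Omega * lambda0 / (2 n sin(theta/2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares
from scipy.signal import find_peaks, medfilt

from .spectrum import Spectrum, lorentzian

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "default_init",
    "fit_spectrum",
    "speed_of_sound",
    "LorentzianPeakFit",
]


@dataclass
class FitConfig:
    """Configuration of the Lorentzian fit.

    ``symmetric_pair=True`` ties each Stokes/anti-Stokes pair to +/-Omega
    with equal width and amplitude; the free mode fits each side
    independently (the conventional "unconstrained" fit).  ``init`` may
    supply explicit starting values as produced by :func:`default_init`.
    """

    n_brillouin_pairs: int = 1
    include_rayleigh: bool = True
    symmetric_pair: bool = True
    init: dict[str, Any] | None = None
    bounds: tuple[ArrayLike, ArrayLike] | None = None
    max_evals: int = 5000

    def __post_init__(self) -> None:
        if self.n_brillouin_pairs < 1:
            raise ValueError("n_brillouin_pairs must be >= 1")


@dataclass
class FitResult:
    """Estimated shift/linewidth with per-component detail and diagnostics."""

    shift_ghz: float
    linewidth_ghz: float
    amplitudes: list[float]
    rayleigh_params: dict[str, float] | None
    rms_error_pct: float
    success: bool
    covariance: NDArray[np.float64] | None
    params: NDArray[np.float64] | None = None
    message: str = ""
    init_fallback: bool = False


def default_init(spectrum: Spectrum, config: FitConfig | None = None) -> dict[str, Any]:
    """Data-driven starting values by peak picking.

    The spectrum is median-smoothed over 5 pixels; local maxima are ranked
    by height.  The strongest maximum near the line centre seeds the
    Rayleigh amplitude; the symmetric pair is seeded at the mean absolute
    offset of the two strongest non-central maxima.  Width starts at two
    pixel spacings.  If no usable maxima exist the guesses fall back to
    generic values and the result is flagged (``fallback=True``).
    """
    config = config or FitConfig()
    axis = spectrum.frequency_ghz
    d = spectrum.intensity
    span = axis[-1] - axis[0]
    spacing = span / max(len(spectrum) - 1, 1)
    exclusion = max(3.0 * spacing, 0.05 * span)

    smoothed = medfilt(d, kernel_size=5) if len(d) >= 5 else d
    idx, _ = find_peaks(smoothed)
    fallback = False
    if idx.size:
        order = np.argsort(smoothed[idx])[::-1]
        idx = idx[order]
    noncentral = [i for i in idx if abs(axis[i]) > exclusion]
    if len(noncentral) >= 2:
        shift0 = 0.5 * (abs(axis[noncentral[0]]) + abs(axis[noncentral[1]]))
        amp0 = max(0.5 * (smoothed[noncentral[0]] + smoothed[noncentral[1]]), 1e-12)
    elif len(noncentral) == 1:
        shift0 = abs(axis[noncentral[0]])
        amp0 = max(smoothed[noncentral[0]], 1e-12)
    else:
        fallback = True
        shift0 = 0.25 * span
        amp0 = max(float(np.max(d)), 1.0)
        logger.warning("no detectable peaks; using uniform fallback initial guesses")
    width0 = 2.0 * spacing
    rayleigh_amp0 = max(float(np.max(smoothed)), amp0)
    return {
        "shift": float(shift0),
        "width": float(width0),
        "amplitude": float(amp0),
        "rayleigh_amplitude": float(rayleigh_amp0),
        "rayleigh_width": float(width0),
        "fallback": fallback,
    }


def _pack_params(config: FitConfig, init: dict[str, Any]) -> NDArray[np.float64]:
    p: list[float] = []
    if config.include_rayleigh:
        p += [init["rayleigh_amplitude"], init["rayleigh_width"]]
    for _ in range(config.n_brillouin_pairs):
        if config.symmetric_pair:
            p += [init["shift"], init["width"], init["amplitude"]]
        else:
            p += [init["shift"], init["width"], init["amplitude"],
                  -init["shift"], init["width"], init["amplitude"]]
    return np.array(p, dtype=float)


def _model_and_jacobian(
    params: NDArray[np.float64], omega: NDArray[np.float64], config: FitConfig
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    n = omega.size
    model = np.zeros(n)
    jac = np.zeros((n, params.size))
    k = 0

    def add_lorentzian(center: float, fwhm: float, amp: float):
        half = 0.5 * abs(fwhm)
        half = max(half, 1e-12)
        dev = omega - center
        denom = dev**2 + half**2
        val = amp * half**2 / denom
        d_amp = half**2 / denom
        d_center = amp * half**2 * 2.0 * dev / denom**2
        # dL/dG = 0.5 * dL/dh;  dL/dh = 2 A h dev^2 / denom^2
        d_fwhm = np.sign(fwhm) * amp * half * dev**2 / denom**2
        return val, d_center, d_fwhm, d_amp

    if config.include_rayleigh:
        amp_r, fwhm_r = params[0], params[1]
        val, _, d_fwhm, d_amp = add_lorentzian(0.0, fwhm_r, amp_r)
        model += val
        jac[:, 0] = d_amp
        jac[:, 1] = d_fwhm
        k = 2
    for _ in range(config.n_brillouin_pairs):
        if config.symmetric_pair:
            shift, fwhm, amp = params[k : k + 3]
            v1, dc1, dg1, da1 = add_lorentzian(shift, fwhm, amp)
            v2, dc2, dg2, da2 = add_lorentzian(-shift, fwhm, amp)
            model += v1 + v2
            jac[:, k] = dc1 - dc2  # d/dOmega: centers move apart
            jac[:, k + 1] = dg1 + dg2
            jac[:, k + 2] = da1 + da2
            k += 3
        else:
            for _side in range(2):
                center, fwhm, amp = params[k : k + 3]
                v, dc, dg, da = add_lorentzian(center, fwhm, amp)
                model += v
                jac[:, k] = dc
                jac[:, k + 1] = dg
                jac[:, k + 2] = da
                k += 3
    return model, jac


def fit_spectrum(spectrum: Spectrum, config: FitConfig | None = None) -> FitResult:
    """Least-squares Lorentzian fit of a spectrum over its unmasked pixels.

    Never raises on optimizer trouble: a failed or unphysical solution
    (non-positive or out-of-band shift/width) is returned with
    ``success=False``.
    """
    config = config or FitConfig()
    axis = spectrum.frequency_ghz
    if axis[-1] - axis[0] <= 0:
        raise ValueError("degenerate frequency axis")
    mask = spectrum.mask
    n_params = (2 if config.include_rayleigh else 0) + config.n_brillouin_pairs * (
        3 if config.symmetric_pair else 6
    )
    if int(mask.sum()) < 3 * n_params:
        raise ValueError(
            f"need at least {3 * n_params} unmasked pixels for {n_params} parameters"
        )
    init = dict(config.init) if config.init is not None else default_init(spectrum, config)
    fallback = bool(init.get("fallback", False))
    p0 = _pack_params(config, init)

    omega = axis[mask]
    data = spectrum.intensity[mask]

    def residual(p: NDArray[np.float64]) -> NDArray[np.float64]:
        return _model_and_jacobian(p, omega, config)[0] - data

    def jacobian(p: NDArray[np.float64]) -> NDArray[np.float64]:
        return _model_and_jacobian(p, omega, config)[1]

    bounds = config.bounds if config.bounds is not None else (-np.inf, np.inf)
    try:
        sol = least_squares(
            residual, p0, jac=jacobian, bounds=bounds,
            max_nfev=config.max_evals, method="trf",
        )
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("least_squares raised: %s", exc)
        return FitResult(
            shift_ghz=float("nan"), linewidth_ghz=float("nan"), amplitudes=[],
            rayleigh_params=None, rms_error_pct=float("nan"), success=False,
            covariance=None, message=str(exc), init_fallback=fallback,
        )

    p = sol.x
    k = 0
    rayleigh: dict[str, float] | None = None
    if config.include_rayleigh:
        rayleigh = {"amplitude": float(p[0]), "fwhm_ghz": float(abs(p[1]))}
        k = 2
    shifts, widths, amps = [], [], []
    for _ in range(config.n_brillouin_pairs):
        if config.symmetric_pair:
            shifts.append(abs(p[k]))
            widths.append(abs(p[k + 1]))
            amps.append(float(p[k + 2]))
            k += 3
        else:
            shifts.append(0.5 * (abs(p[k]) + abs(p[k + 3])))
            widths.append(0.5 * (abs(p[k + 1]) + abs(p[k + 4])))
            amps.append(0.5 * (float(p[k + 2]) + float(p[k + 5])))
            k += 6
    shift = float(shifts[0])
    width = float(widths[0])

    resid = residual(p)
    rms = float(np.sqrt(np.mean(resid**2)))
    ref_amp = abs(amps[0]) if amps and amps[0] != 0 else float("nan")
    rms_pct = 100.0 * rms / ref_amp if np.isfinite(ref_amp) else float("nan")

    span = float(axis[-1] - axis[0])
    bounded_ok = True
    if config.bounds is not None:
        lo, hi = (np.broadcast_to(np.asarray(b, dtype=float), p.shape) for b in bounds)
        bounded_ok = not np.any(np.isclose(p, lo) | np.isclose(p, hi))
    physical = (
        0.0 < shift <= span
        and 0.0 < width <= span
        and all(a > 0 for a in amps)
    )
    success = bool(sol.success) and physical and bounded_ok

    covariance = None
    dof = omega.size - p.size
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            covariance = np.linalg.inv(jtj) * (np.sum(resid**2) / dof)
        except np.linalg.LinAlgError:
            covariance = None

    return FitResult(
        shift_ghz=shift, linewidth_ghz=width, amplitudes=amps,
        rayleigh_params=rayleigh, rms_error_pct=rms_pct, success=success,
        covariance=covariance, params=p, message=sol.message,
        init_fallback=fallback,
    )


def speed_of_sound(
    shift_ghz: float,
    wavelength_nm: float,
    refractive_index: float,
    scattering_angle_deg: float = 180.0,
) -> float:
    """Speed of sound (m/s) from a Brillouin shift.

    ``v = Omega * lambda0 / (2 n sin(theta/2))`` with the shift in Hz and
    the vacuum wavelength in metres; theta is the scattering angle
    (180 degrees for backscattering).
    """
    if not (0.0 < scattering_angle_deg <= 180.0):
        raise ValueError("scattering angle must be in (0, 180] degrees")
    if refractive_index < 1.0:
        raise ValueError("refractive index must be >= 1")
    omega_hz = shift_ghz * 1e9
    lam_m = wavelength_nm * 1e-9
    return omega_hz * lam_m / (2.0 * refractive_index * np.sin(np.deg2rad(scattering_angle_deg) / 2.0))


class LorentzianPeakFit:
    """Estimator-style wrapper around :func:`fit_spectrum`.

    After ``fit`` the results are available as trailing-underscore
    attributes (``shift_ghz_``, ``linewidth_ghz_``, ``result_``) and the
    fitted model can be evaluated with :meth:`predict`.
    """

    def __init__(
        self,
        n_brillouin_pairs: int = 1,
        include_rayleigh: bool = True,
        symmetric_pair: bool = True,
        init: dict[str, Any] | None = None,
        bounds: tuple[ArrayLike, ArrayLike] | None = None,
        max_evals: int = 5000,
    ) -> None:
        self.n_brillouin_pairs = n_brillouin_pairs
        self.include_rayleigh = include_rayleigh
        self.symmetric_pair = symmetric_pair
        self.init = init
        self.bounds = bounds
        self.max_evals = max_evals

    _param_names = (
        "n_brillouin_pairs", "include_rayleigh", "symmetric_pair",
        "init", "bounds", "max_evals",
    )

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params: Any) -> "LorentzianPeakFit":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _config(self) -> FitConfig:
        return FitConfig(
            n_brillouin_pairs=self.n_brillouin_pairs,
            include_rayleigh=self.include_rayleigh,
            symmetric_pair=self.symmetric_pair,
            init=self.init,
            bounds=self.bounds,
            max_evals=self.max_evals,
        )

    def fit(self, spectrum: Spectrum, y: Any = None) -> "LorentzianPeakFit":
        config = self._config()
        self.result_ = fit_spectrum(spectrum, config)
        self.shift_ghz_ = self.result_.shift_ghz
        self.linewidth_ghz_ = self.result_.linewidth_ghz
        self._fit_config = config
        return self

    def predict(self, omega: ArrayLike) -> NDArray[np.float64]:
        if not hasattr(self, "result_"):
            raise AttributeError("fit the estimator before calling predict")
        if self.result_.params is None:
            raise ValueError("no fitted parameters available")
        omega = np.asarray(omega, dtype=float)
        return _model_and_jacobian(self.result_.params, omega, self._fit_config)[0]
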