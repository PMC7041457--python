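"""Maximum entropy reconstruction (MER) of noisy spectra.

MER selects, among all spectra consistent with the measured data, the one
of maximal Shannon entropy.  Consistency is a chi-squared constraint: with
additive Gaussian noise of per-pixel variance ``sigma_j^2`` the normalized
error ``chi^2 = (1/N) sum_j ((R f)_j - d_j)^2 / sigma_j^2`` is chi-squared
distributed, and requiring ``chi^2 = chi0^2 ~ 1`` keeps the reconstruction
within the ~95% confidence region of the data.  The constrained problem is
solved through the Lagrangian

    Q(f) = S(f) - lambda * (chi^2(f) - chi0^2),   f > 0,

maximized by Polak-Ribiere conjugate-gradient ascent with a Wolfe line
search.  Entropy is computed on the normalized distribution p = f / sum(f)
(optionally relative to a prior "default model" m built from approximately
known peak positions/widths):  S_m = -sum_i p_i log(p_i / m_i).

Iterations stop when the entropy and constraint gradients are parallel:
``0.5 * || grad S/|grad S| - grad chi^2/|grad chi^2| ||^2`` below a
threshold (default 0.01); at the exact constrained optimum the two
gradients align and the metric is 0.

A maximum-entropy solution only exists when the data actually constrain
the problem: if the unconstrained entropy maximizer (the uniform spectrum
carrying the total observed intensity) already satisfies ``chi^2 <=
chi0^2``, the data are too noisy for a meaningful reconstruction and
:func:`me_solution_exists` returns False.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import line_search

from .spectrum import PeakSet, Spectrum, SpectrometerModel

logger = logging.getLogger(__name__)

__all__ = [
    "MEROptions",
    "ReconstructionResult",
    "entropy",
    "chi_squared",
    "gradients",
    "termination_metric",
    "me_solution_exists",
    "mer_reconstruct",
    "MaximumEntropyReconstruction",
    "default_lambda",
]

# Lagrange multiplier schedule keyed by data SNR, calibrated once on the
# canonical synthetic instrument so that converged chi^2 lands near chi0^2.
# Interpolated on log(SNR); clamped at the ends.  See docs/methods.md.
_LAMBDA_TABLE: tuple[tuple[float, float], ...] = (
    (0.5, 0.47),
    (1.0, 0.37),
    (2.0, 0.38),
    (3.0, 0.39),
    (5.0, 0.36),
    (7.0, 0.34),
    (10.0, 0.30),
    (20.0, 0.21),
)


def default_lambda(snr: float) -> float:
    """Default Lagrange multiplier for data of a given SNR."""
    snrs = np.array([row[0] for row in _LAMBDA_TABLE])
    lams = np.array([row[1] for row in _LAMBDA_TABLE])
    snr = float(np.clip(snr, snrs[0], snrs[-1]))
    return float(np.exp(np.interp(np.log(snr), np.log(snrs), np.log(lams))))


@dataclass
class MEROptions:
    """Tuning knobs of the maximum-entropy reconstruction.

    ``lagrange_lambda=None`` selects the SNR-keyed default schedule.
    ``prior`` may be a :class:`PeakSet` (converted to a normalized
    Lorentzian-sum default model on the spectrum axis) or an explicit
    positive vector; ``None`` means the uniform (maximally ignorant) model.
    ``tune_lambda`` turns on an outer bisection driving the converged
    chi^2 to chi0_sq exactly; off by default since solutions are stable
    over a broad range of lambda.
    """

    chi0_sq: float = 1.0
    lagrange_lambda: float | None = None
    max_iters: int = 2000
    term_threshold: float = 0.01
    wolfe_c1: float = 1e-4
    wolfe_c2: float = 0.9
    cg_memory: int = 2
    floor_eps: float = 1e-12
    prior: PeakSet | ArrayLike | None = None
    mask_policy: bool = True
    tune_lambda: bool = False
    force: bool = False  # iterate even when no ME solution exists

    def __post_init__(self) -> None:
        if not (0 < self.wolfe_c1 < self.wolfe_c2 < 1):
            raise ValueError("require 0 < wolfe_c1 < wolfe_c2 < 1")
        if self.chi0_sq <= 0:
            raise ValueError("chi0_sq must be positive")
        if self.lagrange_lambda is not None and self.lagrange_lambda <= 0:
            raise ValueError("lagrange_lambda must be positive")
        if self.term_threshold <= 0:
            raise ValueError("term_threshold must be positive")


@dataclass
class ReconstructionResult:
    """Reconstructed spectrum plus convergence diagnostics."""

    f: NDArray[np.float64]
    entropy: float
    chi_sq: float
    term_metric: float
    n_iters: int
    converged: bool
    exists: bool
    lagrange_lambda: float = float("nan")
    floor: float = 0.0


def entropy(f: ArrayLike, prior: ArrayLike | None = None) -> float:
    """Shannon entropy of the normalized spectrum ``p = f / sum(f)``.

    With a ``prior`` model ``m`` the entropy is relative:
    ``-sum p_i log(p_i / m_i)`` with ``m`` normalized to unit sum; the
    uniform prior recovers the plain entropy up to the constant ``log N``.
    Maximal value ``log N`` at uniform ``p`` (uniform prior).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("entropy requires non-negative intensities with positive total")
    p = f / f.sum()
    pos = p > 0  # 0 * log 0 == 0 by the usual convention
    if prior is None:
        return float(-np.sum(p[pos] * np.log(p[pos])))
    m = np.asarray(prior, dtype=float)
    if np.any(m <= 0):
        raise ValueError("prior model must be strictly positive")
    m = m / m.sum()
    return float(-np.sum(p[pos] * np.log(p[pos] / m[pos])))


def chi_squared(f: ArrayLike, spectrum: Spectrum, model: SpectrometerModel | None = None) -> float:
    """Normalized mean-square misfit between ``R f`` and the data.

    Averaged over unmasked pixels only; raises if every pixel is masked or
    any unmasked pixel has a non-positive noise sigma.
    """
    f = np.asarray(f, dtype=float)
    mask = spectrum.mask
    n_eff = int(mask.sum())
    if n_eff == 0:
        raise ValueError("all pixels are masked; chi-squared undefined")
    sigma = spectrum.sigma_vector
    if np.any(sigma[mask] <= 0):
        raise ValueError("noise sigma must be positive on unmasked pixels")
    rf = model.apply_response(f) if model is not None else f
    resid = (rf - spectrum.intensity)[mask] / sigma[mask]
    return float(np.sum(resid**2) / n_eff)


def _entropy_gradient(f: NDArray[np.float64], log_m: NDArray[np.float64]) -> NDArray[np.float64]:
    # d/df_k of -sum p log(p/m) with p = f/sum(f):
    #   grad_k = -(log(p_k/m_k) + S_m) / sum(f)
    total = f.sum()
    p = f / total
    log_ratio = np.log(p) - log_m
    s_m = -float(np.sum(p * log_ratio))
    return -(log_ratio + s_m) / total


def _chi_gradient(
    f: NDArray[np.float64], spectrum: Spectrum, model: SpectrometerModel | None
) -> NDArray[np.float64]:
    mask = spectrum.mask
    n_eff = int(mask.sum())
    sigma = spectrum.sigma_vector
    rf = model.apply_response(f) if model is not None else f
    w = np.zeros(len(f))
    w[mask] = (rf - spectrum.intensity)[mask] / sigma[mask] ** 2
    if model is not None and model.response_fwhm_ghz != 0.0:
        g = model.response.T @ w
    else:
        g = w
    return 2.0 * g / n_eff


def gradients(
    f: ArrayLike,
    spectrum: Spectrum,
    model: SpectrometerModel | None = None,
    options: MEROptions | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Analytic gradients of the entropy and of chi-squared with respect to f."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("gradients require strictly positive f")
    options = options or MEROptions()
    log_m = _prior_log_model(options.prior, spectrum, len(f))
    grad_s = _entropy_gradient(f, log_m)
    grad_c = _chi_gradient(f, spectrum, model)
    if not (np.all(np.isfinite(grad_s)) and np.all(np.isfinite(grad_c))):
        raise FloatingPointError("non-finite gradient encountered")
    return grad_s, grad_c


def termination_metric(grad_s: ArrayLike, grad_chi: ArrayLike) -> float:
    """Alignment of the entropy and constraint gradients, in [0, 2].

    ``0.5 * ||u - v||^2`` for the unit vectors of the two gradients: 0 when
    parallel (the constrained optimum), 1 when orthogonal, 2 when
    anti-parallel.
    """
    u = np.asarray(grad_s, dtype=float)
    v = np.asarray(grad_chi, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 and nv == 0.0:
        return 0.0
    if nu == 0.0 or nv == 0.0:
        raise FloatingPointError("termination metric undefined for a single zero gradient")
    w = u / nu - v / nv
    return float(0.5 * np.dot(w, w))


def _prior_log_model(
    prior: PeakSet | ArrayLike | None, spectrum: Spectrum, n: int
) -> NDArray[np.float64]:
    """log of the normalized default model m on the spectrum's pixel grid."""
    if prior is None:
        return np.full(n, -np.log(n))
    if isinstance(prior, PeakSet):
        m = prior.evaluate(spectrum.frequency_ghz)
    else:
        m = np.asarray(prior, dtype=float)
        if m.size != n:
            raise ValueError("explicit prior model has wrong length")
    # Lorentzians never vanish, but guard against user-supplied zeros
    m = np.maximum(m, m.max() * 1e-12)
    m = m / m.sum()
    return np.log(m)


def me_solution_exists(
    spectrum: Spectrum,
    model: SpectrometerModel | None = None,
    options: MEROptions | None = None,
) -> bool:
    """Whether a meaningful maximum-entropy reconstruction exists.

    The unconstrained entropy maximizer is the uniform spectrum carrying
    the total observed intensity.  If it already satisfies ``chi^2 <=
    chi0^2`` the constraint is inactive -- the data are too noisy to pin
    down any structure -- and no ME solution exists.
    """
    options = options or MEROptions()
    mask = spectrum.mask
    total = float(spectrum.intensity[mask].sum())
    n = len(spectrum)
    uniform = np.full(n, max(total, 0.0) / mask.sum() if mask.sum() else 0.0)
    chi = chi_squared(uniform, spectrum, model)
    return chi > options.chi0_sq


def _reconstruct_fixed_lambda(
    d: NDArray[np.float64],
    sigma: NDArray[np.float64],
    mask: NDArray[np.bool_],
    model: SpectrometerModel | None,
    log_m: NDArray[np.float64],
    lam: float,
    options: MEROptions,
) -> tuple[NDArray[np.float64], int, float, bool]:
    """Core CG/Wolfe ascent in normalized intensity units. Deterministic."""
    n = d.size
    n_eff = int(mask.sum())
    total0 = float(d[mask].sum())
    scale = total0 if total0 > 0 else float(np.abs(d).sum()) or 1.0
    dd = d / scale
    sig = sigma / scale
    sig_sq = sig**2

    use_r = model is not None and model.response_fwhm_ghz != 0.0
    r_mat = model.response if use_r else None

    f = np.full(n, dd[mask].sum() / n if total0 > 0 else 1.0 / n)
    f = np.maximum(f, 1e-12)
    floor = options.floor_eps * float(f.mean())

    def clip(x: NDArray[np.float64]) -> NDArray[np.float64]:
        return np.maximum(x, floor)

    def split_grads(x: NDArray[np.float64]):
        x = clip(x)
        total = x.sum()
        p = x / total
        log_ratio = np.log(p) - log_m
        s_m = -float(np.sum(p * log_ratio))
        g_s = -(log_ratio + s_m) / total
        rx = r_mat @ x if use_r else x
        w = np.zeros(n)
        w[mask] = (rx - dd)[mask] / sig_sq[mask]
        g_c = 2.0 * ((r_mat.T @ w) if use_r else w) / n_eff
        chi = float(np.sum((rx - dd)[mask] ** 2 / sig_sq[mask]) / n_eff)
        return s_m, g_s, g_c, chi

    # scalar objective, cheaper than split_grads when no gradient is needed
    def neg_q(x: NDArray[np.float64]) -> float:
        x = clip(x)
        total = x.sum()
        p = x / total
        s_m = -float(np.sum(p * (np.log(p) - log_m)))
        rx = r_mat @ x if use_r else x
        chi = float(np.sum((rx - dd)[mask] ** 2 / sig_sq[mask]) / n_eff)
        return -(s_m - lam * (chi - options.chi0_sq))

    def neg_grad(x: NDArray[np.float64]) -> NDArray[np.float64]:
        _, g_s, g_c, _ = split_grads(x)
        return -(g_s - lam * g_c)

    def wolfe_step(x, direction, g):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ls = line_search(
                neg_q, neg_grad, x, direction, gfk=g,
                maxiter=30, c1=options.wolfe_c1, c2=options.wolfe_c2,
            )
        return ls[0]

    # in normalized units the gradients are O(1) away from the optimum;
    # both vanishing means the unconstrained interior optimum was reached
    grad_tol = 1e-9

    g = neg_grad(f)
    direction = -g
    metric = float("inf")
    for it in range(options.max_iters):
        _, g_s, g_c, chi = split_grads(f)
        n_s = float(np.linalg.norm(g_s))
        n_c = float(np.linalg.norm(g_c))
        if n_s <= grad_tol and n_c <= grad_tol:
            return clip(f) * scale, it, 0.0, True
        if n_s > 0 and n_c > 0:
            w = g_s / n_s - g_c / n_c
            metric = float(0.5 * np.dot(w, w))
            if metric < options.term_threshold:
                return clip(f) * scale, it, metric, True
        if np.dot(direction, g) >= 0:  # not an ascent direction: restart
            direction = -g
        alpha = wolfe_step(f, direction, g)
        if alpha is None:
            direction = -g
            alpha = wolfe_step(f, direction, g)
        if alpha is None:
            # bounded backtracking along steepest ascent
            direction = -g
            alpha = 1.0
            q0 = neg_q(f)
            while alpha > 1e-20 and neg_q(clip(f + alpha * direction)) >= q0:
                alpha *= 0.5
            if alpha <= 1e-20:
                if float(np.linalg.norm(g)) <= 1e-6:
                    # stationary point of Q whose component gradients are
                    # individually negligible
                    if n_s <= 1e-6 and n_c <= 1e-6:
                        return clip(f) * scale, it, 0.0, True
                return clip(f) * scale, it, metric, False
        f_new = clip(f + alpha * direction)
        g_new = neg_grad(f_new)
        if options.cg_memory >= 1:
            # Polak-Ribiere conjugacy (nonnegative restart variant)
            beta = max(0.0, float(np.dot(g_new, g_new - g) / np.dot(g, g)))
        else:
            beta = 0.0  # plain steepest ascent
        direction = -g_new + beta * direction
        f, g = f_new, g_new
    return clip(f) * scale, options.max_iters, metric, False


def mer_reconstruct(
    spectrum: Spectrum,
    model: SpectrometerModel | None = None,
    options: MEROptions | None = None,
) -> ReconstructionResult:
    """Maximum-entropy reconstruction of a noisy spectrum.

    Returns a :class:`ReconstructionResult`; never raises on optimizer
    trouble -- a non-convergent run is reported with ``converged=False``.
    When no ME solution exists (see :func:`me_solution_exists`) the data
    are returned unprocessed with ``exists=False`` unless ``options.force``.
    """
    options = options or MEROptions()
    n = len(spectrum)
    exists = me_solution_exists(spectrum, model, options)
    if not exists and not options.force:
        f0 = np.maximum(spectrum.intensity, np.finfo(float).tiny)
        return ReconstructionResult(
            f=f0, entropy=float("nan"), chi_sq=float("nan"),
            term_metric=float("inf"), n_iters=0, converged=False, exists=False,
        )

    lam = options.lagrange_lambda
    if lam is None:
        snr = spectrum.meta.get("snr")
        if snr is None or not np.isfinite(snr):
            lam = 1.0
        else:
            lam = default_lambda(float(snr))

    log_m = _prior_log_model(options.prior, spectrum, n)
    sigma = spectrum.sigma_vector
    mask = spectrum.mask

    def run(lam_val: float):
        return _reconstruct_fixed_lambda(
            spectrum.intensity, sigma, mask, model, log_m, lam_val, options
        )

    f, iters, metric, converged = run(lam)
    if options.tune_lambda:
        # chi^2 of the converged solution decreases as lambda grows (more
        # weight on the data); expand a bracket around chi0^2 then bisect
        # on log-lambda
        def chi_of(lam_val):
            sol = run(lam_val)
            return sol, chi_squared(sol[0], spectrum, model)

        sol, chi = (f, iters, metric, converged), chi_squared(f, spectrum, model)
        lo = hi = lam
        sol_lo = sol_hi = sol
        for _ in range(12):
            if chi > options.chi0_sq:
                lo, sol_lo = lam, sol
                lam = lam * 4.0
            else:
                hi, sol_hi = lam, sol
                lam = lam / 4.0
            sol, chi = chi_of(lam)
            bracketed = (
                chi_squared(sol_lo[0], spectrum, model) > options.chi0_sq
                and chi_squared(sol_hi[0], spectrum, model) <= options.chi0_sq
                and lo < hi
            ) if lo != hi else False
            if bracketed:
                break
        if lo < hi:
            best = (abs(chi - options.chi0_sq), lam, sol)
            for _ in range(30):
                lam = float(np.sqrt(lo * hi))
                sol, chi = chi_of(lam)
                if abs(chi - options.chi0_sq) < best[0]:
                    best = (abs(chi - options.chi0_sq), lam, sol)
                if abs(chi - options.chi0_sq) < 0.02:
                    break
                if chi > options.chi0_sq:
                    lo = lam
                else:
                    hi = lam
            _, lam, sol = best
        f, iters, metric, converged = sol

    chi_final = chi_squared(f, spectrum, model)
    s_final = entropy(np.maximum(f, np.finfo(float).tiny),
                      None if options.prior is None else np.exp(log_m))
    return ReconstructionResult(
        f=f, entropy=s_final, chi_sq=chi_final, term_metric=metric,
        n_iters=iters, converged=converged, exists=True,
        lagrange_lambda=float(lam),
        floor=options.floor_eps * float(np.mean(f)),
    )


class MaximumEntropyReconstruction:
    """Scikit-learn style transformer applying MER row-wise.

    Each row of ``X`` is one spectrum sampled on the pixel grid of
    ``spectrometer``.  The noise scale is taken from ``noise_sigma``
    (scalar, per-pixel vector, or per-row scalars).

    Examples
    --------
    >>> from brispec import build_spectrometer, PeakSet, synth_truth, add_noise
    >>> model = build_spectrometer()
    >>> peaks = PeakSet()
    >>> noisy = add_noise(synth_truth(peaks, model), snr=5, seed=0)
    >>> rec = MaximumEntropyReconstruction(spectrometer=model,
    ...     noise_sigma=noisy.noise_sigma, prior=peaks, snr=5)
    >>> X = rec.fit_transform(noisy.intensity[None, :])
    """

    def __init__(
        self,
        spectrometer: SpectrometerModel | None = None,
        noise_sigma: float | ArrayLike = 1.0,
        chi0_sq: float = 1.0,
        lagrange_lambda: float | None = None,
        term_threshold: float = 0.01,
        max_iters: int = 2000,
        prior: PeakSet | None = None,
        snr: float | None = None,
        mask: ArrayLike | None = None,
    ) -> None:
        self.spectrometer = spectrometer
        self.noise_sigma = noise_sigma
        self.chi0_sq = chi0_sq
        self.lagrange_lambda = lagrange_lambda
        self.term_threshold = term_threshold
        self.max_iters = max_iters
        self.prior = prior
        self.snr = snr
        self.mask = mask

    # minimal get/set_params so the class composes with sklearn pipelines
    _param_names = (
        "spectrometer", "noise_sigma", "chi0_sq", "lagrange_lambda",
        "term_threshold", "max_iters", "prior", "snr", "mask",
    )

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params: Any) -> "MaximumEntropyReconstruction":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _axis(self, n: int) -> NDArray[np.float64]:
        if self.spectrometer is not None:
            return self.spectrometer.frequency_axis_ghz
        return np.arange(n, dtype=float)

    def fit(self, X: ArrayLike, y: Any = None) -> "MaximumEntropyReconstruction":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        if self.spectrometer is not None and self.spectrometer.n_pixels != X.shape[1]:
            raise ValueError("spectrometer pixel count does not match X")
        return self

    def transform(self, X: ArrayLike) -> NDArray[np.float64]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of pixels than seen in fit")
        axis = self._axis(X.shape[1])
        options = MEROptions(
            chi0_sq=self.chi0_sq,
            lagrange_lambda=self.lagrange_lambda,
            term_threshold=self.term_threshold,
            max_iters=self.max_iters,
            prior=self.prior,
        )
        sigma = self.noise_sigma
        per_row = np.ndim(sigma) == 1 and np.shape(sigma)[0] == X.shape[0] != X.shape[1]
        out = np.empty_like(X)
        results: list[ReconstructionResult] = []
        for i, row in enumerate(X):
            sig_i = sigma[i] if per_row else sigma
            meta = {"snr": self.snr} if self.snr is not None else {}
            spec = Spectrum(
                frequency_ghz=axis, intensity=row, noise_sigma=sig_i,
                mask=self.mask, meta=meta,
            )
            res = mer_reconstruct(spec, self.spectrometer, options)
            results.append(res)
            out[i] = res.f
        self.results_ = results
        return out

    def fit_transform(self, X: ArrayLike, y: Any = None) -> NDArray[np.float64]:
        return self.fit(X).transform(X)
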