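"""Flicker spectroscopy: vesicle tension and rigidity from contour modes.

A quasi-spherical vesicle of mean radius ``R`` shows thermal fluctuations
of its equatorial contour ``r(phi, t)``.  Decomposing the relative radial
displacement ``u(phi) = r(phi)/R - 1`` into Fourier modes
``c_n = (1/2pi) \\oint u(phi) e^{-i n phi} dphi``, the quasi-circular
(static) spectrum of the Helfrich membrane predicts

    <|c_n|^2> = (kBT / 2 kappa) / ((n^2 - 1) (n^2 + sigma R^2 / kappa))

for n >= 2 (n = 0 is dilation, n = 1 translation).  Tension ``sigma``
suppresses long-wavelength modes (low n), rigidity ``kappa`` the short
ones, which makes the pair identifiable from the mode-power profile.

Estimation is maximum likelihood: for Gaussian thermal modes the per-frame
power ``|c_n|^2`` is exponentially distributed about the model mean, so the
per-mode time-averaged powers are sufficient statistics.  An optional white
noise floor absorbs radial tracking error.  Full dynamic corrections
(camera integration time, focal-plane projection) are out of scope; an
exposure-correction hook is exposed for callers that need one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

from .units import KBT_REF

__all__ = [
    "ContourSeries",
    "SpectrumEstimate",
    "contour_modes",
    "mode_powers",
    "spectrum_model",
    "fit_fluctuation_spectrum",
]


@dataclass
class ContourSeries:
    """Equatorial contour radii sampled at equally spaced polar angles.

    ``radii`` has shape (n_frames, n_angles); ``frame_interval`` is in
    seconds.  Angles are implicit: ``phi_k = 2 pi k / n_angles``.
    """

    radii: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.radii = np.atleast_2d(np.asarray(self.radii, dtype=float))
        if self.radii.shape[1] < 64:
            raise ValueError("need at least 64 angular samples per contour")
        if np.any(self.radii <= 0):
            raise ValueError("contour radii must be positive")

    @property
    def n_frames(self) -> int:
        return self.radii.shape[0]

    @property
    def n_angles(self) -> int:
        return self.radii.shape[1]

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())


@dataclass
class SpectrumEstimate:
    """Fitted tension and rigidity with asymptotic standard errors."""

    sigma: float  # N/m
    kappa: float  # J
    sigma_stderr: float
    kappa_stderr: float
    n_range: tuple[int, int]
    noise_floor: float = 0.0  # fitted white power floor (0 if not fitted)
    converged: bool = True

    @property
    def kappa_kbt(self) -> float:
        return self.kappa / KBT_REF


def contour_modes(series: ContourSeries | np.ndarray, angles: np.ndarray | None = None
                  ) -> np.ndarray:
    """Complex contour mode amplitudes c_n per frame.

    Returns an array of shape (n_frames, n_angles//2 + 1) holding
    ``c_n`` for n = 0 .. n_angles//2; the n = 0 column is identically
    zero because u is defined relative to the per-frame mean radius.

    Raises if explicit ``angles`` are supplied and not uniformly spaced.
    """
    if isinstance(series, ContourSeries):
        radii = series.radii
    else:
        radii = np.atleast_2d(np.asarray(series, dtype=float))
    if angles is not None:
        angles = np.asarray(angles, dtype=float)
        d = np.diff(angles)
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-12):
            raise ValueError("contour angles must be uniformly spaced")
    m = radii.shape[1]
    r_mean = radii.mean(axis=1, keepdims=True)
    u = radii / r_mean - 1.0
    # (1/2pi) * oint u e^{-in phi} dphi  ==  mean over samples
    c = np.fft.rfft(u, axis=1) / m
    c[:, 0] = 0.0
    return c


def mode_powers(series: ContourSeries | np.ndarray) -> np.ndarray:
    """Time-averaged mode powers <|c_n|^2>, shape (n_angles//2 + 1,)."""
    c = contour_modes(series)
    return np.mean(np.abs(c) ** 2, axis=0)


def spectrum_model(n, sigma: float, kappa: float, R: float,
                   kbt: float = KBT_REF):
    """Expected equatorial mode power <|c_n|^2> for mode(s) n >= 2."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("spectrum is defined for modes n >= 2 "
                         "(n = 0, 1 are dilation/translation)")
    if kappa <= 0 or R <= 0 or sigma < 0:
        raise ValueError("require kappa > 0, R > 0, sigma >= 0")
    sigma_bar = sigma * R**2 / kappa
    return (kbt / (2.0 * kappa)) / ((n**2 - 1.0) * (n**2 + sigma_bar))


def fit_fluctuation_spectrum(series: "ContourSeries | np.ndarray",
                             R: float | None = None,
                             kbt: float = KBT_REF,
                             n_range: tuple[int, int] = (3, 20),
                             fit_noise_floor: bool = False,
                             exposure_correction: Callable | None = None,
                             fix_kappa: float | None = None,
                             fix_sigma: float | None = None
                             ) -> SpectrumEstimate:
    """Maximum-likelihood (sigma, kappa) from contour fluctuations.

    Per-frame mode powers are treated as exponentially distributed about
    the model mean, so the negative log likelihood per mode is
    ``F (log m_n + p_bar_n / m_n)`` with ``p_bar_n`` the observed mean
    power over ``F`` frames.  Optimization runs in log-parameter space.

    Parameters
    ----------
    series:
        A :class:`ContourSeries`, or a complex array of per-frame mode
        amplitudes of shape (frames, modes) as produced by
        :func:`contour_modes` (or by a simulation-side extractor).
    R:
        Mean vesicle radius; defaults to the series mean (required when
        mode amplitudes are passed directly).
    n_range:
        Inclusive mode range used in the fit; low modes are easily
        contaminated by drift, high modes by tracking noise.
    fit_noise_floor:
        Add a white power floor as a third fitted parameter.
    exposure_correction:
        Optional multiplicative hook ``f(n) -> factor`` applied to the
        model mean, for finite-exposure corrections.
    fix_kappa, fix_sigma:
        Hold one parameter at a known value and fit only the other
        (useful when the rigidity has been calibrated on a tensionless
        reference vesicle).
    """
    if isinstance(series, np.ndarray):
        if not np.iscomplexobj(series) or series.ndim != 2:
            raise ValueError("mode-amplitude input must be a complex "
                             "(frames, modes) array")
        if R is None:
            raise ValueError("R is required with mode-amplitude input")
        n_frames = series.shape[0]
        powers = np.mean(np.abs(series) ** 2, axis=0)
    else:
        n_frames = series.n_frames
        if R is None:
            R = series.mean_radius
        powers = mode_powers(series)
    if n_frames < 100:
        raise ValueError("need at least 100 frames for a spectrum fit")
    n_lo, n_hi = n_range
    if n_hi >= powers.size:
        raise ValueError(f"n_range {n_range} exceeds available modes "
                         f"(max {powers.size - 1})")
    if n_lo < 2:
        raise ValueError("fit range must start at n >= 2")
    n = np.arange(n_lo, n_hi + 1)
    p_bar = powers[n_lo:n_hi + 1]
    if np.all(p_bar == 0):
        raise ValueError("degenerate input: all mode powers are zero")
    corr = np.ones_like(n, dtype=float)
    if exposure_correction is not None:
        corr = np.asarray([exposure_correction(int(k)) for k in n], dtype=float)

    # moment-based initialization: kappa from the high-n (bending) tail,
    # sigma from the lowest modes
    tail = n >= max(n_hi - 4, n_lo)
    kappa0 = float(np.median(kbt / (2.0 * p_bar[tail] * n[tail] ** 4)))
    kappa0 = max(kappa0, 1e-3 * kbt)
    m_low = p_bar[0]
    sbar0 = kbt / (2.0 * kappa0 * (n[0] ** 2 - 1.0) * m_low) - n[0] ** 2
    sigma0 = max(sbar0 * kappa0 / R**2, 1e-12)

    def unpack(x):
        k = 0
        if fix_sigma is None:
            sigma = np.exp(x[k])
            k += 1
        else:
            sigma = fix_sigma
        if fix_kappa is None:
            kappa = np.exp(x[k])
            k += 1
        else:
            kappa = fix_kappa
        floor = np.exp(x[k]) if fit_noise_floor else 0.0
        return sigma, kappa, floor

    def nll(x):
        sigma, kappa, floor = unpack(x)
        m = spectrum_model(n, sigma, kappa, R, kbt) * corr + floor
        return float(n_frames * np.sum(np.log(m) + p_bar / m))

    x0 = []
    if fix_sigma is None:
        x0.append(np.log(sigma0))
    if fix_kappa is None:
        x0.append(np.log(kappa0))
    if fit_noise_floor:
        x0.append(np.log(max(p_bar[-1] * 1e-2, 1e-30)))
    if not x0:
        raise ValueError("nothing to fit: both parameters fixed")
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10,
                                     "maxiter": 20000})
    converged = bool(res.success)
    x = res.x
    sigma_hat, kappa_hat, floor_hat = unpack(x)
    sigma_hat, kappa_hat = float(sigma_hat), float(kappa_hat)
    floor_hat = float(floor_hat)

    # asymptotic errors from a central-difference Hessian in log-space
    k = x.size
    h = 1e-4
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            hess[i, j] = hess[j, i] = (
                nll(x + ei + ej) - nll(x + ei - ej)
                - nll(x - ei + ej) + nll(x - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
        free = []
        if fix_sigma is None:
            free.append("sigma")
        if fix_kappa is None:
            free.append("kappa")
        sig_err = (sigma_hat * np.sqrt(abs(cov[free.index("sigma")][
            free.index("sigma")])) if "sigma" in free else 0.0)
        kap_err = (kappa_hat * np.sqrt(abs(cov[free.index("kappa")][
            free.index("kappa")])) if "kappa" in free else 0.0)
    except np.linalg.LinAlgError:
        sig_err = kap_err = np.nan
        converged = False
    return SpectrumEstimate(sigma=sigma_hat, kappa=kappa_hat,
                            sigma_stderr=float(sig_err),
                            kappa_stderr=float(kap_err),
                            n_range=(n_lo, n_hi), noise_floor=floor_hat,
                            converged=converged)
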