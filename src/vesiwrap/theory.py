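"""Analytical model of dumbbell engulfment by a tense membrane.

The dumbbell is two tangent spheres of radius ``a`` whose junction is
smoothed by a meridional circular fillet of radius ``rho_n`` (the real
membrane bridges the geometric singularity with a catenoid-like neck).
Wrapping is assumed axisymmetric: the membrane contact line advances along
the meridian, parameterized by arc length ``s`` from the first-contact pole
(s = 0) to the far pole (s = s_max).

Energy landscape (per contact-line position)::

    E(s) = -W * A_w(s) + sigma * dA(s) + E_bend(s)

with ``A_w`` the wrapped surface area, ``dA = A_w * (1 - cos psi)/2`` the
leading-order excess membrane area pulled in against tension (``psi`` is
the meridional tangent angle of the outward surface normal relative to the
first-contact direction), and ``E_bend = integral of 2*kappa*H^2`` over the
wrapped, smoothed surface.

Kinetics are overdamped contact-line dynamics: the net thermodynamic drive
``-dE/ds`` is balanced by a frictional force ``alpha * eta_eff * L(s) * v``
proportional to the contact-line circumference ``L(s) = 2 pi r(s)``, giving
the wrap time ``T = integral ds / v(s)``.  Where the drive is non-positive
the front stalls and the model reports the stall location instead of a
time.

All quantities are SI (m, N/m, J, Pa*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid


__all__ = [
    "DumbbellGeometry",
    "EnergyParams",
    "KineticParams",
    "WrapTimeResult",
    "WrapTimeFit",
    "wrapped_area",
    "wrapping_energy",
    "energy_derivative",
    "front_velocity",
    "time_to_wrap",
    "fit_wrap_time",
    "barrier_fluctuation_scale",
]

# Fraction of the lobe radius used to regularize the contact-line
# circumference at the poles; polar caps smaller than this are not resolved
# by the front dynamics.
POLE_FLOOR_FRAC = 0.05


@dataclass(frozen=True)
class DumbbellGeometry:
    """Two tangent spheres of radius ``a`` with a fillet-smoothed neck.

    Parameters
    ----------
    a:
        Lobe radius (m); ``a = d_s / 2`` for lobes of diameter ``d_s``.
    rho_n:
        Meridional radius of the circular fillet bridging the neck (m),
        ``0 < rho_n < a``.  ``rho_n = 2 a / 3`` makes the waist a
        zero-mean-curvature (catenoid-like) neck; small values model a
        membrane forced to conform tightly to the tangent-sphere junction.
    single_lobe:
        If True the geometry degenerates to a single sphere of radius
        ``a`` (no neck, no second lobe); used for closed-form checks
        against classical sphere-wrapping results.
    """

    a: float
    rho_n: float
    single_lobe: bool = False

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("lobe radius a must be positive")
        if not self.single_lobe and not (0 < self.rho_n < self.a):
            raise ValueError("neck radius rho_n must satisfy 0 < rho_n < a")

    @classmethod
    def from_lobe_diameter(cls, d_s: float, rho_frac: float = 0.15,
                           single_lobe: bool = False) -> "DumbbellGeometry":
        a = 0.5 * d_s
        return cls(a=a, rho_n=rho_frac * a, single_lobe=single_lobe)

    @classmethod
    def conformal(cls, d_s: float) -> "DumbbellGeometry":
        """Tight neck (rho_n = 0.15 a): membrane conforming to the junction."""
        return cls.from_lobe_diameter(d_s, rho_frac=0.15)

    @classmethod
    def catenoid_neck(cls, d_s: float) -> "DumbbellGeometry":
        """Relaxed neck (rho_n = 2a/3): zero mean curvature at the waist."""
        return cls.from_lobe_diameter(d_s, rho_frac=2.0 / 3.0)

    # -- piecewise meridian -------------------------------------------------

    @property
    def beta_t(self) -> float:
        """Sphere polar angle (from the neck) at the sphere/fillet tangency."""
        return float(np.arccos(self.a / (self.a + self.rho_n)))

    @property
    def c_fillet(self) -> float:
        """Radial offset of the fillet tube centre from the symmetry axis."""
        return float((self.a + self.rho_n) * np.sin(self.beta_t))

    @property
    def s_lobe1(self) -> float:
        if self.single_lobe:
            return np.pi * self.a
        return self.a * (np.pi - self.beta_t)

    @property
    def s_fillet(self) -> float:
        if self.single_lobe:
            return self.s_lobe1
        return self.s_lobe1 + self.rho_n * (np.pi - 2.0 * self.beta_t)

    @property
    def s_max(self) -> float:
        if self.single_lobe:
            return np.pi * self.a
        return self.s_fillet + self.a * (np.pi - self.beta_t)

    @property
    def s_waist(self) -> float:
        """Arc-length of the waist (innermost neck circle)."""
        if self.single_lobe:
            raise ValueError("single-lobe geometry has no waist")
        return self.s_lobe1 + self.rho_n * (np.pi / 2.0 - self.beta_t)

    @property
    def neck_radius(self) -> float:
        return self.c_fillet - self.rho_n

    def profile(self, s):
        """Meridian profile at arc length ``s``.

        Returns ``(r, psi, kappa_m, kappa_phi)``: distance from the
        symmetry axis, normal tilt angle from the first-contact direction,
        meridional curvature (= d psi/d s) and azimuthal curvature, all
        signed relative to the outward surface normal.
        """
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-12) or np.any(s > self.s_max * (1 + 1e-12)):
            raise ValueError("arc length s outside [0, s_max]")
        s = np.clip(s, 0.0, self.s_max)
        a = self.a
        if self.single_lobe:
            psi = s / a
            r = a * np.sin(psi)
            km = np.full_like(s, 1.0 / a)
            kphi = np.full_like(s, 1.0 / a)
            return r, psi, km, kphi

        rho, c, beta = self.rho_n, self.c_fillet, self.beta_t
        r = np.empty_like(s)
        psi = np.empty_like(s)
        km = np.empty_like(s)
        kphi = np.empty_like(s)

        m1 = s <= self.s_lobe1
        m2 = (s > self.s_lobe1) & (s <= self.s_fillet)
        m3 = s > self.s_fillet

        # lobe 1 sphere
        psi[m1] = s[m1] / a
        r[m1] = a * np.sin(psi[m1])
        km[m1] = 1.0 / a
        kphi[m1] = 1.0 / a

        # fillet: psi runs from pi - beta down to beta
        t = (s[m2] - self.s_lobe1) / rho
        psi[m2] = (np.pi - beta) - t
        r[m2] = c - rho * np.sin(psi[m2])
        km[m2] = -1.0 / rho
        kphi[m2] = np.sin(psi[m2]) / r[m2]

        # lobe 2 sphere: psi runs from beta back up to pi
        psi[m3] = beta + (s[m3] - self.s_fillet) / a
        r[m3] = a * np.sin(psi[m3])
        km[m3] = 1.0 / a
        kphi[m3] = 1.0 / a
        return r, psi, km, kphi


@dataclass(frozen=True)
class EnergyParams:
    """Adhesion energy per area W (J/m^2), tension sigma (N/m), rigidity kappa (J)."""

    W: float
    sigma: float
    kappa: float

    def __post_init__(self):
        # zeros are admitted so tensionless / rigidity-free limits can be
        # compared against closed-form sphere-wrapping expressions
        if self.W < 0:
            raise ValueError("adhesion energy W must be non-negative")
        if self.sigma < 0:
            raise ValueError("tension sigma must be non-negative")
        if self.kappa < 0:
            raise ValueError("bending rigidity kappa must be non-negative")


@dataclass(frozen=True)
class KineticParams:
    """Membrane microviscosity eta_eff (Pa*s) and drag coefficient alpha."""

    eta_eff: float
    alpha: float = 1.0

    def __post_init__(self):
        if self.eta_eff <= 0 or self.alpha <= 0:
            raise ValueError("eta_eff and alpha must be positive")


# ---------------------------------------------------------------------------
# geometry

def wrapped_area(s, geometry: DumbbellGeometry):
    """Area of the dumbbell surface poleward of the front at arc length s.

    Piecewise closed form: spherical caps on the lobes plus the analytic
    area of the fillet band.  Strictly increasing in s.
    """
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    if np.any(s < -1e-12) or np.any(s > geometry.s_max * (1 + 1e-12)):
        raise ValueError("arc length s outside [0, s_max]")
    s = np.clip(s, 0.0, geometry.s_max)
    a = geometry.a
    if geometry.single_lobe:
        area = 2.0 * np.pi * a**2 * (1.0 - np.cos(s / a))
        return float(area[0]) if scalar else area

    rho, c, beta = geometry.rho_n, geometry.c_fillet, geometry.beta_t
    area = np.empty_like(s)

    m1 = s <= geometry.s_lobe1
    m2 = (s > geometry.s_lobe1) & (s <= geometry.s_fillet)
    m3 = s > geometry.s_fillet

    area[m1] = 2.0 * np.pi * a**2 * (1.0 - np.cos(s[m1] / a))

    a_lobe1 = 2.0 * np.pi * a**2 * (1.0 + np.cos(beta))
    t = (s[m2] - geometry.s_lobe1) / rho
    # fillet band: integral of 2 pi r ds with r = c - rho*sin(beta + t')
    area[m2] = a_lobe1 + 2.0 * np.pi * rho * (
        c * t - rho * (np.cos(beta) - np.cos(beta + t))
    )

    t_f = np.pi - 2.0 * beta
    a_fillet = 2.0 * np.pi * rho * (c * t_f - 2.0 * rho * np.cos(beta))
    psi3 = beta + (s[m3] - geometry.s_fillet) / a
    area[m3] = a_lobe1 + a_fillet + 2.0 * np.pi * a**2 * (np.cos(beta) - np.cos(psi3))
    return float(area[0]) if scalar else area


def _fillet_bend_integral(geometry: DumbbellGeometry, s):
    """Cumulative integral of 2 H^2 dA over the fillet up to arc s (vector).

    Geometric part of the fillet bending energy (multiply by kappa).
    Computed by composite Simpson-grade trapezoid on a fine fixed grid.
    """
    if geometry.single_lobe:
        return np.zeros_like(np.asarray(s, dtype=float))
    npts = 4001
    sg = np.linspace(geometry.s_lobe1, geometry.s_fillet, npts)
    r, _, km, kphi = geometry.profile(sg)
    h = 0.5 * (km + kphi)
    integrand = 2.0 * h**2 * 2.0 * np.pi * r
    cum = np.concatenate([[0.0], cumulative_trapezoid(integrand, sg)])
    s = np.asarray(s, dtype=float)
    sc = np.clip(s, geometry.s_lobe1, geometry.s_fillet)
    return np.interp(sc, sg, cum)


def _bending_energy(s, kappa: float, geometry: DumbbellGeometry):
    """E_bend(s) = integral of 2 kappa H^2 dA over the wrapped surface."""
    s = np.asarray(s, dtype=float)
    a = geometry.a
    if geometry.single_lobe:
        return (2.0 * kappa / a**2) * wrapped_area(s, geometry)
    s1, s2 = geometry.s_lobe1, geometry.s_fillet
    # sphere contributions (H = 1/a constant)
    area_sph = np.where(
        s <= s1,
        wrapped_area(np.minimum(s, s1), geometry),
        wrapped_area(np.minimum(s, s1), geometry)
        + np.where(
            s > s2,
            wrapped_area(np.clip(s, s2, geometry.s_max), geometry)
            - wrapped_area(np.full_like(s, s2), geometry),
            0.0,
        ),
    )
    e = (2.0 * kappa / a**2) * area_sph
    e = e + kappa * _fillet_bend_integral(geometry, s)
    return e


def wrapping_energy(s, params: EnergyParams, geometry: DumbbellGeometry):
    """Engulfment energy landscape E(s); continuous, E(0) = 0."""
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    aw = wrapped_area(s, geometry)
    _, psi, _, _ = geometry.profile(s)
    d_area = aw * (1.0 - np.cos(psi)) / 2.0
    e = -params.W * aw + params.sigma * d_area + _bending_energy(s, params.kappa, geometry)
    return float(e[0]) if scalar else e


def energy_derivative(s, params: EnergyParams, geometry: DumbbellGeometry):
    """Analytic dE/ds along the meridian."""
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    r, psi, km, kphi = geometry.profile(s)
    aw = wrapped_area(s, geometry)
    h2 = (0.5 * (km + kphi)) ** 2
    dads = 2.0 * np.pi * r
    de = dads * (-params.W + params.sigma * (1.0 - np.cos(psi)) / 2.0
                 + 2.0 * params.kappa * h2)
    # psi varies with s at rate kappa_m; excess-area term picks up A_w sin(psi) psi'
    de = de + params.sigma * aw * np.sin(psi) * km / 2.0
    return float(de[0]) if scalar else de


def _arc_window(geometry: DumbbellGeometry):
    """Resolved arc range: polar caps below the drag floor are excluded."""
    r_floor = POLE_FLOOR_FRAC * geometry.a
    s_lo = geometry.a * np.arcsin(r_floor / geometry.a)
    return s_lo, geometry.s_max - s_lo


def front_velocity(s, params: EnergyParams, kinetics: KineticParams,
                   geometry: DumbbellGeometry):
    """Overdamped front speed v(s) = max(0, -dE/ds) / (alpha eta_eff L(s)).

    The contact-line circumference ``L(s) = 2 pi r(s)`` is floored at
    ``2 pi * 0.05 a`` so the drag never vanishes at the poles.
    """
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    r, _, _, _ = geometry.profile(s)
    circumference = 2.0 * np.pi * np.maximum(r, POLE_FLOOR_FRAC * geometry.a)
    drive = -energy_derivative(s, params, geometry)
    v = np.maximum(drive, 0.0) / (kinetics.alpha * kinetics.eta_eff * circumference)
    return float(v[0]) if scalar else v


@dataclass(frozen=True)
class WrapTimeResult:
    """Outcome of the front dynamics: a wrap time or a stall location."""

    time: float  # seconds; inf when stalled
    stalled: bool
    s_stall: float | None = None  # arc length of first stall, if stalled

    def __float__(self):
        return self.time


def time_to_wrap(sigma: float, params: EnergyParams, kinetics: KineticParams,
                 geometry: DumbbellGeometry, n_grid: int = 4096) -> WrapTimeResult:
    """Time for the front to traverse the dumbbell at tension ``sigma``.

    ``params.sigma`` is ignored in favour of the ``sigma`` argument so the
    same adhesion/rigidity set can be swept over tensions.  Returns a
    stalled result with the first stall arc length when the drive is
    non-positive anywhere in the resolved arc range.
    """
    from scipy.integrate import quad

    p = EnergyParams(W=params.W, sigma=sigma, kappa=params.kappa)
    s_lo, s_hi = _arc_window(geometry)
    s = np.linspace(s_lo, s_hi, n_grid)
    drive = -energy_derivative(s, p, geometry)
    if np.any(drive <= 0.0):
        i = int(np.argmax(drive <= 0.0))
        s_stall = float(s[i])
        if i == 0:
            s_stall = 0.0  # stalled at first contact
        return WrapTimeResult(time=np.inf, stalled=True, s_stall=s_stall)
    breaks = [b for b in (geometry.s_lobe1, geometry.s_fillet)
              if s_lo < b < s_hi and not geometry.single_lobe]
    t, _ = quad(lambda x: 1.0 / front_velocity(x, p, kinetics, geometry),
                s_lo, s_hi, points=breaks or None, limit=200, epsrel=1e-11)
    return WrapTimeResult(time=float(t), stalled=False)


def _pseudo_log_time(sigma, w, eta, kappa, alpha, geometry, n_grid=4096):
    """Smooth surrogate of log T used inside the fit.

    Identical to ``time_to_wrap`` where wrapping completes; where the drive
    goes non-positive the drive is floored at a tiny positive value, which
    produces an enormous but finite, smoothly varying time so the optimizer
    is pushed back toward completing parameter sets.
    """
    from scipy.integrate import simpson

    p = EnergyParams(W=w, sigma=sigma, kappa=kappa)
    s_lo, s_hi = _arc_window(geometry)
    breaks = [s_lo] + [b for b in (geometry.s_lobe1, geometry.s_fillet)
                       if s_lo < b < s_hi and not geometry.single_lobe] + [s_hi]
    floor = 1e-9 * max(w, 1e-12) * geometry.a
    t = 0.0
    n_seg = max(n_grid // (len(breaks) - 1), 64) | 1  # odd for Simpson
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        s = np.linspace(lo, hi, n_seg)
        r, _, _, _ = geometry.profile(s)
        circ = 2.0 * np.pi * np.maximum(r, POLE_FLOOR_FRAC * geometry.a)
        drive = -energy_derivative(s, p, geometry)
        soft = floor * np.exp(np.clip((drive - floor) / floor, -60.0, 0.0))
        drive = np.where(drive > floor, drive, soft)
        t += simpson(alpha * eta * circ / drive, x=s)
    return np.log(t)


@dataclass
class WrapTimeFit:
    """Least-squares fit of (W, eta_eff) to wrap-time-vs-tension data."""

    W: float
    eta_eff: float
    W_stderr: float
    eta_stderr: float
    residuals: np.ndarray  # log-space residuals at the fitted parameters
    n_used: int
    n_excluded: int  # non-finite (stalled) data points excluded
    cov: np.ndarray = field(repr=False, default=None)


def fit_wrap_time(sigmas: Sequence[float], times: Sequence[float],
                  geometry: DumbbellGeometry, kappa: float,
                  alpha: float = 1.0, p0: tuple[float, float] | None = None
                  ) -> WrapTimeFit:
    """Fit adhesion energy W and microviscosity eta_eff to (sigma, T) data.

    Least squares on log T; data points with non-finite T (stalled runs)
    are excluded and counted.  Confidence information comes from the
    Jacobian at the optimum.  Requires at least 3 completing points.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    times = np.asarray(times, dtype=float)
    if sigmas.shape != times.shape:
        raise ValueError("sigma and time arrays must have the same shape")
    ok = np.isfinite(times) & (times > 0)
    n_excluded = int((~ok).sum())
    sigmas, times = sigmas[ok], times[ok]
    if sigmas.size < 3:
        raise ValueError("need at least 3 completing (sigma, T) points")
    log_t = np.log(times)

    if p0 is None:
        # crude but scale-aware start: W from the bending floor, eta from
        # a single evaluation at the smallest tension
        w0 = 4.0 * kappa / geometry.a**2
        lt0 = _pseudo_log_time(sigmas.min(), w0, 1.0, kappa, alpha, geometry)
        eta0 = float(np.exp(np.median(log_t) - lt0))
        p0 = (w0, max(eta0, 1e-6))

    def residual(x):
        w, eta = np.exp(x)
        model = np.array([
            _pseudo_log_time(sg, w, eta, kappa, alpha, geometry) for sg in sigmas
        ])
        return model - log_t

    res = optimize.least_squares(residual, x0=np.log(p0), xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14)
    w_hat, eta_hat = np.exp(res.x)
    dof = max(sigmas.size - 2, 1)
    s2 = float(res.fun @ res.fun) / dof
    jtj = res.jac.T @ res.jac
    try:
        cov_log = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov_log = np.full((2, 2), np.nan)
    # delta method back to linear scale
    w_err = w_hat * np.sqrt(abs(cov_log[0, 0]))
    eta_err = eta_hat * np.sqrt(abs(cov_log[1, 1]))
    return WrapTimeFit(W=float(w_hat), eta_eff=float(eta_hat),
                       W_stderr=float(w_err), eta_stderr=float(eta_err),
                       residuals=res.fun, n_used=int(sigmas.size),
                       n_excluded=n_excluded, cov=cov_log)


def barrier_fluctuation_scale(params: EnergyParams, geometry: DumbbellGeometry,
                              n_grid: int = 8192) -> float:
    """Membrane-fluctuation amplitude needed to cross the waist barrier.

    Finds the largest uphill climb DeltaE of E(s) from any preceding
    minimum (zero if E is monotone downhill), then converts it to the
    normal-displacement amplitude ``h*`` of a single effective bending/
    tension mode of wavevector ``q = pi / a`` over the waist annulus of
    area ``pi (a^2 - rho_n^2)``::

        DeltaE = 0.5 * (sigma q^2 + kappa q^4) * A_annulus * h*^2

    This is an order-of-magnitude estimator, not a full stochastic
    calculation.  Returns h* in metres.
    """
    s = np.linspace(0.0, geometry.s_max, n_grid)
    e = wrapping_energy(s, params, geometry)
    running_min = np.minimum.accumulate(e)
    delta_e = float(np.max(e - running_min))
    if delta_e <= 0.0:
        return 0.0
    q = np.pi / geometry.a
    rho = 0.0 if geometry.single_lobe else geometry.rho_n
    area = np.pi * (geometry.a**2 - rho**2)
    stiffness = params.sigma * q**2 + params.kappa * q**4
    return float(np.sqrt(2.0 * delta_e / (stiffness * area)))
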