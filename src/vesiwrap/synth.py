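"""Synthetic inputs for every pipeline stage.

Three generators, all deterministic given (parameters, seed):

- :func:`synth_contours` draws equatorial contour series of a
  quasi-spherical vesicle with known tension and rigidity (thermal modes
  plus optional white tracking noise) to exercise flicker spectroscopy.
- :func:`synth_pathway` produces dumbbell wrapping trajectories with the
  characteristic milestones of the four observed pathway classes
  (parallel/perpendicular start x full/half final state): tilt-angle and
  insertion-depth tracks, per-lobe wrapped fractions, and the geometric
  frames (positions, axes) they derive from.  Templates are smooth
  milestone interpolants with additive tracking noise, not mechanistic
  simulations — they exist to test observables and classifiers.
- :func:`synth_wraptime_dataset` samples the analytical wrap-time theory
  on a tension grid with multiplicative lognormal noise to exercise
  parameter fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import theory
from .analysis import ObservableSeries
from .flicker import ContourSeries, spectrum_model
from .units import KBT_REF

__all__ = [
    "PathwayTemplate",
    "PATHWAY_TEMPLATES",
    "SyntheticPathway",
    "synth_contours",
    "synth_pathway",
    "synth_wraptime_dataset",
]


# ---------------------------------------------------------------------------
# contour series

def synth_contours(sigma: float, kappa: float, R: float, n_frames: int,
                   noise_floor: float = 0.0, seed: int = 0,
                   n_angles: int = 256, n_max: int = 64,
                   kbt: float = KBT_REF, frame_interval: float = 0.05
                   ) -> ContourSeries:
    """Equatorial contour fluctuations of a vesicle with known (sigma, kappa).

    Per frame, mode amplitudes c_n (n = 2 .. n_max) are drawn as complex
    Gaussians with <|c_n|^2> given by the quasi-circular spectrum, inverse
    transformed to r(phi), and corrupted by white radial tracking noise of
    rms ``noise_floor`` (same length unit as R).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    n = np.arange(2, n_max + 1)
    m_n = spectrum_model(n, sigma, kappa, R, kbt)
    # real-signal parameterization u = sum a_n cos + b_n sin with
    # <a^2> = <b^2> = 2 <|c_n|^2>
    amp = np.sqrt(2.0 * m_n)
    a = rng.normal(0.0, 1.0, size=(n_frames, n.size)) * amp
    b = rng.normal(0.0, 1.0, size=(n_frames, n.size)) * amp
    phi = 2.0 * np.pi * np.arange(n_angles) / n_angles
    cosm = np.cos(np.outer(n, phi))
    sinm = np.sin(np.outer(n, phi))
    u = a @ cosm + b @ sinm
    radii = R * (1.0 + u)
    if noise_floor > 0.0:
        radii = radii + rng.normal(0.0, noise_floor, size=radii.shape)
    return ContourSeries(radii=radii, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# pathway templates

@dataclass(frozen=True)
class PathwayTemplate:
    """Milestone script of one wrapping pathway class.

    ``milestones`` rows are (time fraction, theta_deg, d/d_s, f1, f2);
    ``contact2_from`` is the time fraction at which the second lobe first
    touches the membrane (None: never).  Noise amplitudes emulate optical
    tracking precision.
    """

    name: str
    milestones: tuple
    contact2_from: float | None
    end_state: str  # "F" or "D"
    duration: float = 120.0       # seconds
    n_frames: int = 720
    noise_theta_deg: float = 3.0  # rms tracking noise on theta
    noise_d: float = 0.03e-6      # rms tracking noise on d (m)
    d_s: float = 0.98e-6          # lobe diameter (m)
    R_vesicle: float = 7.5e-6     # undistorted vesicle radius (m)


PATHWAY_TEMPLATES: dict[str, PathwayTemplate] = {
    # initially parallel (theta ~ 90), both lobes attach, tilts to ~60 while
    # descending, overshoots to d ~ 1.5 d_s, recoils to the d ~ 0.7 d_s plateau
    "parallel_full": PathwayTemplate(
        name="parallel_full",
        milestones=(
            (0.00, 90.0, 0.00, 0.00, 0.00),
            (0.10, 82.0, 0.05, 0.10, 0.06),
            (0.30, 60.0, 0.45, 0.50, 0.30),
            (0.50, 63.0, 1.00, 0.88, 0.60),
            (0.62, 68.0, 1.45, 0.96, 0.85),
            (0.70, 70.0, 1.50, 0.97, 0.93),
            (0.80, 75.0, 1.10, 0.98, 0.95),
            (1.00, 76.0, 0.70, 0.99, 0.97),
        ),
        contact2_from=0.0, end_state="F"),
    # initially perpendicular, straightens to theta ~ 10 by the halfway point
    # (d = 0), then the second lobe binds and it finishes tilted
    "perpendicular_full": PathwayTemplate(
        name="perpendicular_full",
        milestones=(
            (0.00, 25.0, -1.00, 0.02, 0.00),
            (0.20, 15.0, -0.55, 0.30, 0.00),
            (0.45, 10.0, 0.00, 0.85, 0.04),
            (0.65, 30.0, 0.35, 0.95, 0.35),
            (0.85, 55.0, 0.60, 0.97, 0.90),
            (1.00, 65.0, 0.70, 0.98, 0.96),
        ),
        contact2_from=0.45, end_state="F"),
    # initially parallel, reorients perpendicular while one lobe is engulfed
    # up to the waist; second lobe never binds
    "parallel_half": PathwayTemplate(
        name="parallel_half",
        milestones=(
            (0.00, 85.0, -0.40, 0.01, 0.00),
            (0.30, 60.0, -0.10, 0.30, 0.00),
            (0.60, 35.0, 0.20, 0.70, 0.00),
            (1.00, 15.0, 0.50, 0.95, 0.00),
        ),
        contact2_from=None, end_state="D"),
    # initially perpendicular, transiently more parallel, then engulfed to
    # the waist while turning perpendicular again; no overshoot
    "perpendicular_half": PathwayTemplate(
        name="perpendicular_half",
        milestones=(
            (0.00, 15.0, -1.00, 0.01, 0.00),
            (0.25, 45.0, -0.55, 0.20, 0.00),
            (0.55, 30.0, 0.00, 0.60, 0.00),
            (1.00, 10.0, 0.50, 0.96, 0.00),
        ),
        contact2_from=None, end_state="D"),
}


@dataclass
class SyntheticPathway:
    """Geometric frames plus ground-truth observables of one pathway draw."""

    template: PathwayTemplate
    frames: pd.DataFrame = field(repr=False)
    observables: ObservableSeries = field(repr=False)


def synth_pathway(template: str | PathwayTemplate, seed: int = 0,
                  z0_frac: float = 0.3) -> SyntheticPathway:
    """Draw one noisy wrapping trajectory from a pathway template.

    Theta/d/f tracks are monotone-cubic interpolants through the template
    milestones plus Gaussian tracking noise.  Geometric frames place the
    dumbbell on a virtual vesicle (centre at the origin) at slowly
    drifting latitude ``z ~ z0_frac * R`` so the equatorial band filter
    retains the trajectory, with the axis tilted by theta from the local
    radial direction.
    """
    if isinstance(template, str):
        try:
            template = PATHWAY_TEMPLATES[template]
        except KeyError:
            raise ValueError(
                f"unknown pathway template {template!r}; available: "
                f"{sorted(PATHWAY_TEMPLATES)}") from None
    tpl = template
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, tpl.duration, tpl.n_frames)
    frac = t / tpl.duration
    ms = np.asarray(tpl.milestones, dtype=float)
    theta = PchipInterpolator(ms[:, 0], ms[:, 1])(frac)
    d = PchipInterpolator(ms[:, 0], ms[:, 2])(frac) * tpl.d_s
    f1 = PchipInterpolator(ms[:, 0], ms[:, 3])(frac)
    f2 = PchipInterpolator(ms[:, 0], ms[:, 4])(frac)

    theta = np.clip(theta + rng.normal(0.0, tpl.noise_theta_deg, t.size), 0.0, 90.0)
    d = d + rng.normal(0.0, tpl.noise_d, t.size)
    f1 = np.clip(f1 + rng.normal(0.0, 0.01, t.size), 0.0, 1.0)
    f2 = np.clip(f2 + rng.normal(0.0, 0.01, t.size), 0.0, 1.0)
    contact2 = (np.zeros(t.size, dtype=bool) if tpl.contact2_from is None
                else frac >= tpl.contact2_from)
    # keep the ground-truth ordering: lobe 1 is the more-wrapped lobe
    f1, f2 = np.maximum(f1, f2), np.minimum(f1, f2)

    R = tpl.R_vesicle
    # slow latitude drift well inside the +-0.8 R tracking band
    zfrac = z0_frac + 0.08 * np.sin(2.0 * np.pi * frac * 0.7)
    lat = np.arcsin(np.clip(zfrac, -0.95, 0.95))
    azi = 0.3 * np.sin(2.0 * np.pi * frac * 0.23) + 0.05 * 2 * np.pi * frac
    radial = np.column_stack([np.cos(lat) * np.cos(azi),
                              np.cos(lat) * np.sin(azi), np.sin(lat)])
    com = (R - d)[:, None] * radial
    # in-plane direction for the tilt, slowly precessing
    ref = np.array([0.0, 0.0, 1.0])
    w = np.cross(radial, ref)
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    spin = 2.0 * np.pi * frac * 0.11
    w2 = np.cross(radial, w)
    inplane = np.cos(spin)[:, None] * w + np.sin(spin)[:, None] * w2
    th_rad = np.radians(theta)
    axis = np.cos(th_rad)[:, None] * radial + np.sin(th_rad)[:, None] * inplane

    frames = pd.DataFrame({
        "time": t,
        "com_x": com[:, 0], "com_y": com[:, 1], "com_z": com[:, 2],
        "axis_x": axis[:, 0], "axis_y": axis[:, 1], "axis_z": axis[:, 2],
        "center_x": 0.0, "center_y": 0.0, "center_z": 0.0,
        "R": R, "z": com[:, 2],
    })
    obs = ObservableSeries(time=t, theta=theta, d=d, z=com[:, 2],
                           f1=f1, f2=f2, second_contact=contact2)
    return SyntheticPathway(template=tpl, frames=frames, observables=obs)


# ---------------------------------------------------------------------------
# wrap-time datasets

def synth_wraptime_dataset(W: float, eta_eff: float, sigma_grid,
                           cv: float = 0.05, seed: int = 0,
                           geometry: theory.DumbbellGeometry | None = None,
                           kappa: float = 20.0 * KBT_REF,
                           alpha: float = 1.0) -> pd.DataFrame:
    """Wrap-time-vs-tension dataset T_i = T(sigma_i) * exp(eps_i).

    ``eps_i ~ Normal(0, cv^2)`` is multiplicative lognormal noise.  All
    tensions must lie below the stall threshold of the theory; stalled
    entries raise with the offending tensions listed.
    """
    if geometry is None:
        geometry = theory.DumbbellGeometry.catenoid_neck(0.98e-6)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    params = theory.EnergyParams(W=W, sigma=0.0, kappa=kappa)
    kin = theory.KineticParams(eta_eff=eta_eff, alpha=alpha)
    results = [theory.time_to_wrap(s, params, kin, geometry) for s in sigma_grid]
    stalled = [s for s, r in zip(sigma_grid, results) if r.stalled]
    if stalled:
        raise ValueError(
            "wrapping stalls at tension(s) "
            + ", ".join(f"{s:.3g} N/m" for s in stalled)
            + "; choose tensions below the stall threshold")
    t_clean = np.array([r.time for r in results])
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, cv, size=t_clean.size) if cv > 0 else np.zeros_like(t_clean)
    return pd.DataFrame({
        "sigma": sigma_grid,
        "time": t_clean * np.exp(noise),
        "time_true": t_clean,
    })
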