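"""Reference (NumPy) implementations of the interaction potentials.

These scalar-pair routines define the model; the numba kernels in
``kernels.py`` reimplement them for speed and are cross-checked against
this module in the test suite.

Membrane pair potential (beads i, j at separation r, orientations n_i,
n_j, with r_hat the unit separation vector)::

    Phi  = 1 + mu * [ (n_i x r_hat).(n_j x r_hat)
                      + sin(theta0) (n_j - n_i).r_hat - sin^2(theta0) - 1 ]
    u    = eps [ (r_min/r)^4 - 2 (r_min/r)^2 ] + eps (1 - Phi),   r < r_min
    u    = -eps cos^{2 zeta}( (pi/2)(r - r_min)/(r_cut - r_min) ) * Phi,
                                                         r_min <= r < r_cut
    u    = 0,                                            r >= r_cut

The repulsive branch decouples distance and orientation; the attractive
branch is maximally deep (-eps) for a perfectly aligned pair (Phi = 1 at
theta0 = 0) and vanishes smoothly at r_cut.

Dumbbell adhesion acts on the signed distance ``delta`` from a bead to the
*nearest* lobe surface (no double counting at the neck)::

    u_ad = eps_ad [ (d0/delta)^4 - 2 (d0/delta)^2 ],   delta < d0
    u_ad = -eps_ad cos^2( (pi/2)(delta - d0)/(r_cut_ad - d0) ),
                                                d0 <= delta < r_cut_ad

with contact distance ``d0`` (default half a bead diameter).  The
repulsive branch is linearized below ``0.4 d0`` so a bead overlapping a
lobe feels a strong but finite force.
"""

from __future__ import annotations

import numpy as np

from .params import MembranePotentialParams

__all__ = ["membrane_pair_potential", "adhesion_energy", "ADHESION_CONTACT"]

ADHESION_CONTACT = 0.5  # contact distance d0 above the lobe surface, sigma_b
_CAP_FRAC = 0.4  # below this fraction of d0 the adhesive repulsion is linearized


def membrane_pair_potential(r_vec, n_i, n_j, params: MembranePotentialParams):
    """Energy, forces, and orientation torques of one membrane bead pair.

    Parameters
    ----------
    r_vec:
        Separation vector ``x_j - x_i``.
    n_i, n_j:
        Unit orientation vectors of the two beads.

    Returns
    -------
    dict with keys ``energy``, ``force_i``, ``force_j`` (forces are exact
    negative gradients; ``force_i = -force_j``), and ``torque_i``,
    ``torque_j`` (rotational generalized forces ``-n x dU/dn``).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise ValueError("overlapping beads: zero separation")
    eps, mu, zeta = params.epsilon, params.mu, params.zeta
    rmin, rcut = params.r_min, params.r_cut
    st0 = np.sin(params.theta0)
    zero = {
        "energy": 0.0, "force_i": np.zeros(3), "force_j": np.zeros(3),
        "torque_i": np.zeros(3), "torque_j": np.zeros(3),
    }
    if r >= rcut:
        return zero
    rhat = r_vec / r
    nn = float(n_i @ n_j)
    nir = float(n_i @ rhat)
    njr = float(n_j @ rhat)
    phi = 1.0 + mu * (nn - nir * njr + st0 * float((n_j - n_i) @ rhat)
                      - st0 * st0 - 1.0)
    dphi_dni = mu * (n_j - njr * rhat - st0 * rhat)
    dphi_dnj = mu * (n_i - nir * rhat + st0 * rhat)
    dphi_drhat = mu * (-nir * n_j - njr * n_i + st0 * (n_j - n_i))

    if r < rmin:
        x2 = (rmin / r) ** 2
        u = eps * (x2 * x2 - 2.0 * x2) + eps * (1.0 - phi)
        dudr = eps * (-4.0 * x2 * x2 + 4.0 * x2) / r
        dudphi = -eps
    else:
        k = 0.5 * np.pi / (rcut - rmin)
        c = np.cos(k * (r - rmin))
        s = np.sin(k * (r - rmin))
        ua = -eps * c ** (2.0 * zeta)
        u = ua * phi
        dudr = eps * 2.0 * zeta * k * c ** (2.0 * zeta - 1.0) * s * phi
        dudphi = ua

    # gradient wrt x_j: radial part + orientation part through r_hat
    g_perp = dphi_drhat - float(dphi_drhat @ rhat) * rhat
    grad_j = dudr * rhat + dudphi * g_perp / r
    force_j = -grad_j
    force_i = grad_j
    gn_i = dudphi * dphi_dni
    gn_j = dudphi * dphi_dnj
    return {
        "energy": float(u),
        "force_i": force_i, "force_j": force_j,
        "torque_i": -np.cross(n_i, gn_i), "torque_j": -np.cross(n_j, gn_j),
    }


def _adhesion_delta(delta: float, eps_ad: float, d0: float, dc: float):
    """(u, du/ddelta) of the adhesion well at surface distance delta."""
    if delta >= dc:
        return 0.0, 0.0
    cap = _CAP_FRAC * d0
    if delta < d0:
        de = max(delta, cap)
        x2 = (d0 / de) ** 2
        u = eps_ad * (x2 * x2 - 2.0 * x2)
        dud = eps_ad * (-4.0 * x2 * x2 + 4.0 * x2) / de
        if delta < cap:
            # linear extension: finite repulsion for beads inside a lobe
            u = u + dud * (delta - cap)
        return u, dud
    k = 0.5 * np.pi / (dc - d0)
    c = np.cos(k * (delta - d0))
    s = np.sin(k * (delta - d0))
    return -eps_ad * c * c, 2.0 * eps_ad * k * c * s


def adhesion_energy(bead_pos, dumbbell, epsilon_ad: float, r_cut_ad: float,
                    d0: float = ADHESION_CONTACT):
    """Adhesion energy and force on one membrane bead from the dumbbell.

    The well acts on the distance to the *nearest* lobe surface only, so
    a bead in the neck region is never double counted.  Returns
    ``(energy, force_on_bead, force_on_dumbbell, torque_on_dumbbell)``
    with the torque taken about the dumbbell centre.
    """
    x = np.asarray(bead_pos, dtype=float)
    if r_cut_ad <= d0:
        raise ValueError("adhesion cutoff must exceed the contact distance")
    c1, c2 = dumbbell.lobe_centers()
    best = None
    for ck in (c1, c2):
        v = x - ck
        dist = float(np.linalg.norm(v))
        if best is None or dist - dumbbell.lobe_radius < best[0]:
            best = (dist - dumbbell.lobe_radius, v, dist, ck)
    delta, v, dist, ck = best
    u, dud = _adhesion_delta(delta, epsilon_ad, d0, r_cut_ad)
    dhat = v / dist if dist > 0 else np.array([0.0, 0.0, 1.0])
    f_bead = -dud * dhat
    f_db = -f_bead
    torque = np.cross(ck - dumbbell.center, f_db)
    return float(u), f_bead, f_db, torque
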