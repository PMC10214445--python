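"""Numba kernels for the Langevin membrane + dumbbell dynamics.

Everything here mirrors the reference potentials in ``potential.py`` and
is cross-checked against them in the test suite.  Particle types:
0 = membrane bead, 1 = interior solute, 2 = exterior solute.  All
positions live in a cubic periodic box of side ``box``; pair vectors use
the minimal image.

The integrator is BAOAB-style Langevin: half-kick, half-drift, thermostat
(Ornstein-Uhlenbeck), half-drift, force, half-kick.  Membrane bead
orientations carry an angular velocity perpendicular to the orientation
vector and feel the rotational analogue; the dumbbell is a rigid body
with quaternion orientation and body-frame angular velocity.  With the
thermostat off (``kBT = 0`` or zero friction) the scheme reduces to
velocity Verlet and conserves energy to O(dt^2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# WCA length scales (sigma_b units)
SIGMA_SS = 0.5   # solute-solute
SIGMA_SM = 0.75  # solute-membrane bead
SIGMA_SD = 0.5   # solute-dumbbell surface (acts on surface distance)
ADH_D0 = 0.5     # adhesion contact distance above lobe surface
ADH_CAP_FRAC = 0.4
WCA_EVAL_FLOOR = 0.65  # fraction of sigma below which WCA force saturates
MASS_MEMBRANE = 1.0
MASS_SOLUTE = 0.5
INERTIA_NORMAL = 1.0


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _min_image(d, box):
    if d > 0.5 * box:
        d -= box
    elif d < -0.5 * box:
        d += box
    return d


@njit(cache=True)
def build_pairs(pos, box, rlist, pairs):
    """Cell-list pair construction; returns pair count (-1 on overflow)."""
    n = pos.shape[0]
    ncell = int(box / rlist)
    if ncell < 3:
        ncell = 3
    cell_sz = box / ncell
    head = -np.ones(ncell * ncell * ncell, dtype=np.int32)
    nxt = -np.ones(n, dtype=np.int32)
    cidx = np.empty(n, dtype=np.int32)
    for i in range(n):
        cx = int(pos[i, 0] / cell_sz) % ncell
        cy = int(pos[i, 1] / cell_sz) % ncell
        cz = int(pos[i, 2] / cell_sz) % ncell
        c = (cx * ncell + cy) * ncell + cz
        cidx[i] = c
        nxt[i] = head[c]
        head[c] = i
    rl2 = rlist * rlist
    cap = pairs.shape[0]
    np_count = 0
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                i = head[c]
                while i >= 0:
                    # same cell
                    j = nxt[i]
                    while j >= 0:
                        dx = _min_image(pos[i, 0] - pos[j, 0], box)
                        dy = _min_image(pos[i, 1] - pos[j, 1], box)
                        dz = _min_image(pos[i, 2] - pos[j, 2], box)
                        if dx * dx + dy * dy + dz * dz < rl2:
                            if np_count >= cap:
                                return -1
                            pairs[np_count, 0] = i
                            pairs[np_count, 1] = j
                            np_count += 1
                        j = nxt[j]
                    # half of the neighbouring cells
                    for sh in range(13):
                        ox = _CELL_SHIFTS[sh, 0]
                        oy = _CELL_SHIFTS[sh, 1]
                        oz = _CELL_SHIFTS[sh, 2]
                        c2 = (((cx + ox) % ncell) * ncell
                              + ((cy + oy) % ncell)) * ncell + ((cz + oz) % ncell)
                        j = head[c2]
                        while j >= 0:
                            dx = _min_image(pos[i, 0] - pos[j, 0], box)
                            dy = _min_image(pos[i, 1] - pos[j, 1], box)
                            dz = _min_image(pos[i, 2] - pos[j, 2], box)
                            if dx * dx + dy * dy + dz * dz < rl2:
                                if np_count >= cap:
                                    return -1
                                pairs[np_count, 0] = i
                                pairs[np_count, 1] = j
                                np_count += 1
                            j = nxt[j]
                    i = nxt[i]
    return np_count


_CELL_SHIFTS = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
], dtype=np.int64)


@njit(cache=True, inline="always")
def _ipow(base, n):
    """base**n for small non-negative integer n (fast path for cos^2zeta)."""
    out = 1.0
    b = base
    m = n
    while m > 0:
        if m & 1:
            out *= b
        b *= b
        m >>= 1
    return out


@njit(cache=True, fastmath=True)
def compute_forces(pos, nrm, typ, pairs, n_pairs, box,
                   eps, mu, zeta, st0, rmin, rcut,
                   f, gn, vc, radial_acc):
    """Pair forces: membrane-membrane, solute-solute, solute-membrane.

    Fills ``f`` (forces) and ``gn`` (dU/dn for membrane orientations),
    returns potential energy.  ``radial_acc`` (length 2) accumulates the
    net radial force exerted by interior/exterior solutes on the
    membrane, measured about the vesicle centre ``vc`` (for the osmotic
    pressure-difference estimate).
    """
    pe = 0.0
    rcut2 = rcut * rcut
    k_att = 0.5 * np.pi / (rcut - rmin)
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        ti = typ[i]
        tj = typ[j]
        dx = _min_image(pos[j, 0] - pos[i, 0], box)
        dy = _min_image(pos[j, 1] - pos[i, 1], box)
        dz = _min_image(pos[j, 2] - pos[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if ti == 0 and tj == 0:
            if r2 >= rcut2:
                continue
            r = np.sqrt(r2)
            rhx = dx / r
            rhy = dy / r
            rhz = dz / r
            nix, niy, niz = nrm[i, 0], nrm[i, 1], nrm[i, 2]
            njx, njy, njz = nrm[j, 0], nrm[j, 1], nrm[j, 2]
            nn = nix * njx + niy * njy + niz * njz
            nir = nix * rhx + niy * rhy + niz * rhz
            njr = njx * rhx + njy * rhy + njz * rhz
            phi = 1.0 + mu * (nn - nir * njr
                              + st0 * ((njx - nix) * rhx + (njy - niy) * rhy
                                       + (njz - niz) * rhz)
                              - st0 * st0 - 1.0)
            if r < rmin:
                x2 = (rmin / r) * (rmin / r)
                pe += eps * (x2 * x2 - 2.0 * x2) + eps * (1.0 - phi)
                dudr = eps * (-4.0 * x2 * x2 + 4.0 * x2) / r
                dudphi = -eps
            else:
                c = np.cos(k_att * (r - rmin))
                s = np.sin(k_att * (r - rmin))
                two_zeta = int(2.0 * zeta)
                if two_zeta == 2.0 * zeta:
                    czm1 = _ipow(c, two_zeta - 1)
                    cz = czm1 * c
                else:
                    cz = c ** (2.0 * zeta)
                    czm1 = c ** (2.0 * zeta - 1.0)
                ua = -eps * cz
                pe += ua * phi
                dudr = eps * 2.0 * zeta * k_att * czm1 * s * phi
                dudphi = ua
            # dPhi/drhat
            gx = mu * (-nir * njx - njr * nix + st0 * (njx - nix))
            gy = mu * (-nir * njy - njr * niy + st0 * (njy - niy))
            gz = mu * (-nir * njz - njr * niz + st0 * (njz - niz))
            gdotr = gx * rhx + gy * rhy + gz * rhz
            px = (gx - gdotr * rhx) / r
            py = (gy - gdotr * rhy) / r
            pz = (gz - gdotr * rhz) / r
            fjx = -(dudr * rhx + dudphi * px)
            fjy = -(dudr * rhy + dudphi * py)
            fjz = -(dudr * rhz + dudphi * pz)
            f[j, 0] += fjx
            f[j, 1] += fjy
            f[j, 2] += fjz
            f[i, 0] -= fjx
            f[i, 1] -= fjy
            f[i, 2] -= fjz
            gn[i, 0] += dudphi * mu * (njx - njr * rhx - st0 * rhx)
            gn[i, 1] += dudphi * mu * (njy - njr * rhy - st0 * rhy)
            gn[i, 2] += dudphi * mu * (njz - njr * rhz - st0 * rhz)
            gn[j, 0] += dudphi * mu * (nix - nir * rhx + st0 * rhx)
            gn[j, 1] += dudphi * mu * (niy - nir * rhy + st0 * rhy)
            gn[j, 2] += dudphi * mu * (niz - nir * rhz + st0 * rhz)
        else:
            # WCA branches
            if ti > 0 and tj > 0:
                sig = SIGMA_SS
            else:
                sig = SIGMA_SM
            wcut = sig * 1.1224620483093729  # 2^(1/6) sigma
            if r2 >= wcut * wcut:
                continue
            r = np.sqrt(r2)
            re = r
            floor_r = WCA_EVAL_FLOOR * sig
            if re < floor_r:
                re = floor_r
            sr2 = (sig / re) * (sig / re)
            sr6 = sr2 * sr2 * sr2
            pe += 4.0 * (sr6 * sr6 - sr6) + 1.0
            fmag = 24.0 * (2.0 * sr6 * sr6 - sr6) / re  # magnitude along -rhat on j
            fjx = fmag * dx / r
            fjy = fmag * dy / r
            fjz = fmag * dz / r
            f[j, 0] += fjx
            f[j, 1] += fjy
            f[j, 2] += fjz
            f[i, 0] -= fjx
            f[i, 1] -= fjy
            f[i, 2] -= fjz
            if ti == 0 or tj == 0:
                # radial force on the membrane bead from this solute
                if ti == 0:
                    b = i
                    frx, fry, frz = -fjx, -fjy, -fjz
                    stype = tj
                else:
                    b = j
                    frx, fry, frz = fjx, fjy, fjz
                    stype = ti
                ux = _min_image(pos[b, 0] - vc[0], box)
                uy = _min_image(pos[b, 1] - vc[1], box)
                uz = _min_image(pos[b, 2] - vc[2], box)
                un = np.sqrt(ux * ux + uy * uy + uz * uz)
                if un > 0:
                    radial_acc[stype - 1] += (frx * ux + fry * uy + frz * uz) / un
    return pe


@njit(cache=True)
def dumbbell_forces(pos, typ, box, dbc, dbax, a, eps_ad, rc_ad,
                    f):
    """Adhesion (membrane) and exclusion (solute) forces from the dumbbell.

    Returns (potential energy, force on dumbbell (3,), torque about its
    centre (3,), contact count lobe +, contact count lobe -).  Contact
    counts are membrane beads within the adhesive range of each lobe
    surface (nearest-lobe assignment).
    """
    n = pos.shape[0]
    fd = np.zeros(3)
    td = np.zeros(3)
    pe = 0.0
    nc1 = 0
    nc2 = 0
    d0 = ADH_D0
    cap = ADH_CAP_FRAC * d0
    k_ad = 0.5 * np.pi / (rc_ad - d0)
    wcut_sd = SIGMA_SD * 1.1224620483093729
    reach = a + max(rc_ad, wcut_sd) + 1.0
    for i in range(n):
        dx = _min_image(pos[i, 0] - dbc[0], box)
        dy = _min_image(pos[i, 1] - dbc[1], box)
        dz = _min_image(pos[i, 2] - dbc[2], box)
        # quick reject on distance to the centre
        rr = np.sqrt(dx * dx + dy * dy + dz * dz)
        if rr > reach + a:
            continue
        proj = dx * dbax[0] + dy * dbax[1] + dz * dbax[2]
        sgn = 1.0 if proj >= 0.0 else -1.0
        # nearest lobe centre
        cx = sgn * a * dbax[0]
        cy = sgn * a * dbax[1]
        cz = sgn * a * dbax[2]
        vx = dx - cx
        vy = dy - cy
        vz = dz - cz
        dist = np.sqrt(vx * vx + vy * vy + vz * vz)
        delta = dist - a
        if typ[i] == 0:
            if delta >= rc_ad:
                continue
            if delta < d0:
                de = delta if delta > cap else cap
                x2 = (d0 / de) * (d0 / de)
                u = eps_ad * (x2 * x2 - 2.0 * x2)
                dud = eps_ad * (-4.0 * x2 * x2 + 4.0 * x2) / de
                if delta < cap:
                    u += dud * (delta - cap)
                pe += u
            else:
                c = np.cos(k_ad * (delta - d0))
                s = np.sin(k_ad * (delta - d0))
                pe += -eps_ad * c * c
                dud = 2.0 * eps_ad * k_ad * c * s
            if sgn > 0:
                nc1 += 1
            else:
                nc2 += 1
        else:
            if delta >= wcut_sd:
                continue
            de = delta
            floor_d = WCA_EVAL_FLOOR * SIGMA_SD
            if de < floor_d:
                de = floor_d
            sr2 = (SIGMA_SD / de) * (SIGMA_SD / de)
            sr6 = sr2 * sr2 * sr2
            pe += 4.0 * (sr6 * sr6 - sr6) + 1.0
            dud = -24.0 * (2.0 * sr6 * sr6 - sr6) / de
        if dist > 1e-12:
            dhx = vx / dist
            dhy = vy / dist
            dhz = vz / dist
        else:
            dhx, dhy, dhz = 0.0, 0.0, 1.0
        fbx = -dud * dhx
        fby = -dud * dhy
        fbz = -dud * dhz
        f[i, 0] += fbx
        f[i, 1] += fby
        f[i, 2] += fbz
        fd[0] -= fbx
        fd[1] -= fby
        fd[2] -= fbz
        # torque about the dumbbell centre; force acts along the line
        # through the lobe centre, so apply it there
        td[0] += cy * (-fbz) - cz * (-fby)
        td[1] += cz * (-fbx) - cx * (-fbz)
        td[2] += cx * (-fby) - cy * (-fbx)
    return pe, fd, td, nc1, nc2


@njit(cache=True)
def neighbor_counts(pos, typ, pairs, n_pairs, box, rcut):
    """Membrane-membrane neighbour count per bead within rcut."""
    n = pos.shape[0]
    cnt = np.zeros(n, dtype=np.int32)
    rc2 = rcut * rcut
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if typ[i] != 0 or typ[j] != 0:
            continue
        dx = _min_image(pos[j, 0] - pos[i, 0], box)
        dy = _min_image(pos[j, 1] - pos[i, 1], box)
        dz = _min_image(pos[j, 2] - pos[i, 2], box)
        if dx * dx + dy * dy + dz * dz < rc2:
            cnt[i] += 1
            cnt[j] += 1
    return cnt


@njit(cache=True, inline="always")
def _rotate_about(vx, vy, vz, kx, ky, kz, angle):
    """Rodrigues rotation of v about unit axis k."""
    c = np.cos(angle)
    s = np.sin(angle)
    kdotv = kx * vx + ky * vy + kz * vz
    cx = ky * vz - kz * vy
    cy = kz * vx - kx * vz
    cz = kx * vy - ky * vx
    rx = vx * c + cx * s + kx * kdotv * (1.0 - c)
    ry = vy * c + cy * s + ky * kdotv * (1.0 - c)
    rz = vz * c + cz * s + kz * kdotv * (1.0 - c)
    return rx, ry, rz


@njit(cache=True)
def _quat_mul(q1, q2):
    out = np.empty(4)
    out[0] = q1[0] * q2[0] - q1[1] * q2[1] - q1[2] * q2[2] - q1[3] * q2[3]
    out[1] = q1[0] * q2[1] + q1[1] * q2[0] + q1[2] * q2[3] - q1[3] * q2[2]
    out[2] = q1[0] * q2[2] - q1[1] * q2[3] + q1[2] * q2[0] + q1[3] * q2[1]
    out[3] = q1[0] * q2[3] + q1[1] * q2[2] - q1[2] * q2[1] + q1[3] * q2[0]
    return out


@njit(cache=True)
def _quat_axis(q):
    """Third column of the rotation matrix (body z axis in the lab frame)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    out = np.empty(3)
    out[0] = 2.0 * (x * z + w * y)
    out[1] = 2.0 * (y * z - w * x)
    out[2] = 1.0 - 2.0 * (x * x + y * y)
    return out


@njit(cache=True)
def _quat_rotate_vec(q, v, transpose):
    """R(q) v (transpose=False) or R(q)^T v (True)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    if transpose:
        x, y, z = -x, -y, -z
    out = np.empty(3)
    tx = 2.0 * (y * v[2] - z * v[1])
    ty = 2.0 * (z * v[0] - x * v[2])
    tz = 2.0 * (x * v[1] - y * v[0])
    out[0] = v[0] + w * tx + (y * tz - z * ty)
    out[1] = v[1] + w * ty + (z * tx - x * tz)
    out[2] = v[2] + w * tz + (x * ty - y * tx)
    return out


@njit(cache=True, fastmath=True)
def run_steps(pos, nrm, typ, vel, ang,
              dbc, dbq, dbv, dbw, db_on, db_mass, db_inertia, a,
              box, n_steps,
              eps, mu, zeta, st0, rmin, rcut,
              eps_ad, rc_ad,
              dt, kBT, gamma_t, gamma_r,
              rlist, skin, pairs, pos_ref,
              state_out, radial_acc):
    """Advance the system ``n_steps`` BAOAB steps.

    ``state_out`` (float64[8]) returns: [0] potential energy, [1] pair
    count, [2] rebuild count, [3] lobe1 contacts, [4] lobe2 contacts,
    [5] translational kinetic energy, [6] rotational (normal) kinetic
    energy, [7] status (0 ok, 1 pair overflow).
    ``radial_acc`` accumulates solute radial force sums (interior,
    exterior, sample count) for pressure estimates.
    """
    n = pos.shape[0]
    nm = 0
    for i in range(n):
        if typ[i] == 0:
            nm += 1
    f = np.zeros((n, 3))
    gn = np.zeros((n, 3))
    vc = np.zeros(3)

    c1t = np.exp(-gamma_t * dt)
    c1r = np.exp(-gamma_r * dt)

    # vesicle centre for pressure bookkeeping
    for i in range(n):
        if typ[i] == 0:
            vc[0] += pos[i, 0]
            vc[1] += pos[i, 1]
            vc[2] += pos[i, 2]
    if nm > 0:
        vc /= nm

    n_pairs = build_pairs(pos, box, rlist, pairs)
    if n_pairs < 0:
        state_out[7] = 1.0
        return
    for i in range(n):
        pos_ref[i, 0] = pos[i, 0]
        pos_ref[i, 1] = pos[i, 1]
        pos_ref[i, 2] = pos[i, 2]
    rebuilds = 0.0

    # initial forces
    f[:] = 0.0
    gn[:] = 0.0
    rtmp = np.zeros(2)
    pe = compute_forces(pos, nrm, typ, pairs, n_pairs, box,
                        eps, mu, zeta, st0, rmin, rcut, f, gn, vc, rtmp)
    nc1 = 0
    nc2 = 0
    if db_on:
        dbax = _quat_axis(dbq)
        pe_d, fd, td, nc1, nc2 = dumbbell_forces(pos, typ, box, dbc, dbax, a,
                                                 eps_ad, rc_ad, f)
        pe += pe_d
    else:
        fd = np.zeros(3)
        td = np.zeros(3)

    half = 0.5 * dt
    skin_half2 = (0.5 * skin) * (0.5 * skin)

    for step in range(n_steps):
        # --- B: half kick
        for i in range(n):
            m = MASS_MEMBRANE if typ[i] == 0 else MASS_SOLUTE
            vel[i, 0] += half * f[i, 0] / m
            vel[i, 1] += half * f[i, 1] / m
            vel[i, 2] += half * f[i, 2] / m
            if typ[i] == 0:
                # torque on the orientation: tau = -n x dU/dn
                tx = -(nrm[i, 1] * gn[i, 2] - nrm[i, 2] * gn[i, 1])
                ty = -(nrm[i, 2] * gn[i, 0] - nrm[i, 0] * gn[i, 2])
                tz = -(nrm[i, 0] * gn[i, 1] - nrm[i, 1] * gn[i, 0])
                ang[i, 0] += half * tx / INERTIA_NORMAL
                ang[i, 1] += half * ty / INERTIA_NORMAL
                ang[i, 2] += half * tz / INERTIA_NORMAL
        if db_on:
            for k in range(3):
                dbv[k] += half * fd[k] / db_mass
            tb = _quat_rotate_vec(dbq, td, True)
            # Euler equations with gyroscopic term
            dbw[0] += half * (tb[0] - (db_inertia[2] - db_inertia[1])
                              * dbw[1] * dbw[2]) / db_inertia[0]
            dbw[1] += half * (tb[1] - (db_inertia[0] - db_inertia[2])
                              * dbw[2] * dbw[0]) / db_inertia[1]
            dbw[2] += half * (tb[2] - (db_inertia[1] - db_inertia[0])
                              * dbw[0] * dbw[1]) / db_inertia[2]

        # --- A: half drift
        for i in range(n):
            pos[i, 0] = (pos[i, 0] + half * vel[i, 0]) % box
            pos[i, 1] = (pos[i, 1] + half * vel[i, 1]) % box
            pos[i, 2] = (pos[i, 2] + half * vel[i, 2]) % box
            if typ[i] == 0:
                wx, wy, wz = ang[i, 0], ang[i, 1], ang[i, 2]
                wn = np.sqrt(wx * wx + wy * wy + wz * wz)
                if wn > 1e-14:
                    rx, ry, rz = _rotate_about(nrm[i, 0], nrm[i, 1], nrm[i, 2],
                                               wx / wn, wy / wn, wz / wn,
                                               wn * half)
                    nn = np.sqrt(rx * rx + ry * ry + rz * rz)
                    nrm[i, 0] = rx / nn
                    nrm[i, 1] = ry / nn
                    nrm[i, 2] = rz / nn
        if db_on:
            for k in range(3):
                dbc[k] += half * dbv[k]
            wn = np.sqrt(dbw[0] ** 2 + dbw[1] ** 2 + dbw[2] ** 2)
            if wn > 1e-14:
                dq = np.empty(4)
                hang = 0.5 * wn * half
                dq[0] = np.cos(hang)
                sfac = np.sin(hang) / wn
                dq[1] = dbw[0] * sfac
                dq[2] = dbw[1] * sfac
                dq[3] = dbw[2] * sfac
                qn = _quat_mul(dbq, dq)
                qq = np.sqrt(qn[0] ** 2 + qn[1] ** 2 + qn[2] ** 2 + qn[3] ** 2)
                for k in range(4):
                    dbq[k] = qn[k] / qq

        # --- O: thermostat
        if kBT > 0.0:
            for i in range(n):
                m = MASS_MEMBRANE if typ[i] == 0 else MASS_SOLUTE
                sd = np.sqrt(kBT * (1.0 - c1t * c1t) / m)
                vel[i, 0] = c1t * vel[i, 0] + sd * np.random.normal()
                vel[i, 1] = c1t * vel[i, 1] + sd * np.random.normal()
                vel[i, 2] = c1t * vel[i, 2] + sd * np.random.normal()
                if typ[i] == 0:
                    sdr = np.sqrt(kBT * (1.0 - c1r * c1r) / INERTIA_NORMAL)
                    wx = c1r * ang[i, 0] + sdr * np.random.normal()
                    wy = c1r * ang[i, 1] + sdr * np.random.normal()
                    wz = c1r * ang[i, 2] + sdr * np.random.normal()
                    # keep only the spin perpendicular to the orientation
                    dot = wx * nrm[i, 0] + wy * nrm[i, 1] + wz * nrm[i, 2]
                    ang[i, 0] = wx - dot * nrm[i, 0]
                    ang[i, 1] = wy - dot * nrm[i, 1]
                    ang[i, 2] = wz - dot * nrm[i, 2]
            if db_on:
                sdv = np.sqrt(kBT * (1.0 - c1t * c1t) / db_mass)
                for k in range(3):
                    dbv[k] = c1t * dbv[k] + sdv * np.random.normal()
                for k in range(3):
                    sdw = np.sqrt(kBT * (1.0 - c1r * c1r) / db_inertia[k])
                    dbw[k] = c1r * dbw[k] + sdw * np.random.normal()

        # --- A: half drift
        max_disp2 = 0.0
        for i in range(n):
            pos[i, 0] = (pos[i, 0] + half * vel[i, 0]) % box
            pos[i, 1] = (pos[i, 1] + half * vel[i, 1]) % box
            pos[i, 2] = (pos[i, 2] + half * vel[i, 2]) % box
            if typ[i] == 0:
                wx, wy, wz = ang[i, 0], ang[i, 1], ang[i, 2]
                wn = np.sqrt(wx * wx + wy * wy + wz * wz)
                if wn > 1e-14:
                    rx, ry, rz = _rotate_about(nrm[i, 0], nrm[i, 1], nrm[i, 2],
                                               wx / wn, wy / wn, wz / wn,
                                               wn * half)
                    nn = np.sqrt(rx * rx + ry * ry + rz * rz)
                    nrm[i, 0] = rx / nn
                    nrm[i, 1] = ry / nn
                    nrm[i, 2] = rz / nn
            ddx = _min_image(pos[i, 0] - pos_ref[i, 0], box)
            ddy = _min_image(pos[i, 1] - pos_ref[i, 1], box)
            ddz = _min_image(pos[i, 2] - pos_ref[i, 2], box)
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_disp2:
                max_disp2 = d2
        if db_on:
            for k in range(3):
                dbc[k] += half * dbv[k]
            wn = np.sqrt(dbw[0] ** 2 + dbw[1] ** 2 + dbw[2] ** 2)
            if wn > 1e-14:
                dq = np.empty(4)
                hang = 0.5 * wn * half
                dq[0] = np.cos(hang)
                sfac = np.sin(hang) / wn
                dq[1] = dbw[0] * sfac
                dq[2] = dbw[1] * sfac
                dq[3] = dbw[2] * sfac
                qn = _quat_mul(dbq, dq)
                qq = np.sqrt(qn[0] ** 2 + qn[1] ** 2 + qn[2] ** 2 + qn[3] ** 2)
                for k in range(4):
                    dbq[k] = qn[k] / qq

        # --- pair list maintenance
        if max_disp2 > skin_half2:
            n_pairs = build_pairs(pos, box, rlist, pairs)
            if n_pairs < 0:
                state_out[7] = 1.0
                return
            rebuilds += 1.0
            for i in range(n):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]

        # --- forces at the new positions
        f[:] = 0.0
        gn[:] = 0.0
        pe = compute_forces(pos, nrm, typ, pairs, n_pairs, box,
                            eps, mu, zeta, st0, rmin, rcut, f, gn, vc,
                            radial_acc)
        if db_on:
            dbax = _quat_axis(dbq)
            pe_d, fd, td, nc1, nc2 = dumbbell_forces(pos, typ, box, dbc, dbax,
                                                     a, eps_ad, rc_ad, f)
            pe += pe_d
        radial_acc[2] += 1.0

        # --- B: half kick
        for i in range(n):
            m = MASS_MEMBRANE if typ[i] == 0 else MASS_SOLUTE
            vel[i, 0] += half * f[i, 0] / m
            vel[i, 1] += half * f[i, 1] / m
            vel[i, 2] += half * f[i, 2] / m
            if typ[i] == 0:
                tx = -(nrm[i, 1] * gn[i, 2] - nrm[i, 2] * gn[i, 1])
                ty = -(nrm[i, 2] * gn[i, 0] - nrm[i, 0] * gn[i, 2])
                tz = -(nrm[i, 0] * gn[i, 1] - nrm[i, 1] * gn[i, 0])
                ang[i, 0] += half * tx / INERTIA_NORMAL
                ang[i, 1] += half * ty / INERTIA_NORMAL
                ang[i, 2] += half * tz / INERTIA_NORMAL
        if db_on:
            for k in range(3):
                dbv[k] += half * fd[k] / db_mass
            tb = _quat_rotate_vec(dbq, td, True)
            dbw[0] += half * (tb[0] - (db_inertia[2] - db_inertia[1])
                              * dbw[1] * dbw[2]) / db_inertia[0]
            dbw[1] += half * (tb[1] - (db_inertia[0] - db_inertia[2])
                              * dbw[2] * dbw[0]) / db_inertia[1]
            dbw[2] += half * (tb[2] - (db_inertia[1] - db_inertia[0])
                              * dbw[0] * dbw[1]) / db_inertia[2]

    # kinetic energies for diagnostics
    ke_t = 0.0
    ke_r = 0.0
    for i in range(n):
        m = MASS_MEMBRANE if typ[i] == 0 else MASS_SOLUTE
        ke_t += 0.5 * m * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        if typ[i] == 0:
            ke_r += 0.5 * INERTIA_NORMAL * (ang[i, 0] ** 2 + ang[i, 1] ** 2
                                            + ang[i, 2] ** 2)
    state_out[0] = pe
    state_out[1] = float(n_pairs)
    state_out[2] = rebuilds
    state_out[3] = float(nc1)
    state_out[4] = float(nc2)
    state_out[5] = ke_t
    state_out[6] = ke_r
    state_out[7] = 0.0
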