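"""Langevin dynamics driver: runs the kernels, collects snapshots.

``run_dynamics`` advances a :class:`MembraneState` (plus an optional rigid
:class:`DumbbellBody`) with the BAOAB Langevin integrator and returns a
:class:`Trajectory` of snapshots.  Runs terminate early with a rupture
flag when a membrane bead loses its neighbourhood for a sustained window
(the membrane has torn, e.g. under excessive adhesive load).

Identical (state, params, seed) inputs reproduce trajectories bitwise:
the kernels are single-threaded and draw all noise from one seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import kernels
from .dumbbell import DumbbellBody
from .params import MembranePotentialParams, SimParams
from .vesicle import MembraneState

__all__ = ["Trajectory", "run_dynamics", "place_dumbbell", "measure_pressure_difference"]

RUPTURE_MIN_NEIGHBORS = 3
RUPTURE_WINDOW_STEPS = 100  # deficiency must persist at least this long
EVAPORATION_TOLERANCE = 0.02  # tolerated fraction of evaporated monomers


@dataclass
class Snapshot:
    time: float
    bead_positions: np.ndarray
    bead_normals: np.ndarray
    solute_positions: np.ndarray
    db_center: np.ndarray | None
    db_axis: np.ndarray | None
    potential_energy: float
    kinetic_energy: float
    kinetic_energy_rot: float
    contacts: tuple[int, int]


@dataclass
class Trajectory:
    """Snapshots plus run-level flags and osmotic-pressure bookkeeping."""

    params: SimParams
    potential: MembranePotentialParams
    box: float
    n_beads: int
    n_solute_in: int
    n_solute_out: int
    lobe_radius: float | None
    snapshots: list[Snapshot] = field(default_factory=list)
    ruptured: bool = False
    rupture_step: int | None = None
    radial_force_sums: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def final_state(self) -> MembraneState:
        s = self.snapshots[-1]
        nsol_in = self.n_solute_in
        return MembraneState(
            bead_positions=s.bead_positions.copy(),
            bead_normals=s.bead_normals.copy(),
            solute_in_positions=s.solute_positions[:nsol_in].copy(),
            solute_out_positions=s.solute_positions[nsol_in:].copy(),
            box=self.box)

    def final_dumbbell(self) -> DumbbellBody | None:
        s = self.snapshots[-1]
        if s.db_center is None:
            return None
        return DumbbellBody.from_axis(s.db_center, s.db_axis, self.lobe_radius)

    def pressure_difference(self) -> float:
        """Mean osmotic pressure difference (interior minus exterior).

        Estimated from the time-averaged net radial force the solutes
        exert on the membrane, divided by the area of the effective wall
        surface (one solute-membrane exclusion length inside the bead
        centres, where the collisions actually happen).
        """
        n_samples = self.radial_force_sums[2]
        if n_samples == 0:
            return 0.0
        s0 = self.snapshots[-1]
        c = s0.bead_positions.mean(axis=0)
        r_mean = np.linalg.norm(s0.bead_positions - c, axis=1).mean()
        r_wall = r_mean - kernels.SIGMA_SM
        area = 4.0 * np.pi * r_wall**2
        net = (self.radial_force_sums[0] + self.radial_force_sums[1]) / n_samples
        return float(net / area)


def place_dumbbell(state: MembraneState, lobe_radius: float,
                   placement: str = "perpendicular", seed: int = 0,
                   tilt_deg_max: float = 5.0, gap: float = None
                   ) -> DumbbellBody:
    """Put a dumbbell tangent to the vesicle exterior at the +z pole.

    ``perpendicular``: long axis along the local outward normal;
    ``parallel``: long axis in the membrane tangent plane.  A random tilt
    up to ``tilt_deg_max`` degrees (drawn from the seed) breaks exact
    symmetry, as thermal attachment would.
    """
    rng = np.random.default_rng(seed)
    c = state.center()
    R = state.mean_radius()
    a = lobe_radius
    if gap is None:
        gap = kernels.ADH_D0
    zhat = np.array([0.0, 0.0, 1.0])
    if placement == "perpendicular":
        center = c + (R + gap + 2.0 * a) * zhat
        axis = zhat.copy()
    elif placement == "parallel":
        center = c + (R + gap + a) * zhat
        axis = np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError(f"unknown placement {placement!r}")
    tilt = np.radians(tilt_deg_max) * rng.random()
    about = rng.standard_normal(3)
    about -= (about @ axis) * axis
    about /= np.linalg.norm(about)
    ca, sa = np.cos(tilt), np.sin(tilt)
    axis = ca * axis + sa * np.cross(about, axis)
    axis /= np.linalg.norm(axis)
    return DumbbellBody.from_axis(center, axis, lobe_radius)


def run_dynamics(state: MembraneState, params: SimParams,
                 potential: MembranePotentialParams | None = None,
                 dumbbell: DumbbellBody | None = None,
                 rupture_check: bool = True,
                 stop_condition=None) -> Trajectory:
    """Advance the system ``params.n_steps`` steps; snapshots at the stride.

    ``stop_condition``, if given, is called with the running trajectory
    after every snapshot; returning True ends the run early (used e.g. to
    stop once a terminal wrapping state is reached).
    """
    potential = potential or MembranePotentialParams()
    if state.box is None:
        raise ValueError("state needs a periodic box")
    box = float(state.box)

    nm = state.n_beads
    ns_in = state.solute_in_positions.shape[0]
    ns_out = state.solute_out_positions.shape[0]
    n = nm + ns_in + ns_out
    pos = np.concatenate([state.bead_positions, state.solute_in_positions,
                          state.solute_out_positions]).astype(float) % box
    nrm = np.zeros((n, 3))
    nrm[:nm] = state.bead_normals
    nrm[:nm] /= np.linalg.norm(nrm[:nm], axis=1, keepdims=True)
    typ = np.zeros(n, dtype=np.int8)
    typ[nm:nm + ns_in] = 1
    typ[nm + ns_in:] = 2
    vel = np.zeros((n, 3))
    ang = np.zeros((n, 3))

    db_on = dumbbell is not None
    if db_on:
        dbc = dumbbell.center.astype(float).copy()
        dbq = dumbbell.quat.astype(float).copy()
        db_mass = dumbbell.mass
        db_inertia = dumbbell.inertia_body()
        a = dumbbell.lobe_radius
    else:
        dbc = np.zeros(3)
        dbq = np.array([1.0, 0.0, 0.0, 0.0])
        db_mass = 1.0
        db_inertia = np.ones(3)
        a = 1.0
    dbv = np.zeros(3)
    dbw = np.zeros(3)

    skin = 0.4
    rlist = potential.r_cut + skin
    pairs = np.empty((max(90 * n, 20000), 2), dtype=np.int32)
    pos_ref = np.empty_like(pos)
    state_out = np.zeros(8)
    radial_acc = np.zeros(3)

    kernels.seed_rng(params.seed % (2**31 - 1))

    traj = Trajectory(params=params, potential=potential, box=box,
                      n_beads=nm, n_solute_in=ns_in, n_solute_out=ns_out,
                      lobe_radius=(a if db_on else None))

    stride = max(1, min(params.snapshot_stride, params.n_steps))
    steps_done = 0
    deficient_since: int | None = None

    def record():
        ke_t = state_out[5]
        traj.snapshots.append(Snapshot(
            time=steps_done * params.dt * params.tau0,
            bead_positions=pos[:nm].copy(),
            bead_normals=nrm[:nm].copy(),
            solute_positions=pos[nm:].copy(),
            db_center=dbc.copy() if db_on else None,
            db_axis=kernels._quat_axis(dbq).copy() if db_on else None,
            potential_energy=state_out[0],
            kinetic_energy=ke_t,
            kinetic_energy_rot=state_out[6],
            contacts=(int(state_out[3]), int(state_out[4]))))

    # record the initial state (forces evaluated over 0 steps)
    kernels.run_steps(pos, nrm, typ, vel, ang, dbc, dbq, dbv, dbw,
                      db_on, db_mass, db_inertia, a, box, 0,
                      potential.epsilon, potential.mu, potential.zeta,
                      np.sin(potential.theta0), potential.r_min,
                      potential.r_cut, params.epsilon_ad, params.r_cut_ad,
                      params.dt, params.kBT, params.gamma_t, params.gamma_r,
                      rlist, skin, pairs, pos_ref, state_out, radial_acc)
    if state_out[7] != 0:
        raise RuntimeError("pair list overflow at initialization")
    record()

    while steps_done < params.n_steps:
        chunk = min(stride, params.n_steps - steps_done)
        kernels.run_steps(pos, nrm, typ, vel, ang, dbc, dbq, dbv, dbw,
                          db_on, db_mass, db_inertia, a, box, chunk,
                          potential.epsilon, potential.mu, potential.zeta,
                          np.sin(potential.theta0), potential.r_min,
                          potential.r_cut, params.epsilon_ad, params.r_cut_ad,
                          params.dt, params.kBT, params.gamma_t,
                          params.gamma_r, rlist, skin, pairs, pos_ref,
                          state_out, radial_acc)
        if state_out[7] != 0:
            raise RuntimeError("pair list overflow during run")
        steps_done += chunk
        record()

        if stop_condition is not None and stop_condition(traj):
            break

        if rupture_check:
            # distinguish a tear (clustered under-coordinated beads = hole
            # rim) from benign single-bead evaporation, which the
            # self-healing membrane tolerates in small numbers
            tree = cKDTree(pos[:nm])
            counts = tree.query_ball_point(
                pos[:nm], potential.r_cut, return_length=True) - 1
            deficient = np.where(counts < RUPTURE_MIN_NEIGHBORS)[0]
            torn = False
            if deficient.size > EVAPORATION_TOLERANCE * nm:
                torn = True
            elif deficient.size >= 2:
                dt_def = cKDTree(pos[:nm][deficient])
                nbr = dt_def.query_ball_point(
                    pos[:nm][deficient], 2.0 * potential.r_cut,
                    return_length=True) - 1
                if np.any(nbr >= 2):
                    torn = True  # >=3 mutually close rim beads
            if torn:
                if deficient_since is None:
                    deficient_since = steps_done
                elif steps_done - deficient_since >= RUPTURE_WINDOW_STEPS:
                    traj.ruptured = True
                    traj.rupture_step = steps_done
                    break
            else:
                deficient_since = None

    traj.radial_force_sums = radial_acc.copy()
    return traj


def measure_pressure_difference(state: MembraneState, params: SimParams,
                                potential: MembranePotentialParams | None = None
                                ) -> float:
    """Short equilibration run returning the osmotic dP estimate."""
    traj = run_dynamics(state, params, potential)
    return traj.pressure_difference()
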