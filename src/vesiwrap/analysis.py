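"""Wrapping observables, state taxonomy, and transition kinetics.

The engulfment of a dumbbell by a quasi-spherical vesicle is tracked by
two geometric observables measured against the *undistorted* vesicle
sphere (centre, radius R):

- ``theta``: angle between the dumbbell long axis and the radial
  direction at the dumbbell centre of mass, folded to [0, 90] degrees
  (the dumbbell is fore-aft symmetric);
- ``d``: insertion depth ``R - |com - centre|``, positive toward the
  vesicle interior.

Frames are only retained while the dumbbell centre of mass sits inside
the equatorial band ``-0.8 R < z < 0.8 R`` (tracking is unreliable near
the poles).  Per-lobe wrapped fractions ``(f1, f2)`` quantify how much of
each lobe's reachable surface is in adhesive contact with membrane beads;
lobes are relabelled per frame so that ``f1 >= f2``.

Frames are classified into a nine-state taxonomy:

- A1/A2/A3: attached, essentially unwrapped; perpendicular, oblique, or
  parallel with both lobes touching;
- B: a single lobe partially wrapped, second lobe free;
- C: both lobes touch, shallow wrapping;
- D: one lobe fully wrapped up to the waist, second lobe never bound
  (terminal at high tension);
- E1: asymmetric two-lobe wrapping (first lobe full, second partial);
- E2: near-symmetric shallow two-lobe wrapping (unstable, resolves
  toward E1/F);
- F: both lobes fully wrapped (terminal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "WrapState",
    "StateThresholds",
    "ObservableSeries",
    "compute_theta",
    "compute_depth",
    "filter_equatorial_band",
    "lobe_mesh",
    "wrapped_fraction",
    "classify_wrap_state",
    "classify_series",
    "transition_times",
    "transition_summary",
    "bin_time_average",
]


class WrapState(str, enum.Enum):
    """Wrapping-configuration taxonomy; NONE marks an unattached dumbbell."""

    NONE = "none"
    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B = "B"
    C = "C"
    D = "D"
    E1 = "E1"
    E2 = "E2"
    F = "F"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class StateThresholds:
    """Wrapped-fraction and angle thresholds of the state decision table.

    The taxonomy itself is pictorial; these cut points are the package's
    operational choices and are deliberately far apart compared with the
    wrapped-fraction mesh resolution (~0.02).
    """

    f_attach: float = 0.05   # below: essentially unwrapped
    f_shallow: float = 0.45  # below: shallow single/double-lobe wrapping
    f_full: float = 0.90     # above: a lobe counts as fully wrapped
    f_symmetric: float = 0.20  # both above: near-symmetric two-lobe state
    theta_perp_deg: float = 30.0  # below: perpendicular attachment


def compute_theta(axis: np.ndarray, outward_normal: np.ndarray) -> float:
    """Tilt angle (degrees in [0, 90]) between dumbbell axis and normal.

    Folded via ``|axis . normal|`` because the dumbbell has head-tail
    symmetry.  Raises on zero-length input.
    """
    axis = np.asarray(axis, dtype=float)
    normal = np.asarray(outward_normal, dtype=float)
    na, nn = np.linalg.norm(axis), np.linalg.norm(normal)
    if na == 0.0 or nn == 0.0:
        raise ValueError("axis and normal must be nonzero vectors")
    cosang = abs(float(axis @ normal)) / (na * nn)
    return float(np.degrees(np.arccos(min(cosang, 1.0))))


def compute_depth(com: np.ndarray, vesicle_center: np.ndarray, R: float) -> float:
    """Insertion depth d = R - |com - centre|; positive inside the sphere."""
    if R <= 0:
        raise ValueError("vesicle radius must be positive")
    com = np.asarray(com, dtype=float)
    c = np.asarray(vesicle_center, dtype=float)
    return float(R - np.linalg.norm(com - c))


def filter_equatorial_band(frames: pd.DataFrame, R: float | None = None,
                           band: float = 0.8) -> pd.DataFrame:
    """Keep frames whose centre-of-mass height satisfies -band*R < z < band*R.

    ``frames`` must carry a ``z`` column; ``R`` defaults to a per-frame
    ``R`` column if present.
    """
    z = frames["z"].to_numpy(dtype=float)
    if R is None:
        R = frames["R"].to_numpy(dtype=float)
    keep = (z > -band * R) & (z < band * R)
    return frames.loc[keep]


def lobe_mesh(n_points: int = 500, seed: int = 0) -> np.ndarray:
    """Quasi-uniform unit-sphere mesh (Fibonacci spiral), shape (n, 3)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def wrapped_fraction(bead_positions: np.ndarray, center: np.ndarray,
                     axis: np.ndarray, lobe_radius: float, cutoff: float,
                     mesh_points: int = 500) -> tuple[float, float]:
    """Per-lobe wrapped fractions (f1, f2), unsorted (lobe 1 = +axis lobe).

    Each lobe surface is sampled on a fixed quasi-uniform mesh; a mesh
    point counts as wrapped when at least one membrane bead lies within
    ``cutoff`` of it.  Mesh points occluded by the partner lobe (closer
    than ``cutoff`` to its surface) are excluded from the reachable area.
    Returns (0, 0) for an empty bead set.
    """
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = float(lobe_radius)
    mesh = lobe_mesh(mesh_points) * a
    c1 = center + a * axis
    c2 = center - a * axis
    beads = np.asarray(bead_positions, dtype=float).reshape(-1, 3)

    fractions = []
    for own, other in ((c1, c2), (c2, c1)):
        pts = mesh + own
        reachable = np.linalg.norm(pts - other, axis=1) - a >= cutoff
        n_reach = int(reachable.sum())
        if n_reach == 0:
            fractions.append(0.0)
            continue
        if beads.size == 0:
            fractions.append(0.0)
            continue
        tree = cKDTree(beads)
        dist, _ = tree.query(pts[reachable], k=1)
        fractions.append(float(np.mean(dist <= cutoff)))
    return fractions[0], fractions[1]


def classify_wrap_state(f1: float, f2: float, theta_deg: float | None = None,
                        second_lobe_contact: bool = False,
                        attached: bool = True,
                        thresholds: StateThresholds = StateThresholds()
                        ) -> WrapState:
    """Classify a frame into the wrapping-state taxonomy.

    Requires the lobe-relabelled convention ``f1 >= f2``.  ``theta_deg``
    is only needed to split the attachment states A1/A2; ``None`` there
    defaults to the oblique A2.
    """
    th = thresholds
    if not (0.0 <= f2 <= f1 <= 1.0):
        raise ValueError("need 0 <= f2 <= f1 <= 1 (relabel lobes so f1 >= f2)")
    if not attached:
        return WrapState.NONE
    if f1 < th.f_attach:
        if second_lobe_contact:
            return WrapState.A3
        if theta_deg is not None and theta_deg < th.theta_perp_deg:
            return WrapState.A1
        return WrapState.A2
    both_bound = second_lobe_contact or f2 >= th.f_attach
    if f1 < th.f_shallow:
        if both_bound:
            if f1 >= th.f_symmetric and f2 >= th.f_symmetric:
                return WrapState.E2
            return WrapState.C
        return WrapState.B
    if f1 < th.f_full:
        # deep single-lobe wrapping: second contact upgrades to asymmetric
        # two-lobe wrapping, otherwise still the single-lobe branch
        if both_bound:
            return WrapState.E1
        return WrapState.B
    if f2 >= th.f_full:
        return WrapState.F
    if f2 >= th.f_attach or second_lobe_contact:
        return WrapState.E1
    return WrapState.D


def classify_series(observables: "ObservableSeries",
                    thresholds: StateThresholds = StateThresholds()
                    ) -> np.ndarray:
    """Vector of WrapState labels for every frame of an observable series."""
    states = np.empty(len(observables.time), dtype=object)
    for i in range(len(observables.time)):
        states[i] = classify_wrap_state(
            observables.f1[i], observables.f2[i],
            theta_deg=observables.theta[i],
            second_lobe_contact=bool(observables.second_contact[i]),
            attached=bool(observables.attached[i]),
            thresholds=thresholds,
        )
    return states


@dataclass
class ObservableSeries:
    """Per-frame wrapping observables of one trajectory.

    ``f1 >= f2`` is enforced at construction (lobe-relabelling
    convention).  ``state`` may be filled by :func:`classify_series`.
    """

    time: np.ndarray
    theta: np.ndarray  # degrees, [0, 90]
    d: np.ndarray      # insertion depth (length units of the trajectory)
    z: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    second_contact: np.ndarray = None
    attached: np.ndarray = None
    state: np.ndarray = None

    def __post_init__(self):
        n = len(np.atleast_1d(self.time))
        for name in ("time", "theta", "d", "z", "f1", "f2"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if self.second_contact is None:
            self.second_contact = self.f2 > 0.0
        else:
            self.second_contact = np.atleast_1d(np.asarray(self.second_contact, dtype=bool))
        if self.attached is None:
            self.attached = np.ones(n, dtype=bool)
        else:
            self.attached = np.atleast_1d(np.asarray(self.attached, dtype=bool))
        # relabel lobes so lobe 1 is the more-wrapped one
        swap = self.f2 > self.f1
        if np.any(swap):
            fa, fb = self.f1.copy(), self.f2.copy()
            self.f1 = np.where(swap, fb, fa)
            self.f2 = np.where(swap, fa, fb)
        if self.state is None:
            self.state = classify_series(self)
        else:
            self.state = np.asarray(
                [WrapState(s) if not isinstance(s, WrapState) else s
                 for s in np.atleast_1d(self.state)], dtype=object)

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "theta_deg": self.theta, "d": self.d,
            "z": self.z, "f1": self.f1, "f2": self.f2,
            "state": [WrapState(s).value for s in self.state],
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservableSeries":
        return cls(time=df["time"].to_numpy(), theta=df["theta_deg"].to_numpy(),
                   d=df["d"].to_numpy(), z=df["z"].to_numpy(),
                   f1=df["f1"].to_numpy(), f2=df["f2"].to_numpy(),
                   state=np.asarray([WrapState(s) for s in df["state"]],
                                    dtype=object))


def _debounced_segments(states, times, debounce_frames: int):
    """Collapse a frame-wise state sequence into debounced (state, t_enter) runs."""
    states = [WrapState(s) for s in states]
    # run-length encode
    runs = []  # (state, start_index, length)
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start, i - start))
            start = i
    # drop flickers shorter than the debounce window (keep first & last runs)
    kept = [r for k, r in enumerate(runs)
            if r[2] >= debounce_frames or k == 0 or k == len(runs) - 1]
    # merge adjacent identical states after the drop
    merged = []
    for r in kept:
        if merged and merged[-1][0] == r[0]:
            continue
        merged.append(r)
    return [(r[0], times[r[1]]) for r in merged]


def transition_times(states, times, debounce_frames: int = 5) -> pd.DataFrame:
    """Durations between consecutively visited states.

    For each ordered pair of debounced consecutive states the elapsed time
    is measured from entering the first state to entering the second.
    Flickers shorter than ``debounce_frames`` output frames are ignored.
    Returns a DataFrame with columns (from, to, duration); empty input
    yields an empty table.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return pd.DataFrame(columns=["from", "to", "duration"])
    if np.any(np.diff(times) < 0):
        raise ValueError("time stamps must be monotone")
    segs = _debounced_segments(states, times, debounce_frames)
    rows = [
        {"from": segs[k][0].value, "to": segs[k + 1][0].value,
         "duration": segs[k + 1][1] - segs[k][1]}
        for k in range(len(segs) - 1)
    ]
    return pd.DataFrame(rows, columns=["from", "to", "duration"])


def transition_summary(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Ensemble mean +/- sd of transition durations over several runs."""
    if not tables:
        return pd.DataFrame(columns=["from", "to", "mean", "sd", "n"])
    allt = pd.concat(tables, ignore_index=True)
    g = allt.groupby(["from", "to"])["duration"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def bin_time_average(times, values, window: float) -> pd.DataFrame:
    """Non-overlapping window means of one or more observable columns.

    ``values`` may be a 1-D array or a dict of named 1-D arrays.  Returns
    per-bin means, bin centres, and per-bin frame counts.
    """
    if window <= 0:
        raise ValueError("averaging window must be positive")
    times = np.asarray(times, dtype=float)
    if isinstance(values, dict):
        cols = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    else:
        cols = {"value": np.asarray(values, dtype=float)}
    t0 = times.min() if times.size else 0.0
    idx = np.floor((times - t0) / window).astype(int)
    df = pd.DataFrame({"bin": idx, **cols})
    g = df.groupby("bin")
    out = g.mean()
    out["count"] = g.size()
    out["time"] = t0 + (out.index.to_numpy() + 0.5) * window
    return out.reset_index(drop=True)[["time", *cols.keys(), "count"]]
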