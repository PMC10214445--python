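"""Osmotic tension control by volume-excluded solute particles.

Solutes on the two sides of the membrane interact with everything by
volume exclusion only.  A concentration imbalance produces an ideal-gas
pressure difference ``dP = kBT (c_in - c_out)`` which the closed vesicle
balances by the Laplace law ``dP = 2 sigma / R``, so a target tension maps
to integer solute counts for the enclosed and exterior volumes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .kernels import SIGMA_SM, SIGMA_SS
from .vesicle import MembraneState

__all__ = ["set_tension_by_solutes", "place_solutes", "accessible_volumes"]


def accessible_volumes(state: MembraneState) -> tuple[float, float]:
    """Volumes available to interior / exterior solute centres.

    The effective wall sits one solute-membrane exclusion length inside
    (outside) the bead-centre sphere.
    """
    R = state.mean_radius()
    if state.box is None:
        raise ValueError("state needs a periodic box")
    v_in = 4.0 / 3.0 * np.pi * max(R - SIGMA_SM, 0.0) ** 3
    v_out = state.box**3 - 4.0 / 3.0 * np.pi * (R + SIGMA_SM) ** 3
    return float(v_in), float(v_out)

# volume fraction above which the volume-exclusion gas stops being dilute
PACKING_LIMIT = 0.25


def set_tension_by_solutes(target_sigma: float, R: float, kBT: float,
                           v_in: float, v_out: float,
                           c_out_base: float = 0.0,
                           solute_diameter: float = 0.5
                           ) -> tuple[int, int]:
    """Solute counts (n_in, n_out) realizing a target membrane tension.

    ``v_in``/``v_out`` are the volumes available to interior and exterior
    solutes; ``c_out_base`` sets a baseline exterior concentration on top
    of which the imbalance is applied.  Raises when the required interior
    concentration exceeds the packing limit of the excluded-volume gas.
    """
    if target_sigma < 0:
        raise ValueError("target tension must be non-negative")
    if kBT <= 0:
        raise ValueError("solute tension control needs kBT > 0")
    dp = 2.0 * target_sigma / R
    c_in = c_out_base + dp / kBT
    vol_solute = np.pi / 6.0 * solute_diameter**3
    if c_in * vol_solute > PACKING_LIMIT:
        raise ValueError(
            f"target tension {target_sigma} needs interior concentration "
            f"{c_in:.3f}/sigma_b^3, beyond the packing limit")
    n_in = int(round(c_in * v_in))
    n_out = int(round(c_out_base * v_out))
    return n_in, n_out


def place_solutes(state: MembraneState, n_in: int, n_out: int, seed: int = 0,
                  margin: float = 1.0) -> MembraneState:
    """Rejection-sample solute positions inside/outside the vesicle.

    Interior solutes fill the sphere ``r < R - margin`` about the vesicle
    centre, exterior ones the box minus ``r < R + margin``; placements
    overlapping membrane beads or earlier solutes are rejected.
    """
    rng = np.random.default_rng(seed)
    c = state.center()
    R = state.mean_radius()
    box = state.box
    if box is None:
        raise ValueError("state needs a periodic box to place solutes")
    bead_tree = cKDTree(state.bead_positions)
    placed: list[np.ndarray] = []

    def try_place(n, inside):
        pts = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 200 * max(n, 1) + 1000:
                raise RuntimeError("solute placement failed: volume too crowded")
            if inside:
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                r = (R - margin) * rng.random() ** (1.0 / 3.0)
                p = c + r * u
            else:
                p = rng.random(3) * box
                if np.linalg.norm(p - c) < R + margin:
                    continue
            if bead_tree.query(p)[0] < 0.95 * SIGMA_SM:
                continue
            if placed or pts:
                allp = np.asarray(placed + pts).reshape(-1, 3)
                if cKDTree(allp).query(p)[0] < 0.95 * SIGMA_SS:
                    continue
            pts.append(p)
        return pts

    sol_in = try_place(n_in, inside=True)
    placed.extend(sol_in)
    sol_out = try_place(n_out, inside=False)
    return MembraneState(
        bead_positions=state.bead_positions.copy(),
        bead_normals=state.bead_normals.copy(),
        solute_in_positions=np.asarray(sol_in).reshape(-1, 3),
        solute_out_positions=np.asarray(sol_out).reshape(-1, 3),
        box=box)
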