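"""Parameter containers for the coarse-grained membrane simulation."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MembranePotentialParams:
    """One-particle-thick membrane pair potential parameters.

    ``epsilon`` sets the bond energy scale; ``mu`` weights the energy
    penalty for misaligned orientation vectors (and thereby the bending
    rigidity); ``zeta`` controls how fast the attractive tail decays;
    ``theta0`` is a spontaneous-curvature angle (0 for a flat-preferring
    membrane); ``r_min``/``r_cut`` bound the attractive well.  Lengths in
    bead diameters, energies in epsilon.
    """

    epsilon: float = 1.0
    mu: float = 3.0
    zeta: float = 4.0
    theta0: float = 0.0
    r_min: float = 2.0 ** (1.0 / 6.0)
    r_cut: float = 2.6

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (self.r_cut > self.r_min > 0):
            raise ValueError("need r_cut > r_min > 0")
        if self.zeta < 1 or self.mu < 1:
            raise ValueError("need zeta >= 1 and mu >= 1")


@dataclass(frozen=True)
class SimParams:
    """Langevin run settings (reduced units).

    ``gamma_t``/``gamma_r`` are translational/rotational friction rates
    (1/tau0); ``epsilon_ad`` is the adhesion well depth per membrane bead
    and ``r_cut_ad`` the adhesion range measured from the lobe surface.
    ``tau0`` is the MD unit of time used when reporting times.
    """

    dt: float = 0.01
    n_steps: int = 100_000
    kBT: float = 0.23
    gamma_t: float = 1.0
    gamma_r: float = 1.0
    epsilon_ad: float = 5.0
    r_cut_ad: float = 1.5
    seed: int = 0
    tau0: float = 1.0
    snapshot_stride: int = 1000

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kBT > 0 and (self.gamma_t <= 0 or self.gamma_r <= 0):
            raise ValueError("thermostat needs positive friction")
        if self.kBT < 0:
            raise ValueError("kBT must be non-negative")
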