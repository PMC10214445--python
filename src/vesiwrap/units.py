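"""Unit conventions and physical constants.

Two unit systems coexist in the package and are never mixed implicitly:

- Simulation stages (``vesiwrap.membrane``) use reduced units: the membrane
  bead diameter ``sigma_b`` for length, the bond energy ``epsilon`` for
  energy, and ``tau0 = sigma_b * sqrt(m / epsilon)`` (m = 1) for time.
- Theory and spectroscopy stages use SI: metres, N/m for tension, joules
  for bending rigidity, Pa*s for viscosity.

Helpers below convert between kBT multiples and joules at a reference
temperature of 298 K.
"""

KB = 1.380649e-23  # Boltzmann constant, J/K
T_REF = 298.0  # reference lab temperature, K
KBT_REF = KB * T_REF  # thermal energy at 298 K, J


def kbt_to_joules(n_kbt: float, temperature: float = T_REF) -> float:
    """Convert an energy given in units of kBT to joules."""
    return n_kbt * KB * temperature


def joules_to_kbt(energy_j: float, temperature: float = T_REF) -> float:
    """Convert an energy in joules to units of kBT."""
    return energy_j / (KB * temperature)
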