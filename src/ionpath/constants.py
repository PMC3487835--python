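"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, distances angstrom, time ns (KMC) or ps (Langevin),
temperatures kelvin, voltages millivolt.
"""

#: Boltzmann constant, kcal/(mol K)  (R / 4184 J kcal^-1)
BOLTZMANN_KCAL = 1.987204259e-3

#: Elementary charge, coulomb
ELEMENTARY_CHARGE = 1.602176634e-19

#: Conversion factor: 1 eV of electrostatic energy per elementary charge,
#: expressed per mole (e * N_A / 4184).
KCAL_PER_MOL_PER_EV = 23.060548

#: Default simulation temperature (K); physiological for cardiomyocytes.
DEFAULT_TEMPERATURE = 310.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B * T in kcal/mol."""
    return BOLTZMANN_KCAL * temperature


def voltage_to_kcal(voltage_mv: float) -> float:
    """Electrostatic energy q*V of a monovalent cation, kcal/mol, for V in mV."""
    return voltage_mv * 1e-3 * KCAL_PER_MOL_PER_EV
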