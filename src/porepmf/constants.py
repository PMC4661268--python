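"""Physical constants and unit conversions.

All energies are in kcal/mol, lengths in angstrom (A), temperatures in kelvin.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872

#: Molar mass of water, g/mol.
M_WATER = 18.0153

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Conversion factor from e*A to Debye.
EA_TO_DEBYE = 4.80321


def kT(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol (0.5961 kcal/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
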