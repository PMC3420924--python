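"""Physical constants and unit conventions.

Energies are kcal/mol, lengths nm, angles rad, times ps throughout the
sampling layer; the thermodynamic layer reports areas in µm² (1 nm² =
1e-6 µm²) and the kinetic layer uses seconds.
"""

#: Boltzmann constant / gas constant, kcal mol⁻¹ K⁻¹ (numerically equal for
#: per-mole energies).
KB_KCAL = 1.987204259e-3

#: Default absolute temperature (K). kT = 0.5962 kcal/mol at 300 K.
DEFAULT_TEMPERATURE = 300.0

#: nm² → µm² conversion for surface association constants.
NM2_TO_UM2 = 1e-6


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB_KCAL * temperature
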