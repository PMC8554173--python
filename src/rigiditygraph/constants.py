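"""Physical constants and package-wide defaults.

Energies are kcal/mol, lengths Å, stiffnesses kcal·mol⁻¹·Å⁻², temperatures K.
"""

#: Boltzmann constant in kcal/mol/K (rounded convention; k_B·T = 0.5961 at 300 K).
BOLTZMANN_KCAL = 1.987e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0

#: Default interaction cutoff l_c (Å) used to seed the spring network.
DEFAULT_CUTOFF = 7.8


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return BOLTZMANN_KCAL * temperature
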