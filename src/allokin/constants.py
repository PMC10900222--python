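"""Physical constants used throughout the package.

All energies are in kcal/mol, angles in degrees, times in seconds and
diffusion coefficients in deg^2/s unless stated otherwise.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: Default simulation/analysis temperature in kelvin.
DEFAULT_TEMPERATURE = 300.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature


def beta(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
    return 1.0 / kbt(temperature)
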