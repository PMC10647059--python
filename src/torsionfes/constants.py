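"""Physical constants used throughout the package."""

#: Molar gas constant in kcal/(mol K).  Multiplied by the absolute
#: temperature it gives the thermal energy RT that scales every
#: Boltzmann factor in this package; RT(300 K) = 0.59616 kcal/mol.
GAS_CONSTANT_KCAL = 1.987204259e-3


def thermal_energy(temperature: float) -> float:
    """RT in kcal/mol at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature
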