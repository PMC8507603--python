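"""Physical constants and unit conventions.

Units used throughout the package: length nm, time ps, energy kJ/mol,
temperature K, charge in elementary charges (e).
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083145


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
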