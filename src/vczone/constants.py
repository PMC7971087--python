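"""Physical constants and unit conversions.

The package works in Å, kcal/mol, K, fs and amu throughout.  Internal
kinetic quantities (velocities, kinetic energy) live in amu·Å²/fs²; the
single conversion factor below moves potential-energy gradients into that
system.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/fs²  (4184 J/mol / (1e7 J/mol per amu·Å²/fs²))
KCAL_PER_MOL = 4.184e-4


def kt_internal(temperature: float) -> float:
    """k_B·T in internal units (amu·Å²/fs²)."""
    return KB * temperature * KCAL_PER_MOL
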