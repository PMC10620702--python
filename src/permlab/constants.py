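"""Physical constants used across the package.

All energies are in kcal/mol, lengths in Angstrom, times in ns, and
single-channel permeabilities in cm^3/s, the units conventional for
aquaporin permeation analysis.
"""

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214e23

#: Molar volume of liquid water, cm^3/mol (at physiological temperature).
WATER_MOLAR_VOLUME_CM3 = 18.02

#: Volume of a single water molecule, cm^3.
SINGLE_WATER_VOLUME_CM3 = WATER_MOLAR_VOLUME_CM3 / AVOGADRO

#: Gas constant, kcal/(mol K).  Also used as the Boltzmann constant in
#: molar units for free-energy profiles.
R_KCAL = 1.98588e-3

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 310.15

#: Number density of bulk water, 1/A^3 (0.997 g/cm^3 at ~310 K).
BULK_WATER_DENSITY = 0.0334

#: ns -> s
NS_TO_S = 1e-9


def kT(temperature: float) -> float:
    """Thermal energy in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
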