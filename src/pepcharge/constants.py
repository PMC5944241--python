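"""Physical constants (CODATA via scipy) and unit conversion factors.

All public API quantities use the units the instruments and the literature
report in: masses in ng cm^-2, concentrations in mol L^-1, charge densities
in C m^-2, z coordinates in Angstrom, potentials in V.
"""

from scipy.constants import (
    Avogadro as N_A,
    Boltzmann as K_B,
    R as GAS_CONSTANT,
    e as ELEMENTARY_CHARGE,
    epsilon_0 as EPSILON_0,
)

__all__ = [
    "N_A",
    "K_B",
    "GAS_CONSTANT",
    "ELEMENTARY_CHARGE",
    "EPSILON_0",
    "NG_CM2_TO_KG_M2",
    "ANGSTROM",
    "E_PER_A3_TO_C_PER_M3",
]

# 1 ng cm^-2 = 1e-9 g / 1e-4 m^2 = 1e-8 kg m^-2
NG_CM2_TO_KG_M2 = 1e-8
ANGSTROM = 1e-10  # m
# elementary charges per cubic Angstrom -> C m^-3
E_PER_A3_TO_C_PER_M3 = ELEMENTARY_CHARGE / ANGSTROM**3
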