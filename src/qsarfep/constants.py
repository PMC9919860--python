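"""Physical constants used throughout the package (kcal/mol, Angstrom, Kelvin)."""

#: Boltzmann constant in kcal/(mol K)
KB_KCAL = 0.0019872041

#: Default simulation/assay temperature (K)
DEFAULT_TEMPERATURE = 300.0

#: Coulomb conversion factor: (e^2/Angstrom) -> kcal/mol
COULOMB_KCAL = 332.0636

#: ln(10), used in the pIC50 <-> free energy conversion
import math

LN10 = math.log(10.0)
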