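"""Unit conventions and physical constants.

Internal units throughout the package: length in Angstrom, energy in eV,
charge in elementary charges e, mass in amu, time in fs. Electronegativities
are eV/e, hardnesses eV/e^2.
"""

import math

#: Coulomb constant e^2/(4 pi eps0) in eV * Angstrom / e^2
K_E = 14.399645

#: Boltzmann constant in eV / K
K_B = 8.617333262e-5

#: (eV/Angstrom) / amu -> Angstrom / fs^2
FORCE_TO_ACC = 9.648533212e-3

SQRT_PI = math.sqrt(math.pi)
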