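"""Physical constants and unit conventions.

Quantities throughout the package carry the units customary in monolayer
work: potentials in mV, dipole moments in mD (millidebye), areas in Å² per
molecule, surface pressure in mN/m, concentrations in mol/L, temperature in
K.  Conversion to SI happens only inside the Grahame solver.

The Helmholtz parallel-plate relation ΔV = 12π·μ⊥/A is dimensionally
consistent in exactly this mixed unit system (mV, mD, Å²); the 12π factor
absorbs the Debye and ångström conversions.
"""

import math
from typing import Final

#: Helmholtz capacitor factor, mV·Å²/mD.  Exactly 12π.
K_HELMHOLTZ: Final[float] = 12.0 * math.pi

#: Faraday constant, C/mol.
F: Final[float] = 96485.33

#: Molar gas constant, J/(mol·K).
R: Final[float] = 8.314463

#: Vacuum permittivity, F/m.
EPS0: Final[float] = 8.8541878e-12

#: Elementary charge, C.
E_CHARGE: Final[float] = 1.602177e-19

#: Avogadro constant, 1/mol.
N_A: Final[float] = 6.022141e23
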