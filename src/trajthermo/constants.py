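"""Physical constants in the package's internal unit system.

Internal units: length Å, mass amu, time ps, energy kcal/mol, charge e,
temperature K.  The mechanical energy unit amu·Å²/ps² is used wherever a
dimensionless ratio such as ħω/(k_B·T) must be formed; 1 kcal/mol equals
exactly 418.4 amu·Å²/ps² (4184 J/mol over Avogadro's number, expressed in
amu, Å and ps).

Values derive from CODATA 2018.
"""

import math

#: Avogadro constant, 1/mol
N_A = 6.02214076e23

#: Boltzmann constant, J/K
K_B_SI = 1.380649e-23

#: reduced Planck constant, J*s
HBAR_SI = 1.054571817e-34

#: atomic mass unit, kg
AMU_SI = 1.66053906660e-27

#: 1 kcal/mol expressed in amu*A^2/ps^2 (numerically 418.4):
#: 4184 J/mol / N_A, divided by amu*(1e-10 m)^2/(1e-12 s)^2
KCAL_PER_MOL_TO_AKMA = 4184.0 / N_A / (AMU_SI * 1e-20 / 1e-24)

#: Boltzmann constant, kcal/(mol*K)
K_B_KCAL = K_B_SI * N_A / 4184.0

#: Boltzmann constant, amu*A^2/(ps^2*K)
K_B_AKMA = K_B_KCAL * KCAL_PER_MOL_TO_AKMA

#: reduced Planck constant, amu*A^2/ps
HBAR_AKMA = HBAR_SI / (AMU_SI * 1e-20 / 1e-12)

#: Coulomb constant, kcal*A/(mol*e^2) -- the conventional MM value
COULOMB_K = 332.0636

#: 4*pi, used by the finite-difference Poisson solver source term
FOUR_PI = 4.0 * math.pi

#: default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0
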