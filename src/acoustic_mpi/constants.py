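"""Physical and material constants.

All magnetic "fields" throughout the package are carried as mu0*H in tesla
(the T mu0^-1 convention common in magnetic particle imaging); gradients are
in T/m.  Everything else is SI, except iron concentrations, which follow the
clinical mol(Fe)/l convention.
"""

import math

#: Boltzmann constant [J/K] (exact, 2019 SI).
KB = 1.380649e-23

#: Vacuum permeability [T*m/A].
MU0 = 4e-7 * math.pi

#: Bulk magnetite (Fe3O4) saturation magnetization [A/m]; mu0*Ms = 0.598 T.
MAGNETITE_SATURATION_A_PER_M = 476e3

#: Bulk magnetite density [kg/m^3].
MAGNETITE_DENSITY_KG_PER_M3 = 5200.0

#: Magnetite molar mass [kg/mol].
MAGNETITE_MOLAR_MASS_KG_PER_MOL = 0.23153

#: Iron atoms per Fe3O4 formula unit.
IRON_ATOMS_PER_FORMULA_UNIT = 3

#: Default absolute temperature [K]: body temperature, water at 37 degC.
DEFAULT_TEMPERATURE_K = 310.0

#: Density of water at 310 K [kg/m^3].
WATER_DENSITY_310K_KG_PER_M3 = 993.0

#: Speed of sound in water at 310 K [m/s].
WATER_SOUND_SPEED_310K_M_PER_S = 1523.0
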