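"""Physical constants and conventions shared across the package.

All free energies are in kJ/mol, temperatures in kelvin, aqueous
activities in mol/L and gas activities in atm partial pressure.
"""

#: Ideal gas constant in kJ K^-1 mol^-1.
R_KJ = 8.314e-3

#: Faraday constant in kJ per volt per mole of electrons.
FARADAY_KJ_PER_V = 96.5

#: Reference temperature (25 degC) used for all tabulated dG0' values.
T_STANDARD = 298.15

#: Reference pH of the biochemical standard state (dG0' convention).
PH_STANDARD = 7.0

#: One standard atmosphere in pascal, used in Henry's-law conversions.
ATM_PA = 101325.0

#: Henry solubility of H2 in water, mol m^-3 Pa^-1.
HENRY_H2 = 7.8e-6

#: Henry solubility of CH4 in water, mol m^-3 Pa^-1.
HENRY_CH4 = 1.4e-5

#: Minimum free-energy yield (kJ/mol) commonly assumed necessary for
#: microbial energy conservation; the biological quantum is -10 +/- 1.
DG_MIN_DEFAULT = -10.0
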