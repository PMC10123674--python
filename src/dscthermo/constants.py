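"""Physical constants used throughout the package.

All energies are in kcal/mol and temperatures in kelvin, the customary
units of protein calorimetry.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987e-3

#: Offset between the Celsius and kelvin scales.
CELSIUS_OFFSET: float = 273.15
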