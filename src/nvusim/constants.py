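"""Physical constants and unit conversions.

Internal unit convention: strict SI.  Concentrations are carried in
mol/m^3, which is numerically identical to mmol/L (mM), so config files
may state concentrations in mM without conversion.
"""

#: Avogadro constant, 1/mol (CODATA 2018 exact value).
AVOGADRO = 6.02214076e23

#: One millimetre of mercury in pascal.
MMHG_TO_PA = 133.322

#: Micrometre in metres, for readable geometry literals.
UM = 1e-6
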