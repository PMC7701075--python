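"""Physical constants and default experimental conditions.

Internal computations use SI units throughout (metres, seconds, kg m^-3,
Pa s).  Svedberg and nanometre appear only at interfaces.
"""

#: Boltzmann constant [J K^-1]
BOLTZMANN = 1.380649e-23

#: Avogadro constant [mol^-1]
AVOGADRO = 6.02214076e23

#: One Svedberg in seconds
SVEDBERG = 1e-13

#: One nanometre in metres
NM = 1e-9

#: Density of water at 20 degC [kg m^-3]; the pH-2 HCl background used for
#: beta-lactoglobulin fibril dispersions is indistinguishable from water at
#: this precision.
WATER_DENSITY_20C = 998.2

#: Dynamic viscosity of water at 20 degC [Pa s]
WATER_VISCOSITY_20C = 1.002e-3

#: Anhydrous density of beta-lactoglobulin, the inverse of its partial
#: specific volume [kg m^-3]
BLG_DENSITY = 1331.6

#: Relative densification of packed beta-sheet fibril structures with
#: respect to native BLG (from structural MD estimates; consumed here as a
#: constant multiplicative factor).
FIBRIL_DENSIFICATION = 1.02

#: Reference absolute temperature for diffusion coefficients [K] (20 degC)
TEMPERATURE_20C_K = 293.15

#: Effective hydrodynamic height increment added to AFM (dried-state)
#: fibril heights to account for two bound water layers [nm]
WATER_LAYER_OFFSET_NM = 0.7
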