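"""Physical constants and model coefficients used throughout the package.

Every numeric coefficient of the partial-solvation-parameter (PSP) framework
lives here so that the working equations elsewhere read symbolically.
"""

#: Universal gas constant, J/(mol K).
R = 8.314

#: Reference temperature for bulk-phase properties, K.
T_REF = 298.15

#: Default inverse-gas-chromatography column temperature (30 deg C), K.
T_IGC = 303.15

#: Standard temperature entering the net-retention-volume definition, K.
T_STANDARD = 273.15

#: Segment volume of the lattice model: one segment per 0.213 units of
#: McGowan volume (Vx expressed in (cm^3/mol)/100), so r = Vx / 0.213.
SEGMENT_MCGOWAN_VOLUME = 0.213

#: Dispersion offset multiplying Vx in the cavity/dispersion term 3.1*Vx + E.
DISPERSION_VX_COEFF = 3.1

#: Hydrogen-bond formation energy coefficient, J/mol:
#: E_HB = -EHB_COEFF * sqrt(A*B).
EHB_COEFF = 30450.0

#: Hydrogen-bond formation entropy coefficient, J/(K mol):
#: S_HB = -SHB_COEFF * sqrt(A*B).
SHB_COEFF = 35.1

#: Scale factor mapping descriptor/volume ratios to MPa^0.5:
#: sigma = PSP_SCALE * sqrt(descriptor / Vm) with Vm in cm^3/mol.
PSP_SCALE = 100.0

#: PSP_SCALE squared; appears in the activity working equations
#: (10000 * Vx * phi2^2 / (R*T) * (...)^2).
PSP_SCALE_SQ = 10000.0
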