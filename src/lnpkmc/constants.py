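"""Physical constants (SI, CODATA 2018) and unit-conversion factors.

The package convention is: lengths in nm, time in s, energies in kBT,
salt concentration in mol/L, temperature in K, viscosity in Pa*s.
All conversions between the molecular (nm) and SI scales are localized
here and in :mod:`lnpkmc.physchem`.
"""

KB = 1.380649e-23  # Boltzmann constant, J/K
NA = 6.02214076e23  # Avogadro number, 1/mol
E0 = 1.602176634e-19  # elementary charge, C
EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

M_PER_NM = 1e-9
NM3_PER_M3 = 1e27
# mol/L -> particles per nm^3
PER_NM3_PER_MOLAR = NA / 1e24
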