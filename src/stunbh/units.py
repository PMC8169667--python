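"""Internal unit system and physical constants.

All quantities in the package use a single unit system:

* length      — Angstrom (A)
* time        — femtosecond (fs)
* energy      — kJ/mol
* mass        — atomic mass unit (amu)
* charge      — elementary charge (e)
* temperature — Kelvin (K)

Velocities are A/fs; forces kJ mol^-1 A^-1.  One amu A^2 fs^-2 equals
exactly 1e4 kJ/mol (because amu * Avogadro = 1 g/mol), which is the only
conversion factor dynamics needs.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083144621

#: Coulomb prefactor k_e * e^2 * N_A, in kJ mol^-1 A e^-2 (vacuum).
COULOMB_PREFACTOR = 1389.35

#: Conversion amu * (A/fs)^2 -> kJ/mol.  Exact: 1 amu = 1/N_A g.
AMU_A2_FS2_TO_KJ_MOL = 1.0e4

#: Inverse conversion, kJ/mol -> amu * (A/fs)^2 (used by integrators).
KJ_MOL_TO_AMU_A2_FS2 = 1.0e-4
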