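"""Physical constants and unit conversions (GROMACS convention: nm, ps, kJ/mol)."""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145

#: 1 kJ mol^-1 nm^-2 expressed in mN/m (= mJ/m^2)
KJ_PER_MOL_NM2_TO_MN_PER_M = 1.6606

#: 1 bar expressed in kJ mol^-1 nm^-3
BAR_TO_KJ_PER_MOL_NM3 = 0.06022

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 310.0

LIPID_SPECIES = ("DPPC", "DLiPC", "POPC", "CHOL")

#: Residue-name aliases -> canonical species labels (MARTINI naming; DIPC is
#: the common distribution name for dilinoleoyl-PC)
DEFAULT_SPECIES_ALIASES = {
    "DPPC": "DPPC",
    "DIPC": "DLiPC",
    "DLIPC": "DLiPC",
    "DLIP": "DLiPC",
    "POPC": "POPC",
    "CHOL": "CHOL",
}
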