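"""Physical constants and monoisotopic atomic masses.

Atomic masses are the standard monoisotopic values (most abundant isotope),
on the carbon-12 scale; only the elements needed for quinone and adduct
arithmetic are included.
"""

# monoisotopic atomic masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "O": 15.99491462,
    "N": 14.00307401,
    "Na": 22.98976928,
}

ELECTRON_MASS = 0.00054858  # Da
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645 Da

FARADAY = 96485.33212  # C mol^-1
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1

# Ag|AgCl (sat. KCl) vs SHE at 298 K; applied as a fixed offset
AGCL_VS_SHE = 0.199  # V
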