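"""Per-residue property scales used by the descriptor engine.

Every scale is a plain ``{one-letter code: value}`` mapping over the 20
canonical residues, with its literature provenance recorded in
``SCALE_PROVENANCE``.  These tables are configuration: the descriptor
registry reads them, nothing else hard-codes a residue property.
"""

from __future__ import annotations

# Kyte & Doolittle (1982) hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Hopp & Woods (1981) hydrophilicity
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

# Eisenberg et al. (1984) consensus hydrophobicity
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

# Vihinen et al. (1994) normalized flexibility (window-less per-residue values)
VIHINEN_FLEXIBILITY = {
    "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915, "G": 1.031,
    "H": 0.950, "I": 0.927, "K": 1.102, "L": 0.935, "M": 0.952, "N": 1.048,
    "P": 1.049, "Q": 1.037, "R": 1.008, "S": 1.046, "T": 0.997, "V": 0.931,
    "W": 0.904, "Y": 0.929,
}

# Kolaskar & Tongaonkar (1990) antigenic propensity
KOLASKAR_TONGAONKAR = {
    "A": 1.064, "C": 1.412, "D": 0.866, "E": 0.851, "F": 1.091, "G": 0.874,
    "H": 1.105, "I": 1.152, "K": 0.930, "L": 1.250, "M": 0.826, "N": 0.776,
    "P": 1.064, "Q": 1.015, "R": 0.873, "S": 1.012, "T": 0.909, "V": 1.383,
    "W": 0.893, "Y": 1.161,
}

# Fraga (1982) recognition factors
FRAGA_RECOGNITION = {
    "A": 78.0, "C": 89.0, "D": 81.0, "E": 78.0, "F": 81.0, "G": 84.0,
    "H": 84.0, "I": 88.0, "K": 87.0, "L": 85.0, "M": 80.0, "N": 94.0,
    "P": 91.0, "Q": 87.0, "R": 95.0, "S": 107.0, "T": 93.0, "V": 89.0,
    "W": 104.0, "Y": 84.0,
}

# Zamyatnin (1972) residue volumes, cubic angstroms
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}

# Tien et al. (2013) theoretical maximum solvent-accessible area, square angstroms
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0, "Q": 225.0,
    "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0, "L": 201.0, "K": 236.0,
    "M": 224.0, "F": 240.0, "P": 159.0, "S": 155.0, "T": 172.0, "W": 285.0,
    "Y": 263.0, "V": 174.0,
}

# Wolfenden et al. (1981) side-chain hydration free energies, kcal/mol
# (proline has no measured analog; 0 by convention)
WOLFENDEN_SOLVATION = {
    "A": 1.94, "R": -19.92, "N": -9.68, "D": -10.95, "C": -1.24, "Q": -9.38,
    "E": -10.20, "G": 2.39, "H": -10.27, "I": 2.15, "L": 2.28, "K": -9.52,
    "M": -1.48, "F": -0.76, "P": 0.0, "S": -5.06, "T": -4.88, "W": -5.88,
    "Y": -6.11, "V": 1.99,
}

# Pickett & Sternberg (1993) side-chain conformational entropy, T*dS kcal/mol at 300 K
SIDECHAIN_ENTROPY = {
    "A": 0.0, "C": 1.14, "D": 1.25, "E": 2.21, "F": 0.58, "G": 0.0,
    "H": 0.99, "I": 0.89, "K": 2.21, "L": 0.78, "M": 1.61, "N": 1.45,
    "P": 0.0, "Q": 2.02, "R": 2.13, "S": 1.71, "T": 1.63, "V": 0.51,
    "W": 0.97, "Y": 0.98,
}

# Side-chain hydrogen-bond donor / acceptor group counts (neutral pH bookkeeping)
HBOND_DONORS = {
    "A": 0, "C": 1, "D": 0, "E": 0, "F": 0, "G": 0, "H": 1, "I": 0, "K": 3,
    "L": 0, "M": 0, "N": 2, "P": 0, "Q": 2, "R": 5, "S": 1, "T": 1, "V": 0,
    "W": 1, "Y": 1,
}
HBOND_ACCEPTORS = {
    "A": 0, "C": 0, "D": 2, "E": 2, "F": 0, "G": 0, "H": 1, "I": 0, "K": 0,
    "L": 0, "M": 1, "N": 2, "P": 0, "Q": 2, "R": 0, "S": 1, "T": 1, "V": 0,
    "W": 0, "Y": 1,
}

# Monoisotopic-free average residue masses, Da (ExPASy)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Side-chain ionization pKa values (EMBOSS-like set) for charge bookkeeping at pH 7.4
SIDECHAIN_PKA = {"D": 3.9, "E": 4.1, "H": 6.5, "C": 8.5, "Y": 10.1, "K": 10.8, "R": 12.5}
NTERM_PKA = 8.6
CTERM_PKA = 3.6

# Residue class memberships (documented choice; the literature names classes only)
AROMATIC = set("FWY")
ALIPHATIC = set("AGILV")
POLAR_NEUTRAL = set("NQSTC")
SULFUR = set("CM")
NEGATIVE = set("DE")
POSITIVE = set("KRH")

# Chou-Fasman-style secondary-structure propensity classes (as used by
# Biopython's secondary_structure_fraction)
HELIX_SET = set("VIYFWL")
TURN_SET = set("NPGS")
SHEET_SET = set("EMAL")

SCALE_PROVENANCE = {
    "KYTE_DOOLITTLE": "Kyte & Doolittle, J Mol Biol 157:105 (1982)",
    "HOPP_WOODS": "Hopp & Woods, PNAS 78:3824 (1981)",
    "EISENBERG": "Eisenberg et al., J Mol Biol 179:125 (1984)",
    "VIHINEN_FLEXIBILITY": "Vihinen et al., Proteins 19:141 (1994)",
    "KOLASKAR_TONGAONKAR": "Kolaskar & Tongaonkar, FEBS Lett 276:172 (1990)",
    "FRAGA_RECOGNITION": "Fraga, Can J Chem 60:2606 (1982)",
    "RESIDUE_VOLUME": "Zamyatnin, Prog Biophys Mol Biol 24:107 (1972)",
    "MAX_ASA": "Tien et al., PLoS ONE 8:e80635 (2013)",
    "WOLFENDEN_SOLVATION": "Wolfenden et al., Biochemistry 20:849 (1981)",
    "SIDECHAIN_ENTROPY": "Pickett & Sternberg, J Mol Biol 231:825 (1993)",
    "RESIDUE_MASS": "ExPASy average residue masses",
}
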