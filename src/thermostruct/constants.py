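"""Shared physical tables: residue codes, vdW radii, reference accessibilities,
atomic masses, pKa sets, and interaction atom tables.

All distances in Å, masses in Da, areas in Å² unless noted.
"""

from __future__ import annotations

# 3-letter -> 1-letter residue codes. MSE (selenomethionine) is treated as MET.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Residue classes used for composition profiles (sequence-level analysis).
CLASS_CHARGED = set("DEHKR")
CLASS_HYDROPHOBIC = set("GAVLIPMFW")
CLASS_POLAR = set("CNQSTY")

# Apolar set for hydrophobic *contact* detection (structure-level; the
# contact convention differs from the composition class above on G and Y).
APOLAR_CONTACT = set("AVLIMFWPY")

# van der Waals radii (Bondi), Å. Unknown elements fall back to DEFAULT_VDW.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "P": 1.80, "SE": 1.90, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

# Standard atomic masses, Da.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "SE": 78.971, "P": 30.974,
}
DEFAULT_MASS = 12.011

# Maximum accessible surface area of residue X in an extended Gly-X-Gly
# tripeptide (theoretical values of Tien et al. 2013), Å². Used to turn
# absolute residue SASA into relative accessibility.
MAX_ASA_GXG = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Bjellqvist pKa set (the ProtParam convention).
# Side-chain pKa values; negative groups lose a proton above their pKa.
PKA_SIDECHAIN_NEG = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDECHAIN_POS = {"H": 5.98, "K": 10.0, "R": 12.0}
PKA_CTERM = 3.55
PKA_NTERM_DEFAULT = 7.5
# Residue-specific N-terminal pKa overrides (keyed by the first residue).
PKA_NTERM = {
    "A": 7.59, "E": 7.70, "M": 7.00, "P": 8.36,
    "S": 6.93, "T": 6.82, "V": 7.44,
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# --- Interaction atom tables ---------------------------------------------

# Side-chain heavy-atom donors of H-bonds (heavy-atom criterion).
HBOND_SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"),
    "K": ("NZ",),
    "H": ("ND1", "NE2"),
    "N": ("ND2",),
    "Q": ("NE2",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "W": ("NE1",),
    "C": ("SG",),
}
# Side-chain heavy-atom acceptors.
HBOND_SIDECHAIN_ACCEPTORS = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
    "H": ("ND1", "NE2"),
    "M": ("SD",),
    "C": ("SG",),
}

# Salt bridges: carboxylate oxygens vs. basic nitrogens.
ACIDIC_O_ATOMS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}
BASIC_N_ATOMS = {"K": ("NZ",), "R": ("NE", "NH1", "NH2"), "H": ("ND1", "NE2")}

# Aromatic ring definitions (atom-name tuples); Trp carries two rings.
AROMATIC_RINGS = {
    "F": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "Y": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "H": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "W": (
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ),
}

# Sulfur atoms that can engage aromatic rings.
SULFUR_ATOMS = {"C": ("SG",), "M": ("SD",)}
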