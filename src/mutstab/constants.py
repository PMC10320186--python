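"""Amino-acid alphabets, name maps and reference tables shared across modules."""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA3 = frozenset(AA3_TO_1)
STANDARD_AA1 = frozenset(AA1_TO_3)

# Non-standard residues mapped to their standard parents on parsing.
# Atom renames applied alongside (selenium -> sulphur for selenomethionine).
NONSTANDARD_PARENT = {"MSE": "MET", "SEC": "CYS", "MLY": "LYS", "PTR": "TYR",
                      "SEP": "SER", "TPO": "THR", "CSO": "CYS", "HYP": "PRO"}
NONSTANDARD_ATOM_RENAME = {("MSE", "SE"): "SD"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# van der Waals radii (A) for the heavy elements found in standard residues
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Theoretical maximum accessible surface areas (A^2) per residue, used to
# express solvent accessibility as a fraction (Tien-style reference values).
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
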