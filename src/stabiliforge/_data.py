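"""Reference constants shared across the package.

Amino-acid alphabet ordering, three-/one-letter mappings, BLOSUM62
background frequencies (used as the reference distribution for
Jensen-Shannon conservation scoring), theoretical maximum solvent
accessibilities per residue type (Tien et al. 2013, "theoretical" column)
and Kyte-Doolittle hydropathies (used by the surrogate contact potential).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP_CHARS = frozenset("-.")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Non-standard residues mapped onto a standard parent; anything else is
# dropped on reading with a warning.
NONSTANDARD_PARENT = {"MSE": "MET"}

# BLOSUM62 amino-acid background frequencies (sum to 1.000 exactly at this
# precision); the conventional background for JSD conservation scoring.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

# Theoretical maximum accessible surface area per residue type in A^2
# (Tien et al. 2013); denominator for relative SASA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Kyte-Doolittle hydropathy; basis of the surrogate contact potential.
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Charge classes for the surface-charge filter. Histidine is treated as
# neutral at the pH 7 operating point.
POSITIVE_AA = frozenset("KR")
NEGATIVE_AA = frozenset("DE")


def charge_class(aa: str) -> int:
    """Return +1 / -1 / 0 for positively charged, negatively charged or
    neutral amino acids."""
    if aa in POSITIVE_AA:
        return 1
    if aa in NEGATIVE_AA:
        return -1
    return 0
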