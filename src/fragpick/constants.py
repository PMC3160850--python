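"""Shared alphabets and ideal backbone geometry used across the package."""

# Canonical one-letter amino-acid alphabet; also the column order of every
# 20-wide profile matrix in the package (vall profile columns, query profiles).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

AA1_TO_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}

# Reduced (DSSP 3-state) secondary structure letters, in the internal column
# order used by SSPrediction probability matrices.
SS_LETTERS = "HEL"
SS_INDEX = {s: i for i, s in enumerate(SS_LETTERS)}

# Torsion-bin (ABEGO) letters, the column order of torsion-bin probability
# matrices.  'O' is the cis-omega bin.
ABEGO_LETTERS = "ABEGO"
ABEGO_INDEX = {b: i for i, b in enumerate(ABEGO_LETTERS)}

# Backbone atoms available from the structure database.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

# Ideal backbone geometry (Engh-Huber-like values) used by the synthetic
# chain builder.  Bond lengths in Angstrom, angles in degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4

# CA-CA distance above which two consecutive residues are considered a
# chain break (trans peptide bond gives ~3.8 A).
DEFAULT_BREAK_THRESHOLD = 4.5
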