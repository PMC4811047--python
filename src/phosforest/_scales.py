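"""Amino-acid property tables shared by the descriptor encoders.

Everything here is indexed by the 21-letter alphabet: the 20 standard
residues (alphabetical) plus the placeholder 'X' used for window padding
and sanitized non-standard letters. 'X' carries no chemistry: it maps to
0 on every scale, to all-zero bit codes, and to distance 0 against every
residue, so padded windows stay encodable without inventing values.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PLACEHOLDER = "X"
ALPHABET = AMINO_ACIDS + PLACEHOLDER
N_AA = 20
X_INDEX = 20

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Eisenberg consensus hydrophobicity scale.
EISENBERG = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# Ten overlapping physicochemical classes; a residue may belong to several.
# Bit order is fixed and is the order of this tuple.
OP_CLASSES = (
    ("polar", "NQSDECTKRHYW"),
    ("positive", "KHR"),
    ("negative", "DE"),
    ("charged", "KHRDE"),
    ("hydrophobic", "AGCTIVLKHFWYM"),
    ("aliphatic", "IVL"),
    ("aromatic", "FYWH"),
    ("small", "PNDTCAGSV"),
    ("tiny", "ASGC"),
    ("proline", "P"),
)
OP_CLASS_NAMES = tuple(name for name, _ in OP_CLASSES)
OP_CLASS_MEMBERS = {name: frozenset(members) for name, members in OP_CLASSES}

# Three-group assignments for the seven CTD properties (Dubchak-style
# groupings; the hydrophobicity grouping maps MVKELRTA to 33113122).
CTD_PROPERTIES = (
    ("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    ("vdw_volume", ("GASTPDC", "NVEQIL", "MHKFRYW")),
    ("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    ("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    ("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    ("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    ("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
)
CTD_PROPERTY_NAMES = tuple(name for name, _ in CTD_PROPERTIES)

# Grantham (1974) side-chain composition, polarity and molecular volume,
# the inputs of his chemical-distance formula.
_GRANTHAM_C = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75,
    "Q": 0.89, "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0,
    "L": 0.0, "K": 0.33, "M": 0.0, "F": 0.0, "P": 0.39,
    "S": 1.42, "T": 0.71, "W": 0.13, "Y": 0.20, "V": 0.0,
}
_GRANTHAM_P = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}
_GRANTHAM_V = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0,
    "Q": 85.0, "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0,
    "L": 111.0, "K": 119.0, "M": 105.0, "F": 132.0, "P": 32.5,
    "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0,
}


def _as_vector(scale: dict[str, float], placeholder: float = 0.0) -> np.ndarray:
    out = np.full(len(ALPHABET), placeholder, dtype=float)
    for aa, value in scale.items():
        out[AA_TO_INDEX[aa]] = value
    return out


EISENBERG_VEC = _as_vector(EISENBERG)

# 21 x 10 membership bits, X row all zero.
OP_BITS = np.zeros((len(ALPHABET), len(OP_CLASSES)), dtype=float)
for _j, (_name, _members) in enumerate(OP_CLASSES):
    for _aa in _members:
        OP_BITS[AA_TO_INDEX[_aa], _j] = 1.0

# 21 x 20 one-hot identity, X row all zero.
ONE_HOT = np.zeros((len(ALPHABET), N_AA), dtype=float)
for _aa in AMINO_ACIDS:
    ONE_HOT[AA_TO_INDEX[_aa], AA_TO_INDEX[_aa]] = 1.0

# Per property: 21-vector of group codes 1/2/3, 0 for the placeholder.
CTD_CODES = {}
for _prop, _groups in CTD_PROPERTIES:
    codes = np.zeros(len(ALPHABET), dtype=int)
    for _code, _members in enumerate(_groups, start=1):
        for _aa in _members:
            codes[AA_TO_INDEX[_aa]] = _code
    assert sorted(np.nonzero(codes)[0]) == list(range(N_AA))
    CTD_CODES[_prop] = codes


def grantham_distance_matrix() -> np.ndarray:
    """Grantham chemical distance, normalized to [0, 1].

    D(a,b) = 50.723 * sqrt(1.833 dc^2 + 0.1018 dp^2 + 0.000399 dv^2),
    computed from his composition/polarity/volume table and then divided
    by the largest pairwise distance. Rows/columns follow ``ALPHABET``;
    the placeholder has distance 0 to everything.
    """
    c = _as_vector(_GRANTHAM_C)
    p = _as_vector(_GRANTHAM_P)
    v = _as_vector(_GRANTHAM_V)
    d = np.sqrt(
        1.833 * np.subtract.outer(c, c) ** 2
        + 0.1018 * np.subtract.outer(p, p) ** 2
        + 0.000399 * np.subtract.outer(v, v) ** 2
    ) * 50.723
    d[X_INDEX, :] = 0.0
    d[:, X_INDEX] = 0.0
    return d / d.max()


def hydropathy_distance_matrix() -> np.ndarray:
    """Pairwise |Eisenberg hydrophobicity difference|, normalized to [0, 1].

    Serves as the first of the two physicochemical distance matrices
    behind the sequence-order descriptors. The placeholder has distance 0
    to everything.
    """
    h = EISENBERG_VEC.copy()
    d = np.abs(np.subtract.outer(h, h))
    d[X_INDEX, :] = 0.0
    d[:, X_INDEX] = 0.0
    return d / d.max()


HYDROPATHY_DIST = hydropathy_distance_matrix()
GRANTHAM_DIST = grantham_distance_matrix()

#: The two distance matrices used by the sequence-order descriptors,
#: in the order their feature blocks are laid out.
DISTANCE_MATRICES = (
    ("hydropathy", HYDROPATHY_DIST),
    ("grantham", GRANTHAM_DIST),
)


def encode_indices(window: str) -> np.ndarray:
    """Map a residue string to alphabet indices (X and unknowns -> 20)."""
    return np.array([AA_TO_INDEX.get(ch, X_INDEX) for ch in window], dtype=int)
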