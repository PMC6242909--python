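"""Amino-acid alphabets and standard genetic-code degeneracy tables."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code. This order
#: is the canonical row/column order of every matrix in the package.
STANDARD_AAS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard letters tolerated in input sequences but excluded from
#: variant enumeration and all statistics: B (Asx), U (selenocysteine),
#: X (unknown), Z (Glx).
NONSTANDARD_AAS: str = "BUXZ"

ALLOWED_AAS = frozenset(STANDARD_AAS + NONSTANDARD_AAS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AAS)}

STANDARD_AA_ARRAY = np.array(list(STANDARD_AAS))

#: Number of sense codons encoding each amino acid in the standard nuclear
#: genetic code; the 20 values sum to 61 (64 codons minus 3 stops).
CODON_DEGENERACY: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}

#: MUT_INDEX[i] lists the 19 mutant amino-acid indices for wild-type index i
#: (row i omits i itself), ascending, i.e. alphabetical mutant order.
MUT_INDEX = np.array(
    [[j for j in range(20) if j != i] for i in range(20)], dtype=np.int8
)

# byte value -> standard-AA index; -1 for everything else (incl. B/U/X/Z).
_AA_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _AA_CODE_LUT[ord(_aa)] = _i


def aa_indices(sequence: str) -> np.ndarray:
    """Map a sequence to standard-AA indices; -1 marks non-standard letters.

    Vectorised; the workhorse behind enumeration and matrix construction.
    """
    return _AA_CODE_LUT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
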