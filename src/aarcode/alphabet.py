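"""Canonical amino-acid alphabet and fixed orderings.

Every matrix, feature vector and TSV column in the package uses the
alphabetical one-letter order defined here; downstream code indexes into it
rather than re-deriving orders locally.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical one-letter amino-acid codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Position of each letter in :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA = len(AMINO_ACIDS)

#: Number of unordered pairs of distinct amino acids (20 choose 2).
N_UNORDERED_PAIRS = N_AA * (N_AA - 1) // 2

#: The eight AARs most represented in developmental proteins
#: (polyA/E/G/H/P/Q/R/S), used as the default reduced parameter subset.
DP_AAR_SUBSET: tuple[str, ...] = tuple("AEGHPQRS")

# Byte-level lookup: ASCII code -> alphabet index, -1 for anything else.
_CODE_TO_INDEX = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _CODE_TO_INDEX[ord(_aa)] = _i


def is_canonical(sequence: str) -> bool:
    """True if *sequence* contains only the 20 canonical letters."""
    return all(c in AA_INDEX for c in sequence)


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes (no validation)."""
    return np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
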