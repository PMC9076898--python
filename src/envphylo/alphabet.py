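"""The 20-letter amino-acid alphabet and its canonical ordering.

Every vector, tensor and matrix in the package indexes residues in the
biochemist's customary order A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P,
S, T, W, Y, V.  Characters outside this alphabet (B, Z, J, X, U, O, gaps,
...) are retained in sequences as opaque placeholders: they occupy a
position, so the offsets of flanking standard residues are unchanged, but
they are never counted as targets, neighbors or k-mer members.
"""

from __future__ import annotations

import numpy as np

AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
N_AA: int = 20

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

# byte-value lookup table: standard residue -> 0..19, anything else -> -1
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_aa)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a protein sequence as int8 codes (placeholders become -1)."""
    raw = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def is_standard(residue: str) -> bool:
    return residue in AA_INDEX
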