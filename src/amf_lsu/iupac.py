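"""IUPAC nucleotide codes, bitmask encoding, and reverse complementation.

Bases are encoded as 4-bit masks (A=1, C=2, G=4, T=8); a degenerate code is
the OR of the bases it denotes. Two characters are *compatible* when their
masks intersect — this is the matching rule used for primer scanning, where
an N (mask 15) matches anything.
"""

from __future__ import annotations

import numpy as np

IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn-",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn-",
)

# char-code -> mask lookup; 0 marks an invalid character
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_TABLE[ord(_c)] = _m
    _MASK_TABLE[ord(_c.lower())] = _m
_GAP_OK_TABLE = _MASK_TABLE.copy()
_GAP_OK_TABLE[ord("-")] = 15  # gaps treated as missing data where allowed


class SequenceError(ValueError):
    """Raised for sequences containing non-IUPAC characters."""


def validate_iupac(seq: str, *, allow_gap: bool = False, context: str = "sequence") -> None:
    table = _GAP_OK_TABLE if allow_gap else _MASK_TABLE
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    bad = table[arr] == 0
    if bad.any():
        offending = sorted({seq[i] for i in np.nonzero(bad)[0]})
        raise SequenceError(f"invalid characters in {context}: {offending}")


def encode_mask(seq: str, *, allow_gap: bool = False) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask array; raises on invalid chars."""
    table = _GAP_OK_TABLE if allow_gap else _MASK_TABLE
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    out = table[arr]
    if (out == 0).any():
        validate_iupac(seq, allow_gap=allow_gap)
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
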