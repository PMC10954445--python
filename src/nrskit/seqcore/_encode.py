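"""Nucleotide encoding helpers shared by the seqcore engines."""
from __future__ import annotations

import numpy as np

# A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_LUT = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _LUT[ord(base)] = i
    _LUT[ord(base.lower())] = i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_CHARS = frozenset("ACGTNacgtn")


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integers at every start position without an ambiguous base.

    Returns (kmers, positions); kmers containing code 4 are dropped.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # rolling base-4 packing; windows containing an N are dropped
    wide = codes.astype(np.int64)
    acc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        acc *= 4
        acc += np.clip(wide[j:j + n], 0, 3)
    bad = np.concatenate(([0], np.cumsum(codes == 4)))
    valid = (bad[k:] - bad[:-k]) == 0
    return acc[valid], np.flatnonzero(valid).astype(np.int64)
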