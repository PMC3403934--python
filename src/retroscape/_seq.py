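"""Shared nucleotide encoding helpers (internal).

Integer codes: A=0, C=1, G=2, T=3, '-'=4, N=5. Codes 0-3 are the only
states that enter distance/identity computations; 4 and 5 are masked.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, GAP, N = 0, 1, 2, 3, 4, 5

_CODE = {"A": A, "C": C, "G": G, "T": T, "-": GAP, "N": N}
_CHAR = "ACGT-N"

_COMP = str.maketrans("ACGTN", "TGCAN")

# lookup table for fast byte-level encoding; unknown bytes -> 255
_LUT = np.full(256, 255, dtype=np.uint8)
for _ch, _co in _CODE.items():
    _LUT[ord(_ch)] = _co
    _LUT[ord(_ch.lower())] = _co


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an int8 code array."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0]})
        raise ValueError(f"unsupported characters in sequence: {bad}")
    return arr.astype(np.int8)


def decode(codes) -> str:
    return "".join(_CHAR[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_transition(a: int, b: int) -> bool:
    """A<->G and C<->T are transitions (same parity in this coding)."""
    return a != b and (a & 1) == (b & 1)


def cpg_columns(consensus: str) -> set[int]:
    """1-based positions covered by CpG dinucleotides of `consensus`."""
    cols: set[int] = set()
    for i in range(len(consensus) - 1):
        if consensus[i] == "C" and consensus[i + 1] == "G":
            cols.add(i + 1)
            cols.add(i + 2)
    return cols
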