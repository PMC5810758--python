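"""Small shared helpers: DNA alphabet handling and interval arithmetic.

All genomic intervals at module interfaces are 1-based closed, the GTF/SAM
convention; BED output converts to 0-based half-open at the file boundary.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: nucleotide -> 2-bit code used by the packed off-target scanner
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _CODE_LUT[ord(_b)] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode_seq(seq: str) -> np.ndarray:
    """2-bit codes (A=0,C=1,G=2,T=3) as uint8; N and other bases map to 255."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Shared length, in bp, of two 1-based closed intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return overlap_bp(a, b) > 0
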