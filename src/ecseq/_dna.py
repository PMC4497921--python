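"""Small DNA helpers shared across modules: complementing and 2-bit-ish encoding.

Bases are encoded as uint8 codes 0..3 for A,C,G,T and 4 for anything else
('N'); code 5 is reserved for alignment gaps in per-position tallies.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
CODE_N = 4
CODE_GAP = 5

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ENCODE_LUT = np.full(256, CODE_N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ENCODE_LUT[ord(_b)] = _i
    ENCODE_LUT[ord(_b.lower())] = _i

DECODE_LUT = np.frombuffer(b"ACGTN-", dtype=np.uint8)

BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
BASE_TO_CODE["N"] = CODE_N


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as 'N', 5 as '-'."""
    return DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")
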