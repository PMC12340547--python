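"""Small shared helpers for DNA sequences over the {A,C,G,T,N} alphabet.

Sequences are kept as plain Python strings at module boundaries and encoded
to small integer arrays (A=0, C=1, G=2, T=3, N=4) for numeric work.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# any IUPAC ambiguity code other than ACGT collapses to N on load
_TO_ACGTN = str.maketrans(
    "acgtnRYSWKMBDHVryswkmbdhvUu-.",
    "ACGTN" + "N" * 20 + "TTNN",
)

_ENC_TABLE = np.full(256, N_CODE, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENC_TABLE[ord(_b)] = _i


def clean_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT symbol to N."""
    out = seq.translate(_TO_ACGTN)
    if not set(out) <= {"A", "C", "G", "T", "N"}:
        bad = sorted(set(out) - {"A", "C", "G", "T", "N"})
        raise ValueError(f"unmappable characters in sequence: {bad}")
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN string as int8 codes (N and anything else -> 4)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)
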