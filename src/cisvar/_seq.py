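"""Shared DNA-sequence helpers: A/C/G/T integer encoding and reverse complement.

All scanners in this package work on uppercase A/C/G/T only; IUPAC ambiguity
codes are rejected rather than guessed at.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside uppercase A/C/G/T."""


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes < 0).any():
        bad = sorted({c for c in seq if c not in BASE_INDEX})
        raise InvalidSequenceError(f"non-ACGT characters in sequence: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def reverse_complement(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
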