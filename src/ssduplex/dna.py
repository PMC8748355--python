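"""Byte-level DNA helpers shared across the package.

Sequences are handled as numpy ``uint8`` arrays of ASCII codes so that
consensus calling and spectrum counting stay vectorised.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, N = (ord(b) for b in "ACGTN")
BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASES = "ACGT"

_COMP = np.arange(256, dtype=np.uint8)
for x, y in ((A, T), (C, G), (G, C), (T, A)):
    _COMP[x] = y
_COMP[N] = N
for x, y in ((ord("a"), T), (ord("c"), G), (ord("g"), C), (ord("t"), A)):
    _COMP[x] = y

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def codes_to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return codes_to_str(revcomp_codes(seq_to_codes(seq)))
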