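"""Nucleotide/protein sequence helpers shared across modules.

Sequences are handled as plain Python strings at module boundaries and as
uint8 code arrays (A=0, C=1, G=2, T=3, N/other=4, gap '-'=5) internally.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

_CODE = np.full(256, N, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_CODE[ord("-")] = GAP

_CHAR = np.frombuffer(b"ACGTN-", dtype=np.uint8)

_COMPLEMENT = np.array([T, G, C, A, N, GAP], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CHAR[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(nt: str) -> str:
    """Translate a coding sequence (standard code).

    The trailing stop is dropped; internal stops (possible after simulated
    substitutions) are written as 'X' so downstream protein aligners accept
    the sequence.
    """
    aa = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X")


def gc_fraction(seq: str) -> float:
    codes = encode(seq)
    acgt = np.isin(codes, (A, C, G, T))
    if not acgt.any():
        return 0.0
    return float(np.isin(codes, (C, G)).sum() / acgt.sum())
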