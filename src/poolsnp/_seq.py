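"""Shared sequence utilities: base encoding, reverse complement, FASTA/FASTQ I/O helpers.

Bases are encoded as uint8 codes; code 4 is N (ambiguous), code 5 is the
gap/deletion symbol used in pileups.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN-"
A, C, G, T, N, GAP = range(6)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([T, G, C, A, N, GAP], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A=0, C=1, G=2, T=3, N=4, -=5)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.frombuffer(b"ACGTN-", dtype=np.uint8)[codes]
    return out.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def phred_to_string(quals) -> str:
    """Phred scores -> Sanger (phred+33) quality string."""
    arr = np.asarray(quals, dtype=np.int16)
    return (arr + 33).astype(np.uint8).tobytes().decode("ascii")


def string_to_phred(qual: str, offset: int = 33) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - offset
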