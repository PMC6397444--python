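"""Nucleotide alphabet codec shared across the package.

Sequences are handled internally as ``int8`` arrays with A=0, C=1, G=2, T=3
and N=4.  N marks any character outside {A,C,G,T}; it is excluded from all
composition counts and any scan window containing it is skipped.
"""

from __future__ import annotations

import numpy as np

LETTERS = "ACGT"
N_CODE = 4

_ENC = np.full(256, N_CODE, dtype=np.int8)
for _i, _c in enumerate(LETTERS):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to an int8 array (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


def complement_codes(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr]


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def sanitize(seq: str) -> str:
    """Upper-case a sequence and map every non-ACGT character to N."""
    return decode(encode(seq))
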