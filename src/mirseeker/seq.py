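"""Sequence alphabet helpers.

The internal canonical alphabet is ACGU (RNA). Input data frequently arrives
as DNA (T instead of U); T and U are treated as the same base throughout.
"""

from __future__ import annotations

import numpy as np

CANONICAL_BASES = "ACGU"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

# integer encoding used by the numpy/numba kernels
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(CANONICAL_BASES):
    _ENCODE[ord(_b)] = _i

_VALID = frozenset(CANONICAL_BASES)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U}."""


def canonical(sequence: str) -> str:
    """Uppercase a sequence and map T to U, validating the alphabet."""
    seq = sequence.upper().replace("T", "U")
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise AlphabetError(f"non-ACGTU characters {bad} in sequence {sequence!r}")
    return seq


def is_canonical(sequence: str) -> bool:
    return _VALID.issuperset(sequence)


def revcomp(sequence: str) -> str:
    """Reverse complement on the ACGU alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def encode(sequence: str) -> np.ndarray:
    """Encode an ACGU string as a uint8 array (A,C,G,U -> 0..3)."""
    arr = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise AlphabetError(f"non-canonical sequence {sequence!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(CANONICAL_BASES[i] for i in arr)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(sequence: str) -> int:
    """Length of the longest single-base run."""
    best = run = 1
    if not sequence:
        return 0
    prev = sequence[0]
    for ch in sequence[1:]:
        if ch == prev:
            run += 1
            if run > best:
                best = run
        else:
            run = 1
            prev = ch
    return best
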