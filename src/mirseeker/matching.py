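"""Ungapped k-mismatch matching of short reads against reference sequences.

Reads in this pipeline are 18-35 nt, so full-length ungapped alignment
(substitutions only) emulates short-read mapper semantics exactly; at the
mismatch tolerances used (<= 3) gaps would never win anyway. Matching is
vectorised with a sliding-window comparison over the encoded reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seq import encode, revcomp


@dataclass(frozen=True)
class Match:
    """A full-length placement of a read on a reference sequence.

    ``start``/``end`` are 0-based half-open coordinates on the reference's
    forward strand; ``strand`` is '+' when the read matches the forward
    strand and '-' when its reverse complement does.
    """

    start: int
    end: int
    strand: str
    mismatches: int


class EncodedReference:
    """A reference sequence pre-encoded for repeated scanning."""

    __slots__ = ("sequence", "_arr")

    def __init__(self, sequence: str):
        self.sequence = sequence
        self._arr = encode(sequence)

    def __len__(self):
        return len(self.sequence)


def _scan(ref_arr: np.ndarray, read_arr: np.ndarray, max_mismatches: int) -> list[tuple[int, int]]:
    k = len(read_arr)
    if k == 0 or k > len(ref_arr):
        return []
    windows = sliding_window_view(ref_arr, k)
    mm = np.count_nonzero(windows != read_arr, axis=1)
    hits = np.flatnonzero(mm <= max_mismatches)
    return [(int(i), int(mm[i])) for i in hits]


def find_matches(
    read: str,
    reference: str | EncodedReference,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[Match]:
    """All ungapped full-length placements of ``read`` with at most
    ``max_mismatches`` substitutions.

    Matching the reverse complement of the read against the forward
    reference is reported as a '-' strand hit, which is equivalent to
    matching the read itself against the reverse strand.
    """
    ref = reference if isinstance(reference, EncodedReference) else EncodedReference(reference)
    k = len(read)
    out = [
        Match(s, s + k, "+", mm) for s, mm in _scan(ref._arr, encode(read), max_mismatches)
    ]
    if both_strands:
        rc = encode(revcomp(read))
        out.extend(Match(s, s + k, "-", mm) for s, mm in _scan(ref._arr, rc, max_mismatches))
    out.sort(key=lambda m: (m.mismatches, m.start, m.strand))
    return out


def naive_find_matches(
    read: str,
    reference: str,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[Match]:
    """Sliding-window oracle for :func:`find_matches` (used in tests)."""
    out = []
    queries = [(read, "+")]
    if both_strands:
        queries.append((revcomp(read), "-"))
    k = len(read)
    for query, strand in queries:
        for s in range(0, len(reference) - k + 1):
            mm = sum(a != b for a, b in zip(reference[s : s + k], query))
            if mm <= max_mismatches:
                out.append(Match(s, s + k, strand, mm))
    out.sort(key=lambda m: (m.mismatches, m.start, m.strand))
    return out
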