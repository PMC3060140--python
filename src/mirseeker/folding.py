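"""Deterministic RNA secondary-structure prediction for hairpin screening.

The built-in folder maximises a simple pairing score (Watson-Crick pairs
plus G·U wobble, with a bonus for stacked helices and a minimum hairpin
loop of 3 nt) by dynamic programming and produces a dot-bracket structure
with a fixed traceback preference, so identical inputs give identical
structures on every platform. This is a base-pair-maximisation folder, not
a thermodynamic model: it is meant to recover the dominant stem of a
hairpin-shaped precursor candidate, which is all the downstream suitability
check needs. A thermodynamic engine (the ViennaRNA bindings, if installed)
can be plugged in behind the same contract with ``engine="vienna"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seq import canonical, encode

NEG = -1_000_000

# pair scores on the encoded alphabet (A=0, C=1, G=2, U=3)
_PAIR = np.zeros((4, 4), dtype=np.int64)
for _a, _b, _w in ((0, 3, 2), (1, 2, 3), (2, 3, 1)):  # AU=2, GC=3, GU=1
    _PAIR[_a, _b] = _w
    _PAIR[_b, _a] = _w

STACK_BONUS = 1
MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure plus a stability score
    (lower = more stable; the built-in engine reports the negated pairing
    score, a thermodynamic plug-in reports free energy)."""

    sequence: str
    structure: str
    score: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length must equal sequence length")

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@njit(cache=True)
def _fold_dp(enc, pair, min_loop, stack_bonus):
    n = enc.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int64)   # best score on [i, j)
    P = np.full((n + 1, n + 1), NEG, dtype=np.int64)  # best with i, j-1 paired
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open [i, j); candidate pair (i, j-1)
            w = pair[enc[i], enc[j - 1]]
            if w > 0 and span - 2 >= min_loop:
                inner = M[i + 1, j - 1]
                stacked = P[i + 1, j - 1] + stack_bonus
                P[i, j] = w + (stacked if stacked > inner else inner)
            best = M[i + 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if P[i, j] > best:
                best = P[i, j]
            for k in range(i + 1, j):
                cand = M[i, k] + M[k, j]
                if cand > best:
                    best = cand
            M[i, j] = best
    return M, P


def _traceback(enc, M, P, min_loop, stack_bonus) -> list[tuple[int, int]]:
    """Deterministic traceback: pairing beats leaving ends unpaired beats
    bifurcation; within a helix, stacking beats branching."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(enc), False)]  # (i, j, via_P)
    while stack:
        i, j, via_p = stack.pop()
        if j - i <= min_loop + 1 and not via_p:
            continue
        if via_p:
            pairs.append((i, j - 1))
            w = int(_PAIR[enc[i], enc[j - 1]])
            if (
                P[i + 1, j - 1] + stack_bonus + w == P[i, j]
                and P[i + 1, j - 1] > NEG
            ):
                stack.append((i + 1, j - 1, True))
            elif j - 1 - (i + 1) > min_loop + 1:
                stack.append((i + 1, j - 1, False))
            continue
        target = M[i, j]
        if target == 0:
            continue
        if P[i, j] == target:
            stack.append((i, j, True))
        elif M[i + 1, j] == target:
            stack.append((i + 1, j, False))
        elif M[i, j - 1] == target:
            stack.append((i, j - 1, False))
        else:
            for k in range(i + 1, j):
                if M[i, k] + M[k, j] == target:
                    stack.append((i, k, False))
                    stack.append((k, j, False))
                    break
    return pairs


def fold(sequence: str, max_len: int = 400, engine: str = "builtin") -> FoldResult:
    """Fold an RNA sequence into its best-scoring secondary structure.

    Raises for sequences longer than ``max_len`` (the DP is cubic).
    ``engine="vienna"`` substitutes the ViennaRNA thermodynamic folder, if
    its Python bindings are importable, behind the same contract.
    """
    seq = canonical(sequence)
    if len(seq) > max_len:
        raise ValueError(f"sequence length {len(seq)} exceeds max_len={max_len}")
    if engine == "vienna":
        return _fold_vienna(seq)
    if engine != "builtin":
        raise ValueError(f"unknown folding engine {engine!r}")
    if len(seq) < MIN_LOOP + 2:
        return FoldResult(seq, "." * len(seq), 0.0)
    enc = encode(seq)
    M, P = _fold_dp(enc, _PAIR, MIN_LOOP, STACK_BONUS)
    pairs = _traceback(enc, M, P, MIN_LOOP, STACK_BONUS)
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(seq, "".join(structure), -float(M[0, len(seq)]))


def _fold_vienna(seq: str) -> FoldResult:
    import RNA  # ViennaRNA python bindings; optional plug-in

    structure, mfe = RNA.fold(seq)
    return FoldResult(seq, structure, float(mfe))


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 for unpaired). Validates balance."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def validate_structure(structure: str, min_loop: int = MIN_LOOP) -> None:
    """Assert balanced brackets and the minimum hairpin loop length."""
    pt = pair_table(structure)
    for i, j in enumerate(pt):
        if j > i and j - i - 1 < min_loop:
            raise ValueError(f"pair ({i},{j}) violates minimum loop length {min_loop}")


def hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """Half-open intervals of terminal (hairpin) loops: maximal unpaired
    runs directly enclosed by a base pair, i.e. '(' ... ')' with no pair
    in between."""
    loops = []
    n = len(structure)
    i = 0
    while i < n:
        if structure[i] == ".":
            j = i
            while j < n and structure[j] == ".":
                j += 1
            if i > 0 and j < n and structure[i - 1] == "(" and structure[j] == ")":
                loops.append((i, j))
            i = j
        else:
            i += 1
    return loops
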