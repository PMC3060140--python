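"""Raw-read preprocessing: homopolymer removal, stepwise adapter trimming,
length gating and collapsing to unique sequences with abundances.

Small-RNA libraries are sequenced as fixed-cycle reads (36 by default) in
which the biological insert is flanked by ligation adapters. Adapters are
located by a stepwise anchor search: progressively shorter anchors of the
adapter are matched with progressively fewer allowed mismatches, so that
error-containing adapter copies are still found while chance matches to
insert sequence remain rare. Base qualities are deliberately ignored; the
error handling downstream (``error_model``) works on read abundances instead.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .seq import AlphabetError, canonical, max_homopolymer_run

# Adapter sequences from the standard small-RNA ligation protocol
# (5' adaptor and 3' adaptor, written 5'->3'; the 3' adaptor's inverted-dT
# terminator is not part of the sequenced bases).
FIVE_PRIME_ADAPTER = "GUUCAGAGUUCUACAGUCCGACGAUC"
THREE_PRIME_ADAPTER = "UCGUAUGCCGUCUUCUGCUUGU"


@dataclass(frozen=True)
class RawRead:
    """A single sequencer read (insert plus adapter context)."""

    id: str
    sequence: str
    library: str = "lib1"

    def __post_init__(self):
        object.__setattr__(self, "sequence", canonical(self.sequence))


def _default_five_prime_schedule() -> tuple[tuple[int, int], ...]:
    # anchor lengths 17 -> 10; end points fixed by the library protocol
    # (17 rightmost bases / 4 mismatches down to 10 rightmost / 0 mismatches),
    # interior chosen monotone.
    return tuple(zip(range(17, 9, -1), (4, 4, 3, 3, 2, 1, 0, 0)))


def _default_three_prime_schedule() -> tuple[tuple[int, int], ...]:
    # anchor lengths 22 -> 7 with mismatch allowances decaying quadratically
    # between the fixed end points (22 bases / 8 mismatches, 7 bases /
    # 1 mismatch). A steeper-than-linear decay keeps the chance-match rate of
    # the mid-length anchors against random insert sequence low enough for
    # trimming to be essentially lossless on error-free reads.
    sched = []
    for k in range(22, 6, -1):
        mm = max(1, round(8.0 * ((k - 7) / 15.0) ** 2))
        sched.append((k, mm))
    return tuple(sched)


@dataclass(frozen=True)
class AdapterSpec:
    """Adapters plus their stepwise anchor-search schedules.

    ``five_prime_schedule`` / ``three_prime_schedule`` are ordered lists of
    ``(anchor_length, max_mismatches)`` tried longest-anchor first. For the
    5' adapter the anchor is the adapter's *rightmost* k bases and must match
    near the start of the read; for the 3' adapter it is the *leftmost* k
    bases, searched left-to-right along the read (the shortest anchors may
    partially overhang the read end).
    """

    five_prime: str = FIVE_PRIME_ADAPTER
    three_prime: str = THREE_PRIME_ADAPTER
    five_prime_schedule: tuple[tuple[int, int], ...] = field(
        default_factory=_default_five_prime_schedule
    )
    three_prime_schedule: tuple[tuple[int, int], ...] = field(
        default_factory=_default_three_prime_schedule
    )
    five_prime_window_slack: int = 2   # anchor must match within first k+slack bases
    three_prime_max_overhang: int = 2  # bases of the anchor allowed past the read end

    def __post_init__(self):
        object.__setattr__(self, "five_prime", canonical(self.five_prime))
        object.__setattr__(self, "three_prime", canonical(self.three_prime))
        for name, sched, adapter in (
            ("five_prime", self.five_prime_schedule, self.five_prime),
            ("three_prime", self.three_prime_schedule, self.three_prime),
        ):
            if not sched:
                raise ValueError(f"{name} schedule must be non-empty")
            lengths = [k for k, _ in sched]
            mms = [m for _, m in sched]
            if any(b >= a for a, b in zip(lengths, lengths[1:])):
                raise ValueError(f"{name} anchor lengths must be strictly decreasing")
            if any(b > a for a, b in zip(mms, mms[1:])):
                raise ValueError(f"{name} mismatch allowances must be non-increasing")
            if max(lengths) > len(adapter):
                raise ValueError(f"{name} anchors longer than the adapter")


@dataclass
class CollapsedRead:
    """A unique insert sequence with its observation counts.

    The pipeline's atom: everything downstream works with unique sequences
    weighted by abundance rather than individual reads.
    """

    sequence: str
    abundance_total: int
    abundance_by_library: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = canonical(self.sequence)
        if self.abundance_by_library:
            total = sum(self.abundance_by_library.values())
            if total != self.abundance_total:
                raise ValueError(
                    "abundance_total does not equal the per-library sum "
                    f"({self.abundance_total} != {total})"
                )
        else:
            self.abundance_by_library = {"lib1": self.abundance_total}

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __repr__(self):  # compact: these appear in large collections
        return f"CollapsedRead({self.sequence}, x{self.abundance_total})"


@dataclass(frozen=True)
class Reject:
    sequence: str
    reason: str
    count: int = 1
    library: str = "lib1"


def _mismatches_leq(a: str, b: str, limit: int) -> bool:
    """True if hamming(a, b) <= limit, with early abort."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def filter_homopolymers(
    reads: Iterable[RawRead],
    max_run: int = 6,
    rejects: list[Reject] | None = None,
) -> Iterator[RawRead]:
    """Drop reads containing any single-base run longer than ``max_run``.

    Order is preserved. Invalid-alphabet reads are rejected with a reason
    rather than raising, so a stream with occasional N calls does not abort
    the run.
    """
    for read in reads:
        try:
            seq = canonical(read.sequence)
        except AlphabetError:
            if rejects is not None:
                rejects.append(Reject(read.sequence, "alphabet", library=read.library))
            continue
        if max_homopolymer_run(seq) > max_run:
            if rejects is not None:
                rejects.append(Reject(seq, "homopolymer", library=read.library))
            continue
        yield read


def trim_five_prime(sequence: str, spec: AdapterSpec) -> str:
    """Remove a 5' adapter tail from the start of the read, if present."""
    adapter = spec.five_prime
    for k, mm in spec.five_prime_schedule:
        anchor = adapter[-k:]
        for s in range(0, spec.five_prime_window_slack + 1):
            if s + k > len(sequence):
                break
            if _mismatches_leq(sequence[s : s + k], anchor, mm):
                return sequence[s + k :]
    return sequence


def trim_three_prime(sequence: str, spec: AdapterSpec) -> str:
    """Remove a 3' adapter head (and everything after it), if present."""
    adapter = spec.three_prime
    n = len(sequence)
    for k, mm in spec.three_prime_schedule:
        anchor = adapter[:k]
        # full-fit positions, leftmost hit wins
        for s in range(0, n - k + 1):
            if _mismatches_leq(sequence[s : s + k], anchor, mm):
                return sequence[:s]
        # anchor partially overhanging the read end; a truncated anchor
        # carries little information, so overhang matches must be exact
        for over in range(1, spec.three_prime_max_overhang + 1):
            s = n - k + over
            if s < 0 or s >= n:
                continue
            if sequence[s:] == anchor[: k - over]:
                return sequence[:s]
    return sequence


def trim_adapters(read: RawRead | str, spec: AdapterSpec) -> str | None:
    """Trim both adapters off a read.

    Returns the insert sequence, the read unchanged when no anchor matches,
    or ``None`` for a zero-length insert (adapter dimer).
    """
    seq = read.sequence if isinstance(read, RawRead) else canonical(read)
    seq = trim_five_prime(seq, spec)
    seq = trim_three_prime(seq, spec)
    if len(seq) == 0:
        return None
    return seq


def gate_lengths(
    sequences: Iterable[str],
    min_len: int = 18,
    max_len: int = 35,
    rejects: list[Reject] | None = None,
) -> Iterator[str]:
    """Keep inserts with ``min_len <= length <= max_len``.

    The defaults drop everything shorter than 18 nt and any untrimmed
    36-cycle read.
    """
    for seq in sequences:
        if len(seq) < min_len:
            if rejects is not None:
                rejects.append(Reject(seq, "too_short"))
        elif len(seq) > max_len:
            if rejects is not None:
                rejects.append(Reject(seq, "too_long"))
        else:
            yield seq


def collapse(
    reads: Iterable[RawRead | tuple[str, int, str] | str],
) -> list[CollapsedRead]:
    """Collapse a read stream to unique sequences with abundances.

    Accepts ``RawRead`` objects, bare sequences (count 1, library ``lib1``)
    or ``(sequence, count, library)`` tuples. Total read count is conserved
    exactly. The result is sorted by decreasing abundance, ties broken
    lexicographically, so collapsing is order-independent.
    """
    per_lib: dict[str, Counter] = defaultdict(Counter)
    for item in reads:
        if isinstance(item, RawRead):
            per_lib[item.sequence][item.library] += 1
        elif isinstance(item, str):
            per_lib[canonical(item)]["lib1"] += 1
        else:
            seq, count, library = item
            per_lib[canonical(seq)][library] += count
    out = []
    for seq, libs in per_lib.items():
        total = sum(libs.values())
        out.append(CollapsedRead(seq, total, dict(sorted(libs.items()))))
    out.sort(key=lambda r: (-r.abundance_total, r.sequence))
    return out


def preprocess(
    reads: Iterable[RawRead | tuple[str, int, str]],
    adapters: AdapterSpec | None = None,
    min_len: int = 18,
    max_len: int = 35,
    max_homopolymer: int = 6,
    rejects: list[Reject] | None = None,
) -> list[CollapsedRead]:
    """Full preprocessing stage: homopolymer filter -> adapter trimming ->
    length gate -> collapse.

    For efficiency identical raw sequences are deduplicated before trimming
    (trimming is a pure function of the sequence), so the cost scales with
    the number of unique raw sequences rather than the number of reads.
    """
    adapters = adapters or AdapterSpec()
    tally: dict[tuple[str, str], int] = Counter()
    for item in reads:
        if isinstance(item, RawRead):
            tally[(item.sequence, item.library)] += 1
        else:
            seq, count, library = item
            tally[(canonical(seq), library)] += count

    trimmed_cache: dict[str, str | None] = {}
    kept: list[tuple[str, int, str]] = []
    for (seq, library), count in tally.items():
        if max_homopolymer_run(seq) > max_homopolymer:
            if rejects is not None:
                rejects.append(Reject(seq, "homopolymer", count, library))
            continue
        if seq not in trimmed_cache:
            trimmed_cache[seq] = trim_adapters(seq, adapters)
        insert = trimmed_cache[seq]
        if insert is None:
            if rejects is not None:
                rejects.append(Reject(seq, "adapter_dimer", count, library))
            continue
        if len(insert) < min_len:
            if rejects is not None:
                rejects.append(Reject(insert, "too_short", count, library))
        elif len(insert) > max_len:
            if rejects is not None:
                rejects.append(Reject(insert, "too_long", count, library))
        else:
            kept.append((insert, count, library))
    return collapse(kept)
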