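"""Contaminant and repeat filtering against labelled reference collections.

Reads matching known rRNA/tRNA/snoRNA sequences or repeat collections are
removed before precursor discovery. Match stringency is tiered by how
closely related the reference's species is to the study species: by default
a hit to a barley or wheat sequence may carry at most one mismatch, while
hits to rice or any other species may carry up to three ("erring on the
conservative side": if any applicable tier accepts the alignment, the read
is treated as contaminant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .matching import EncodedReference, find_matches
from .preprocess import CollapsedRead
from .seq import canonical

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snoRNA")
REFERENCE_CLASSES = CONTAMINANT_CLASSES + ("repeat", "genomic", "EST", "organellar")


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str
    species: str
    cls: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for reference {self.id}")
        object.__setattr__(self, "sequence", canonical(self.sequence))
        if self.cls not in REFERENCE_CLASSES:
            raise ValueError(f"unknown reference class {self.cls!r}")
        if not self.species:
            raise ValueError(f"missing species for reference {self.id}")


class ReferenceCollection:
    """A set of reference sequences with species and class labels."""

    def __init__(self, records: Sequence[ReferenceRecord]):
        self.records = list(records)
        self._encoded = [EncodedReference(r.sequence) for r in self.records]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, ref_id: str) -> ReferenceRecord:
        for r in self.records:
            if r.id == ref_id:
                return r
        raise KeyError(ref_id)

    @property
    def classes(self) -> set[str]:
        return {r.cls for r in self.records}


@dataclass(frozen=True)
class MatchPolicy:
    """Species-tiered mismatch tolerances for read-to-reference matching.

    ``tiers`` maps a lowercase species group to its maximum mismatch count;
    the ``other`` entry is the fallback. ``min_score_frac``, when set,
    additionally requires an alignment score of at least that fraction of
    the maximum attainable score under ``match_score``/``mismatch_score``
    (+1/-1 by default), whichever bound is tighter.
    """

    tiers: dict[str, int] = field(
        default_factory=lambda: {"barley": 1, "wheat": 1, "other": 3}
    )
    both_strands: bool = True
    min_score_frac: float | None = None
    match_score: float = 1.0
    mismatch_score: float = -1.0

    def __post_init__(self):
        if any(v < 0 for v in self.tiers.values()):
            raise ValueError("max_mismatches must be >= 0")
        if "other" not in self.tiers:
            raise ValueError("tiers must define an 'other' fallback")

    def max_mismatches(self, species: str, read_length: int) -> int:
        mm = self.tiers.get(species.lower(), self.tiers["other"])
        if self.min_score_frac is not None:
            # score of a full-length ungapped alignment with m mismatches:
            # (L - m) * match + m * mismatch >= frac * L * match
            denom = self.match_score - self.mismatch_score
            bound = (1.0 - self.min_score_frac) * self.match_score * read_length / denom
            mm = min(mm, int(bound + 1e-9))  # epsilon: the bound is inclusive
        return mm


@dataclass(frozen=True)
class ReadHit:
    read: str
    reference_id: str
    species: str
    cls: str
    start: int
    end: int
    strand: str
    mismatches: int


def match_read(
    read: str | CollapsedRead,
    collection: ReferenceCollection,
    policy: MatchPolicy | None = None,
) -> ReadHit | None:
    """Best tier-compliant hit of a read anywhere in the collection, or None.

    The best hit is the one with the fewest mismatches (ties broken by
    record order, then position, then strand) among all placements that
    satisfy the tier bound for the reference's species.
    """
    policy = policy or MatchPolicy()
    seq = read.sequence if isinstance(read, CollapsedRead) else canonical(read)
    if len(collection) == 0:
        warnings.warn("matching against an empty reference collection", RuntimeWarning)
        return None
    best: ReadHit | None = None
    for record, enc in zip(collection.records, collection._encoded):
        mm_allowed = policy.max_mismatches(record.species, len(seq))
        if mm_allowed < 0:
            continue
        for m in find_matches(seq, enc, mm_allowed, both_strands=policy.both_strands):
            if best is None or m.mismatches < best.mismatches:
                best = ReadHit(
                    seq, record.id, record.species, record.cls,
                    m.start, m.end, m.strand, m.mismatches,
                )
            break  # find_matches is sorted; first hit per record is its best
    return best


def filter_contaminants(
    reads: Iterable[CollapsedRead],
    collections: Sequence[ReferenceCollection] | ReferenceCollection,
    policy: MatchPolicy | None = None,
) -> tuple[list[CollapsedRead], list[tuple[CollapsedRead, ReadHit]]]:
    """Split reads into (kept, removed) against contaminant RNA collections.

    Removed reads carry the class (rRNA/tRNA/snoRNA) and reference id of
    their best hit. The final kept set does not depend on the order in which
    the collections are supplied.
    """
    if isinstance(collections, ReferenceCollection):
        collections = [collections]
    policy = policy or MatchPolicy()
    kept, removed = [], []
    for read in reads:
        hits = [
            h for coll in collections
            if len(coll) and (h := match_read(read, coll, policy)) is not None
        ]
        if hits:
            hits.sort(key=lambda h: (h.mismatches, h.cls, h.reference_id))
            removed.append((read, hits[0]))
        else:
            kept.append(read)
    return kept, removed


def filter_repeats(
    reads: Iterable[CollapsedRead],
    repeat_collection: ReferenceCollection,
    policy: MatchPolicy | None = None,
    enabled: bool = True,
) -> tuple[list[CollapsedRead], list[tuple[CollapsedRead, ReadHit]], list[tuple[CollapsedRead, ReadHit]]]:
    """Remove reads similar to known repetitive sequences.

    Returns ``(kept, removed, flagged)``. With ``enabled=False`` repeat-like
    reads are kept but still reported in ``flagged`` — the "filtered but
    noted" side list that lets repeat-similar miRNA candidates be reported
    alongside the main table instead of silently vanishing.
    """
    policy = policy or MatchPolicy()
    kept, removed, flagged = [], [], []
    for read in reads:
        hit = match_read(read, repeat_collection, policy) if len(repeat_collection) else None
        if hit is None:
            kept.append(read)
        elif enabled:
            removed.append((read, hit))
        else:
            kept.append(read)
            flagged.append((read, hit))
    return kept, removed, flagged
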