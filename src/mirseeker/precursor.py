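"""Cross-species precursor discovery: map reads to genomic/EST references,
extract candidate windows around the mapped sites, fold them and evaluate
hairpin suitability.

Without a genome for the study species, reads are mapped to related-species
sequence with species-tiered stringency (exact for the study species' own
sequence, progressively looser for more distant relatives). Windows around
each mapped site are folded and screened with plant-miRNA precursor
criteria: the mature read must sit on one well-paired arm of a hairpin with
a locatable star partner on the opposing arm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_filters import MatchPolicy, ReferenceCollection, ReferenceRecord
from .folding import FoldResult, fold, hairpin_loops, pair_table
from .matching import EncodedReference, find_matches
from .preprocess import CollapsedRead
from .seq import revcomp

#: default mapping stringency: exact in barley, <= 1 mismatch in wheat, up
#: to 3 mismatches (tightened by the 80%-of-max-score rule) in rice,
#: Brachypodium or anything else.
DEFAULT_MAPPING_POLICY = MatchPolicy(
    tiers={"barley": 0, "wheat": 1, "rice": 3, "brachypodium": 3, "other": 3},
    both_strands=True,
    min_score_frac=0.8,
)

#: (upstream, downstream) flank pairs spanning typical plant pre-miRNA sizes
DEFAULT_FLANK_GRID = ((0, 250), (250, 0), (60, 190), (190, 60), (125, 125))


@dataclass(frozen=True)
class GenomicHit:
    """A read placement on a genomic/EST reference (0-based half-open)."""

    read: str
    reference_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    species: str

    def __post_init__(self):
        if self.end - self.start != len(self.read):
            raise ValueError("hit span must equal read length")


def map_reads(
    reads: list[CollapsedRead],
    references: ReferenceCollection,
    policy: MatchPolicy = DEFAULT_MAPPING_POLICY,
    max_hits_per_read: int | None = 20,
) -> list[GenomicHit]:
    """All tier-compliant placements of each read on the references.

    ``max_hits_per_read`` caps the number of placements kept per read
    (lowest mismatch count first) so highly repetitive matches do not blow
    up the downstream folding workload.
    """
    hits: list[GenomicHit] = []
    for read in reads:
        seq = read.sequence
        read_hits: list[GenomicHit] = []
        for record, enc in zip(references.records, references._encoded):
            mm_allowed = policy.max_mismatches(record.species, len(seq))
            if mm_allowed < 0:
                continue
            for m in find_matches(seq, enc, mm_allowed, policy.both_strands):
                read_hits.append(
                    GenomicHit(seq, record.id, m.start, m.end, m.strand,
                               m.mismatches, record.species)
                )
        read_hits.sort(key=lambda h: (h.mismatches, h.reference_id, h.start, h.strand))
        if max_hits_per_read is not None:
            read_hits = read_hits[:max_hits_per_read]
        hits.extend(read_hits)
    return hits


@dataclass(frozen=True)
class PrecursorWindow:
    """A candidate precursor window in transcript orientation.

    ``start``/``end`` are reference forward-strand coordinates; ``sequence``
    is reverse-complemented for '-' strand hits so that the mature site
    always reads 5'->3' within it. ``mature_site`` is the read's half-open
    interval within ``sequence``.
    """

    reference_id: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_site: tuple[int, int]
    species: str
    mismatches: int = 0  # of the generating hit; used to resolve strand

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_windows(
    hit: GenomicHit,
    reference: ReferenceRecord | str,
    flank_grid: tuple[tuple[int, int], ...] = DEFAULT_FLANK_GRID,
    max_window: int = 300,
) -> list[PrecursorWindow]:
    """Candidate windows around a mapped site, one per flank pair.

    Flanks are clipped at the reference ends; every window contains the
    mature site. Duplicate windows arising from clipping are merged.
    """
    if isinstance(reference, ReferenceRecord):
        ref_id, ref_seq, species = reference.id, reference.sequence, reference.species
    else:
        ref_id, ref_seq, species = hit.reference_id, reference, hit.species
    if hit.start < 0 or hit.end > len(ref_seq):
        raise ValueError(
            f"hit {hit.start}..{hit.end} outside reference {ref_id} "
            f"(length {len(ref_seq)})"
        )
    read_len = hit.end - hit.start
    windows: list[PrecursorWindow] = []
    seen: set[tuple[int, int]] = set()
    for up, down in flank_grid:
        if hit.strand == "+":
            ws = max(0, hit.start - up)
            we = min(len(ref_seq), hit.end + down)
        else:  # upstream flank is 3'-of-site on the reference for '-' hits
            ws = max(0, hit.start - down)
            we = min(len(ref_seq), hit.end + up)
        if we - ws > max_window:
            # trim the longer flank back to the cap, keeping the mature site
            excess = we - ws - max_window
            if hit.start - ws >= we - hit.end:
                ws += excess
            else:
                we -= excess
        if (ws, we) in seen:
            continue
        seen.add((ws, we))
        window_seq = ref_seq[ws:we]
        if hit.strand == "+":
            mature = (hit.start - ws, hit.end - ws)
        else:
            window_seq = revcomp(window_seq)
            mature = (we - hit.end, we - hit.start)
        windows.append(
            PrecursorWindow(ref_id, ws, we, hit.strand, window_seq, mature,
                            species, hit.mismatches)
        )
    return windows


@dataclass(frozen=True)
class HairpinCriteria:
    """Suitability thresholds for plant pre-miRNA screening.

    These operationalise the usual plant precursor checks (well-paired
    mature arm, limited bulges, a star arm opposite the loop, an overall
    paired hairpin); every threshold is configurable.
    """

    max_unpaired_mature: int = 4
    max_bulge: int = 2
    min_paired_frac: float = 0.5
    star_overhang: int = 2


@dataclass
class PrecursorCandidate:
    """A folded candidate window with its hairpin verdict."""

    window: PrecursorWindow
    fold: FoldResult
    verdict: str            # 'pass' or the first failing criterion
    star_site: tuple[int, int] | None = None
    organellar: bool = False

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    @property
    def mature_site(self) -> tuple[int, int]:
        return self.window.mature_site


def check_hairpin(
    window: PrecursorWindow,
    fold_result: FoldResult | None = None,
    criteria: HairpinCriteria = HairpinCriteria(),
    engine: str = "builtin",
) -> PrecursorCandidate:
    """Evaluate a folded window for miRNA-precursor suitability.

    Checks, in order (the verdict records the first failure):

    * ``loop``       - the mature site lies in a terminal loop, or pairs
      with itself;
    * ``unpaired``   - more than ``max_unpaired_mature`` mature bases are
      unpaired;
    * ``bulge``      - an internal run of unpaired mature bases exceeds
      ``max_bulge``;
    * ``no_star``    - no star interval can be located on the opposing arm;
    * ``low_pairing``- the hairpin's overall paired fraction is below
      ``min_paired_frac``.
    """
    fr = fold_result if fold_result is not None else fold(window.sequence, engine=engine)
    pt = pair_table(fr.structure)
    m0, m1 = window.mature_site
    n = len(fr.structure)

    # terminal-loop placement: mature midpoint inside a hairpin loop
    mid = (m0 + m1) // 2
    for l0, l1 in hairpin_loops(fr.structure):
        if l0 <= mid < l1:
            return PrecursorCandidate(window, fr, "loop")

    mature_partners = [int(pt[i]) for i in range(m0, m1) if pt[i] >= 0]
    if any(m0 <= q < m1 for q in mature_partners):
        return PrecursorCandidate(window, fr, "loop")

    unpaired = (m1 - m0) - len(mature_partners)
    if unpaired > criteria.max_unpaired_mature:
        return PrecursorCandidate(window, fr, "unpaired")

    # largest internal bulge: run of unpaired bases strictly inside the arm
    run = best_run = 0
    paired_flags = [pt[i] >= 0 for i in range(m0, m1)]
    first = paired_flags.index(True) if True in paired_flags else 0
    last = len(paired_flags) - 1 - paired_flags[::-1].index(True) if True in paired_flags else -1
    for flag in paired_flags[first : last + 1]:
        run = 0 if flag else run + 1
        best_run = max(best_run, run)
    if best_run > criteria.max_bulge:
        return PrecursorCandidate(window, fr, "bulge")

    if not mature_partners:
        return PrecursorCandidate(window, fr, "no_star")
    s_lo, s_hi = min(mature_partners), max(mature_partners) + 1
    if s_lo >= m1:      # star on the 3' arm: 2-nt 3' overhang extends right
        star = (min(s_lo + criteria.star_overhang, n - 1),
                min(s_hi + criteria.star_overhang, n))
    elif s_hi <= m0:    # star on the 5' arm
        star = (max(s_lo - criteria.star_overhang, 0),
                max(s_hi - criteria.star_overhang, 1))
    else:
        return PrecursorCandidate(window, fr, "no_star")

    paired_frac = float((pt >= 0).sum()) / n
    if paired_frac < criteria.min_paired_frac:
        return PrecursorCandidate(window, fr, "low_pairing")

    return PrecursorCandidate(window, fr, "pass", star_site=star)


def flag_organellar(
    candidates: list[PrecursorCandidate],
    organellar: ReferenceCollection | None,
) -> list[PrecursorCandidate]:
    """Flag candidates whose mature sequence occurs exactly in an organellar
    reference (flagged, never removed: such reads may still originate from
    the nuclear genome)."""
    if organellar is None or len(organellar) == 0:
        return candidates
    out = []
    for cand in candidates:
        m0, m1 = cand.mature_site
        mature = cand.window.sequence[m0:m1]
        flagged = any(
            find_matches(mature, enc, 0, both_strands=True)
            for enc in organellar._encoded
        )
        if flagged:
            cand = replace_candidate(cand, organellar=True)
        out.append(cand)
    return out


def replace_candidate(cand: PrecursorCandidate, **changes) -> PrecursorCandidate:
    return PrecursorCandidate(
        window=changes.get("window", cand.window),
        fold=changes.get("fold", cand.fold),
        verdict=changes.get("verdict", cand.verdict),
        star_site=changes.get("star_site", cand.star_site),
        organellar=changes.get("organellar", cand.organellar),
    )
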