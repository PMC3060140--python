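"""Read-depth profiles along candidate precursors and their classification.

The decisive signature of a genuine miRNA precursor in deep data is the
shape of the aligned read distribution: sharp coverage at the mature and
star sites, a silent loop between them. mRNA breakdown spreads reads
quasi-uniformly across the window, simultaneous sense/antisense
transcription puts substantial depth on the reverse strand, and windows
with a long open reading frame point at coding sequence. The classifier
applies those exclusions in order and maps the surviving localized shapes
to confidence stars: two peaks on opposite hairpin arms (mature + star)
rate ***, a single clean peak **, an atypical but still localized
distribution *.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .folding import FoldResult, hairpin_loops
from .matching import EncodedReference, find_matches
from .preprocess import CollapsedRead
from .seq import revcomp

START_CODON = "AUG"
STOP_CODONS = ("UAA", "UAG", "UGA")


@dataclass
class PrecursorProfile:
    """Strand-resolved per-position read depth over a precursor window."""

    precursor_id: str
    sequence: str
    depth_sense: np.ndarray
    depth_antisense: np.ndarray
    aligned_read_intervals: list[tuple[int, int, int, str, int]] = field(
        default_factory=list
    )  # (start, end, abundance, strand, mismatches)

    def __post_init__(self):
        n = len(self.sequence)
        if len(self.depth_sense) != n or len(self.depth_antisense) != n:
            raise ValueError("depth vector lengths must equal precursor length")

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_profile(
    precursor_id: str,
    precursor_seq: str,
    reads: list[CollapsedRead],
    max_mismatches: int = 3,
) -> PrecursorProfile:
    """Map every read (either strand, up to ``max_mismatches``
    substitutions) onto the precursor and accumulate abundance-weighted
    depth per position.

    Only a read's best placements (fewest mismatches) are kept: on a
    hairpin, a read from one arm also aligns antisense to the opposing arm
    with a few extra mismatches purely by complementarity, and counting
    those echoes would make every precursor look sense-antisense
    transcribed."""
    n = len(precursor_seq)
    enc = EncodedReference(precursor_seq)
    sense = np.zeros(n, dtype=np.int64)
    anti = np.zeros(n, dtype=np.int64)
    intervals = []
    for read in reads:
        if len(read.sequence) > n:
            continue
        matches = find_matches(read.sequence, enc, max_mismatches, both_strands=True)
        if not matches:
            continue
        best_mm = matches[0].mismatches  # sorted by mismatches
        for m in matches:
            if m.mismatches > best_mm:
                break
            intervals.append((m.start, m.end, read.abundance_total, m.strand, m.mismatches))
            target = sense if m.strand == "+" else anti
            target[m.start : m.end] += read.abundance_total
    intervals.sort()
    return PrecursorProfile(precursor_id, precursor_seq, sense, anti, intervals)


def segment_peaks(profile: PrecursorProfile, rel_floor: float = 0.05) -> list[tuple[int, int]]:
    """Maximal runs of positions with sense depth >= rel_floor * max depth."""
    depth = profile.depth_sense
    peak_max = int(depth.max(initial=0))
    if peak_max == 0:
        return []
    mask = depth >= rel_floor * peak_max
    peaks = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            peaks.append((i, j))
            i = j
        else:
            i += 1
    return peaks


class ProfileLabel(str, Enum):
    MIRNA_TWO_PEAK = "MIRNA_TWO_PEAK"
    MIRNA_SINGLE_PEAK = "MIRNA_SINGLE_PEAK"
    ATYPICAL_LOCALIZED = "ATYPICAL_LOCALIZED"
    DEGRADATION = "DEGRADATION"
    SENSE_ANTISENSE = "SENSE_ANTISENSE"
    CODING_ORF = "CODING_ORF"

    def __str__(self):
        return self.value


#: labels that exclude a window from miRNA candidacy
EXCLUDING_LABELS = frozenset(
    {ProfileLabel.DEGRADATION, ProfileLabel.SENSE_ANTISENSE, ProfileLabel.CODING_ORF}
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Numeric operationalization of the qualitative profile classes.

    All values are this pipeline's explicit choices and are logged into the
    run manifest: ``rel_floor`` (peak floor as fraction of max depth),
    ``gap_max`` ("virtually no reads" between peaks), ``peak_width_max``
    (sharply localized peak, nt), ``spread_max`` (covered fraction that
    counts as spread-out degradation), ``antisense_max`` (tolerated
    antisense read fraction), ``orf_min`` ("substantial" ORF, codons),
    ``localized_span_max`` (total peak span still called localized, nt).
    """

    rel_floor: float = 0.05
    gap_max: float = 0.02
    peak_width_max: int = 26
    spread_max: float = 0.8
    antisense_max: float = 0.10
    orf_min: int = 80
    localized_span_max: int = 60
    peak_dominance: float = 0.5


@dataclass
class ProfileClass:
    label: ProfileLabel
    peaks: list[tuple[int, int]]
    metrics: dict[str, float]


def longest_orf_codons(seq: str) -> int:
    """Longest open reading frame, in codons, over both strands and all
    three frames. An ORF starts at AUG and runs to the first stop codon or
    the end of the window."""
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        n = len(strand_seq)
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                if strand_seq[i : i + 3] == START_CODON:
                    codons = 0
                    j = i
                    while j + 3 <= n:
                        codon = strand_seq[j : j + 3]
                        if codon in STOP_CODONS:
                            break
                        codons += 1
                        j += 3
                    best = max(best, codons)
                    i = j + 3  # restart past this ORF
                else:
                    i += 3
    return best


def _opposite_arms(peaks, fold: FoldResult | None) -> bool:
    """Two peaks lie on opposite hairpin arms when the fold's main terminal
    loop separates them; without a fold, require non-overlapping peaks."""
    (a0, a1), (b0, b1) = sorted(peaks)
    if fold is None:
        return a1 <= b0
    loops = hairpin_loops(fold.structure)
    if not loops:
        return False
    # main loop: the one between the peaks if any, else the widest
    between = [l for l in loops if l[0] >= a1 and l[1] <= b0]
    loop = between[0] if between else max(loops, key=lambda l: l[1] - l[0])
    center = (loop[0] + loop[1]) / 2.0
    return a1 <= center <= b0


def classify_profile(
    profile: PrecursorProfile,
    fold: FoldResult | None = None,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> ProfileClass:
    """Classify a precursor read-depth profile.

    Decision order: coding-ORF exclusion, sense-antisense exclusion,
    degradation (spread coverage without a dominant sharp peak), two-peak
    miRNA shape, single-peak miRNA shape, atypical-but-localized; anything
    else falls through to DEGRADATION. The metrics the decision used are
    always reported.
    """
    t = thresholds
    peaks = segment_peaks(profile, t.rel_floor)
    sense_total = int(profile.depth_sense.sum())
    anti_total = int(profile.depth_antisense.sum())
    read_total = sense_total + anti_total
    antisense_fraction = anti_total / read_total if read_total else 0.0
    covered = float((profile.depth_sense > 0).mean()) if profile.length else 0.0
    orf = longest_orf_codons(profile.sequence)
    peak_width_max_obs = max((p[1] - p[0] for p in peaks), default=0)
    peak_span = sum(p[1] - p[0] for p in peaks)
    in_peaks = sum(int(profile.depth_sense[p0:p1].sum()) for p0, p1 in peaks)
    gap_fraction = 1.0 - (in_peaks / sense_total) if sense_total else 0.0

    metrics = {
        "gap_fraction": gap_fraction,
        "peak_width_max": float(peak_width_max_obs),
        "antisense_fraction": antisense_fraction,
        "longest_orf_codons": float(orf),
        "covered_fraction": covered,
        "n_peaks": float(len(peaks)),
    }

    def result(label):
        return ProfileClass(label, peaks, metrics)

    if orf >= t.orf_min:
        return result(ProfileLabel.CODING_ORF)
    if antisense_fraction >= t.antisense_max:
        return result(ProfileLabel.SENSE_ANTISENSE)
    if covered >= t.spread_max:
        dominant = any(
            (p1 - p0) <= t.peak_width_max
            and profile.depth_sense[p0:p1].sum() >= t.peak_dominance * sense_total
            for p0, p1 in peaks
        )
        if not dominant:
            return result(ProfileLabel.DEGRADATION)
    if (
        len(peaks) == 2
        and peak_width_max_obs <= t.peak_width_max
        and gap_fraction <= t.gap_max
        and _opposite_arms(peaks, fold)
    ):
        return result(ProfileLabel.MIRNA_TWO_PEAK)
    if (
        len(peaks) == 1
        and peak_width_max_obs <= t.peak_width_max
        and gap_fraction <= t.gap_max
    ):
        return result(ProfileLabel.MIRNA_SINGLE_PEAK)
    if peaks and peak_span <= t.localized_span_max:
        return result(ProfileLabel.ATYPICAL_LOCALIZED)
    return result(ProfileLabel.DEGRADATION)


CONFIDENCE_BY_LABEL = {
    ProfileLabel.MIRNA_TWO_PEAK: "***",
    ProfileLabel.MIRNA_SINGLE_PEAK: "**",
    ProfileLabel.ATYPICAL_LOCALIZED: "*",
}


@dataclass
class MiRNACandidate:
    """A reported miRNA candidate in the final-table layout."""

    name: str
    mature: str
    mature_abundance: int
    confidence: str
    star: str | None = None
    star_abundance: int | None = None
    family_id: str | None = None
    precursor_ids: list[str] = field(default_factory=list)
    organellar: bool = False
    repeat_flagged: bool = False

    def __post_init__(self):
        if self.confidence not in ("***", "**", "*"):
            raise ValueError(f"invalid confidence {self.confidence!r}")
        if self.confidence == "***" and self.star is None:
            raise ValueError("*** candidates require a star sequence")


def _peak_top_read(profile: PrecursorProfile, peak: tuple[int, int]) -> tuple[str, int] | None:
    """Most abundant sense read whose placement lies within the peak."""
    p0, p1 = peak
    best = None
    for start, end, abundance, strand, _mm in profile.aligned_read_intervals:
        if strand != "+" or start < p0 - 1 or end > p1 + 1:
            continue
        seq = profile.sequence[start:end]
        if best is None or (abundance, seq) > (best[1], best[0]):
            # higher abundance wins; lexicographically larger sequence is an
            # arbitrary but deterministic tie-break
            best = (seq, abundance)
    return best


def assign_confidence(
    classified: list[tuple[str, PrecursorProfile, ProfileClass]],
) -> list[MiRNACandidate]:
    """Turn classified profiles into candidates with confidence stars.

    Two-peak profiles rate *** (mature = most abundant read in the dominant
    peak, star = most abundant in the secondary peak), single-peak **,
    atypical-localized *; excluding labels produce no candidate. Pure
    function of the labels: no hidden state.
    """
    out = []
    for name, profile, pclass in classified:
        conf = CONFIDENCE_BY_LABEL.get(pclass.label)
        if conf is None:
            continue
        ranked = sorted(
            pclass.peaks,
            key=lambda p: int(profile.depth_sense[p[0] : p[1]].max(initial=0)),
            reverse=True,
        )
        mature = _peak_top_read(profile, ranked[0]) if ranked else None
        if mature is None:
            continue
        star = _peak_top_read(profile, ranked[1]) if len(ranked) > 1 else None
        if conf == "***" and star is None:
            conf = "**"
        out.append(
            MiRNACandidate(
                name=name,
                mature=mature[0],
                mature_abundance=mature[1],
                confidence=conf,
                star=star[0] if star else None,
                star_abundance=star[1] if star else None,
                precursor_ids=[profile.precursor_id],
            )
        )
    return out


def five_prime_composition(candidates: list[MiRNACandidate] | list[str]):
    """Counts and percentages of the 5'-terminal nucleotide over mature
    sequences (miRNAs show a marked preference for a 5' uracil)."""
    seqs = [
        c.mature if isinstance(c, MiRNACandidate) else c for c in candidates
    ]
    if not seqs:
        raise ValueError("need at least one candidate")
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s[0]] = counts.get(s[0], 0) + 1
    total = len(seqs)
    return {
        base: (count, 100.0 * count / total)
        for base, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
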