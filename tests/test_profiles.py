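"""Depth profiles, peak segmentation, profile classification, confidence
stars and 5' composition."""

import numpy as np
import pytest

from mirseeker.folding import fold
from mirseeker.io import load_table6
from mirseeker.preprocess import CollapsedRead, collapse
from mirseeker.profiles import (
    ClassifierThresholds,
    MiRNACandidate,
    ProfileLabel,
    assign_confidence,
    build_profile,
    classify_profile,
    five_prime_composition,
    longest_orf_codons,
    segment_peaks,
)
from mirseeker.seq import revcomp
from mirseeker.simulate import (
    design_precursor,
    emit_degradation_reads,
    emit_profile_reads,
    random_seq,
)


def orf_free_window(rng, length=300, orf_limit=50):
    """A random window guaranteed to lack long chance ORFs, so profile-shape
    rules can be tested in isolation."""
    while True:
        seq = random_seq(rng, length)
        if longest_orf_codons(seq) < orf_limit:
            return seq


class TestBuildProfile:
    def test_single_read_depth(self, rng):
        win = random_seq(rng, 60)
        read = CollapsedRead(win[10:31], 5)
        prof = build_profile("p", win, [read])
        assert prof.depth_sense[10:31].tolist() == [5] * 21
        assert prof.depth_sense.sum() == 5 * 21
        assert prof.depth_antisense.sum() == 0

    def test_depth_conservation(self, rng):
        d = design_precursor(rng)
        reads = collapse(emit_profile_reads(d, 300, 40, 0.1, rng))
        prof = build_profile("p", d.sequence, reads)
        placed = sum(
            ab * (e - s) for s, e, ab, strand, _ in prof.aligned_read_intervals
            if strand == "+"
        )
        assert prof.depth_sense.sum() == placed

    def test_mature_and_star_blocks_disjoint(self, rng):
        d = design_precursor(rng)
        reads = collapse(emit_profile_reads(d, 500, 60, 0.0, rng))
        prof = build_profile("p", d.sequence, reads)
        peaks = segment_peaks(prof)
        assert len(peaks) == 2
        (a0, a1), (b0, b1) = peaks
        assert a1 <= b0

    def test_read_with_too_many_mismatches_not_placed(self, rng):
        win = random_seq(rng, 80)
        read = list(win[20:41])
        for p in (0, 5, 10, 15):
            read[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[read[p]]
        prof = build_profile("p", win, [CollapsedRead("".join(read), 9)],
                             max_mismatches=3)
        assert prof.depth_sense.sum() == 0


class TestSegmentPeaks:
    def test_zero_profile(self, rng):
        win = random_seq(rng, 50)
        prof = build_profile("p", win, [])
        assert segment_peaks(prof) == []

    def test_uniform_profile_single_spanning_peak(self, rng):
        win = random_seq(rng, 200)
        reads = collapse(emit_degradation_reads(win, 2000, rng))
        prof = build_profile("p", win, reads)
        peaks = segment_peaks(prof)
        assert len(peaks) == 1
        assert peaks[0][1] - peaks[0][0] >= 0.9 * 200


class TestClassifyProfile:
    def test_two_peak_mirna(self, rng):
        d = design_precursor(rng)
        reads = collapse(emit_profile_reads(d, 500, 50, 0.1, rng))
        prof = build_profile("p", d.sequence, reads)
        out = classify_profile(prof, fold(d.sequence))
        assert out.label is ProfileLabel.MIRNA_TWO_PEAK

    def test_single_peak_without_star(self, rng):
        d = design_precursor(rng)
        reads = collapse(emit_profile_reads(d, 500, 0, 0.1, rng))
        prof = build_profile("p", d.sequence, reads)
        out = classify_profile(prof, fold(d.sequence))
        assert out.label is ProfileLabel.MIRNA_SINGLE_PEAK

    def test_uniform_degradation_window(self, rng):
        win = orf_free_window(rng, 300, ClassifierThresholds().orf_min)
        reads = collapse(emit_degradation_reads(win, 1000, rng))
        prof = build_profile("p", win, reads)
        out = classify_profile(prof, fold(win))
        assert out.label is ProfileLabel.DEGRADATION

    def test_antisense_transcription_detected(self, rng):
        win = orf_free_window(rng, 300, ClassifierThresholds().orf_min)
        reads = collapse(
            emit_degradation_reads(win, 300, rng)
            + emit_degradation_reads(win, 200, rng, antisense=True)
        )
        prof = build_profile("p", win, reads)
        out = classify_profile(prof, fold(win))
        assert out.label is ProfileLabel.SENSE_ANTISENSE
        assert out.metrics["antisense_fraction"] >= 0.10

    def test_long_orf_excludes_window(self, rng):
        # construct a window carrying an AUG followed by 90 stop-free codons
        body = "".join(
            str(np.random.default_rng(3).choice(["GCU", "GAA", "CUG", "AAA"]))
            for _ in range(90)
        )
        win = random_seq(rng, 15) + "AUG" + body + random_seq(rng, 12)
        reads = collapse(emit_degradation_reads(win, 500, rng))
        prof = build_profile("p", win, reads)
        out = classify_profile(prof, fold(win, max_len=400))
        assert out.label is ProfileLabel.CODING_ORF

    def test_discrimination_rates(self, rng):
        """Planted precursor profiles vs degradation windows are separated
        nearly perfectly at default thresholds."""
        ok_mir = 0
        for _ in range(40):
            d = design_precursor(rng)
            reads = collapse(emit_profile_reads(d, 500, 50, 0.1, rng))
            lab = classify_profile(
                build_profile("p", d.sequence, reads), fold(d.sequence)).label
            ok_mir += lab is ProfileLabel.MIRNA_TWO_PEAK
        ok_deg = 0
        for _ in range(40):
            win = random_seq(rng, 300)
            reads = collapse(emit_degradation_reads(win, 800, rng))
            lab = classify_profile(
                build_profile("d", win, reads), fold(win)).label
            # both labels exclude the window from candidacy
            ok_deg += lab in (ProfileLabel.DEGRADATION, ProfileLabel.CODING_ORF)
        assert ok_mir / 40 >= 0.95
        assert ok_deg / 40 >= 0.95


class TestLongestOrf:
    def test_counts_known_orf(self):
        seq = "CC" + "AUG" + "GCU" * 10 + "UAA" + "CC"
        assert longest_orf_codons(seq) == 11  # AUG + 10 codons before the stop

    def test_detects_reverse_strand_orf(self):
        fwd = "AUG" + "GAA" * 12 + "UAG"
        assert longest_orf_codons(revcomp(fwd)) == 13


class TestConfidence:
    def _classified(self, rng, star):
        d = design_precursor(rng)
        reads = collapse(emit_profile_reads(d, 500, star, 0.1, rng))
        prof = build_profile("p", d.sequence, reads)
        return d, prof, classify_profile(prof, fold(d.sequence))

    def test_two_peak_gets_three_stars_with_star_sequence(self, rng):
        d, prof, pc = self._classified(rng, star=50)
        (cand,) = assign_confidence([("c1", prof, pc)])
        assert cand.confidence == "***"
        assert cand.mature == d.mature
        assert cand.star == d.star
        assert cand.star_abundance is not None

    def test_single_peak_gets_two_stars_no_star(self, rng):
        d, prof, pc = self._classified(rng, star=0)
        (cand,) = assign_confidence([("c1", prof, pc)])
        assert cand.confidence == "**" and cand.star is None

    def test_excluding_labels_produce_no_candidate(self, rng):
        win = orf_free_window(rng, 300, 50)
        reads = collapse(emit_degradation_reads(win, 800, rng))
        prof = build_profile("p", win, reads)
        pc = classify_profile(prof, fold(win))
        assert assign_confidence([("c1", prof, pc)]) == []

    def test_three_stars_require_star(self):
        with pytest.raises(ValueError):
            MiRNACandidate("x", "ACGU" * 5 + "A", 10, "***")


class TestFivePrimeComposition:
    def test_reference_table_u_preference(self):
        """In the bundled candidate table, 20 of 44 mature sequences (45%)
        start with uracil, with adenine second."""
        df = load_table6()
        comp = five_prime_composition(list(df["sequence"]))
        count, pct = comp["U"]
        assert count == 20
        assert pct == pytest.approx(100 * 20 / 44, abs=0.01)
        ranked = list(comp)
        assert ranked[0] == "U" and ranked[1] == "A"

    def test_single_candidate(self):
        comp = five_prime_composition(["UAGGCUAAGCUAGCUAGCUAG"])
        assert comp == {"U": (1, 100.0)}

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            five_prime_composition([])
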