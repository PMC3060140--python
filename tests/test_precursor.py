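"""Folding, window extraction, hairpin suitability, organellar flagging."""

import numpy as np
import pytest

from mirseeker.annotation_filters import (
    MatchPolicy,
    ReferenceCollection,
    ReferenceRecord,
)
from mirseeker.folding import (
    fold,
    hairpin_loops,
    pair_table,
    validate_structure,
)
from mirseeker.precursor import (
    DEFAULT_MAPPING_POLICY,
    GenomicHit,
    PrecursorWindow,
    check_hairpin,
    extract_windows,
    flag_organellar,
    map_reads,
)
from mirseeker.preprocess import CollapsedRead
from mirseeker.simulate import design_precursor, random_seq


class TestFold:
    def test_perfect_stem_loop(self):
        fr = fold("GGGGAAAACCCC")
        assert fr.structure == "((((....))))"
        assert fr.n_pairs == 4

    def test_unpairable_sequence(self):
        fr = fold("AAAAAAA")
        assert fr.structure == "......."
        assert fr.score == 0.0

    def test_deterministic(self, rng):
        seq = random_seq(rng, 150)
        assert fold(seq).structure == fold(seq).structure

    def test_length_limit(self, rng):
        with pytest.raises(ValueError):
            fold(random_seq(rng, 401))

    def test_structures_valid_on_random_sequences(self, rng):
        for _ in range(25):
            fr = fold(random_seq(rng, int(rng.integers(30, 220))))
            validate_structure(fr.structure)  # balanced + min loop

    def test_designed_hairpin_pairs_recovered(self, rng):
        """The folder recovers at least 80% of the designed stem pairs of a
        generated precursor."""
        fracs = []
        for _ in range(15):
            d = design_precursor(rng, mature_len=21, stem_mismatches=2, loop_len=12)
            pt = pair_table(fold(d.sequence).structure)
            designed = d.designed_pairs
            rec = sum(1 for a, b in designed if pt[a] == b)
            fracs.append(rec / len(designed))
        assert min(fracs) >= 0.8

    def test_vienna_plugin_same_contract(self, rng):
        """The thermodynamic plug-in engine returns a balanced structure of
        the right length (independent cross-check of the fold contract)."""
        seq = design_precursor(rng).sequence
        fr = fold(seq, engine="vienna")
        assert len(fr.structure) == len(seq)
        validate_structure(fr.structure)
        assert fr.score < 0  # a designed hairpin is thermodynamically stable


class TestMapReads:
    def _refs(self, rng):
        return ReferenceCollection([
            ReferenceRecord("bar1", random_seq(rng, 500), "barley", "genomic"),
            ReferenceRecord("rice1", random_seq(rng, 500), "rice", "genomic"),
        ])

    def test_exact_hit_in_barley(self, rng):
        refs = self._refs(rng)
        read = CollapsedRead(refs.records[0].sequence[100:121], 10)
        hits = map_reads([read], refs)
        assert any(h.reference_id == "bar1" and h.mismatches == 0 for h in hits)

    def test_rice_tier_mismatch_bounds(self, rng):
        refs = self._refs(rng)
        base = refs.records[1].sequence[200:230]  # 30-mer: 80% rule allows 3
        def sub(seq, k):
            out = list(seq)
            for p in range(k):
                out[3 * p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[out[3 * p]]
            return "".join(out)
        assert map_reads([CollapsedRead(sub(base, 3), 5)], refs)
        assert not map_reads([CollapsedRead(sub(base, 4), 5)], refs)

    def test_score_fraction_is_the_tighter_bound_for_short_reads(self, rng):
        # for a 24-mer, score >= 0.8 * 24 = 19.2 forces <= 2 mismatches
        refs = self._refs(rng)
        base = refs.records[1].sequence[200:224]
        mutated = list(base)
        for p in (2, 10, 18):
            mutated[p] = {"A": "C", "C": "G", "G": "U", "U": "A"}[mutated[p]]
        assert not map_reads([CollapsedRead("".join(mutated), 5)], refs)


class TestExtractWindows:
    def test_flank_grid_counts(self, rng):
        ref = ReferenceRecord("r", random_seq(rng, 2000), "rice", "genomic")
        hit = GenomicHit(ref.sequence[500:521], "r", 500, 521, "+", 0, "rice")
        wins = extract_windows(hit, ref, flank_grid=((0, 150), (150, 0), (75, 75)))
        assert len(wins) == 3
        for w in wins:
            m0, m1 = w.mature_site
            assert w.sequence[m0:m1] == hit.read

    def test_clipping_at_reference_start(self, rng):
        ref = ReferenceRecord("r", random_seq(rng, 400), "rice", "genomic")
        hit = GenomicHit(ref.sequence[10:31], "r", 10, 31, "+", 0, "rice")
        wins = extract_windows(hit, ref, flank_grid=((150, 0),))
        assert wins[0].start == 0

    def test_all_windows_contain_mature_site(self, rng):
        ref = ReferenceRecord("r", random_seq(rng, 1200), "rice", "genomic")
        hit = GenomicHit(ref.sequence[600:621], "r", 600, 621, "+", 0, "rice")
        for w in extract_windows(hit, ref):
            m0, m1 = w.mature_site
            assert 0 <= m0 < m1 <= len(w.sequence)
            assert w.sequence[m0:m1] == hit.read

    def test_minus_strand_window_is_reverse_complemented(self, rng):
        from mirseeker.seq import revcomp

        ref = ReferenceRecord("r", random_seq(rng, 800), "rice", "genomic")
        read = revcomp(ref.sequence[300:321])
        hit = GenomicHit(read, "r", 300, 321, "-", 0, "rice")
        for w in extract_windows(hit, ref):
            m0, m1 = w.mature_site
            assert w.sequence[m0:m1] == read

    def test_hit_outside_reference_raises(self, rng):
        ref = ReferenceRecord("r", random_seq(rng, 100), "rice", "genomic")
        hit = GenomicHit("A" * 21, "r", 90, 111, "+", 0, "rice")
        with pytest.raises(ValueError):
            extract_windows(hit, ref)


class TestCheckHairpin:
    def _window(self, design):
        return PrecursorWindow("x", 0, len(design.sequence), "+",
                               design.sequence, design.mature_site, "rice")

    def test_designed_precursors_pass(self, rng):
        n_pass = 0
        for _ in range(40):
            d = design_precursor(rng)
            if check_hairpin(self._window(d)).passed:
                n_pass += 1
        assert n_pass / 40 >= 0.95

    def test_star_site_on_opposing_arm(self, rng):
        d = design_precursor(rng, stem_mismatches=0)
        cand = check_hairpin(self._window(d))
        assert cand.passed
        s0, s1 = cand.star_site
        m0, m1 = d.mature_site
        assert s0 >= m1  # mature on the 5' arm, star on the 3' arm
        # the star estimate overlaps the designed star interval
        t0, t1 = d.star_site
        assert min(s1, t1) - max(s0, t0) > 15

    def test_mature_in_loop_fails_with_reason(self, rng):
        d = design_precursor(rng, loop_len=30)
        loop_mid = d.mature_site[1] + 12
        win = PrecursorWindow("x", 0, len(d.sequence), "+", d.sequence,
                              (loop_mid - 10, loop_mid + 11), "rice")
        assert check_hairpin(win).verdict == "loop"

    def test_too_many_unpaired_mature_bases_fails(self, rng):
        """A mature arm with 5 unpaired bases exceeds the default threshold
        of 4 (the designed ground-truth structure is used so the count is
        exact; a free fold could rescue mismatches with shifted pairs)."""
        from mirseeker.folding import FoldResult

        d = design_precursor(rng, stem_mismatches=5, mature_len=21)
        fr = FoldResult(d.sequence, d.structure, 0.0)
        cand = check_hairpin(self._window(d), fold_result=fr)
        assert cand.verdict == "unpaired"

    def test_shuffled_windows_rarely_pass(self, rng):
        """Discrimination: windows of identical composition but shuffled
        order pass at most 10% of the time."""
        n_pass = 0
        for _ in range(40):
            d = design_precursor(rng)
            arr = np.array(list(d.sequence))
            rng.shuffle(arr)
            win = PrecursorWindow("x", 0, len(arr), "+", "".join(arr),
                                  d.mature_site, "rice")
            n_pass += check_hairpin(win).passed
        assert n_pass / 40 <= 0.10


class TestOrganellarFlag:
    def test_planted_mature_flagged_not_removed(self, rng):
        d = design_precursor(rng)
        cand = check_hairpin(PrecursorWindow(
            "x", 0, len(d.sequence), "+", d.sequence, d.mature_site, "rice"))
        organellar = ReferenceCollection([ReferenceRecord(
            "chloroplast", random_seq(rng, 200) + d.mature + random_seq(rng, 200),
            "barley", "organellar")])
        out = flag_organellar([cand], organellar)
        assert len(out) == 1 and out[0].organellar and out[0].passed

    def test_no_reference_means_no_flags(self, rng):
        d = design_precursor(rng)
        cand = check_hairpin(PrecursorWindow(
            "x", 0, len(d.sequence), "+", d.sequence, d.mature_site, "rice"))
        assert not flag_organellar([cand], None)[0].organellar

    def test_absent_mature_unflagged(self, rng):
        d = design_precursor(rng)
        cand = check_hairpin(PrecursorWindow(
            "x", 0, len(d.sequence), "+", d.sequence, d.mature_site, "rice"))
        organellar = ReferenceCollection([ReferenceRecord(
            "chloroplast", random_seq(rng, 300), "barley", "organellar")])
        assert not flag_organellar([cand], organellar)[0].organellar
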