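"""Variant network, error-rate formula and fit, abundance culling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseeker.error_model import (
    brute_force_variant_graph,
    build_variant_graph,
    cull_technical_variants,
    enumerate_substitution_variants,
    estimate_error_rate,
    expected_variant_count,
    grid_search_error_rate,
    n_double_substitution_variants,
    n_single_substitution_variants,
    observed_variant_counts,
    per_read_error_rate,
)
from mirseeker.preprocess import CollapsedRead
from mirseeker.simulate import random_seq, simulate_error_population


def cr(seq, n=1):
    return CollapsedRead(seq, n)


class TestVariantEnumeration:
    def test_single_variant_count_21mer(self):
        seq = random_seq(np.random.default_rng(0), 21)
        variants = set(enumerate_substitution_variants(seq, 1))
        assert len(variants) == n_single_substitution_variants(21) == 63
        assert seq not in variants
        assert all(sum(a != b for a, b in zip(v, seq)) == 1 for v in variants)

    @pytest.mark.parametrize("L", [2, 4, 6, 8])
    def test_double_variant_count_matches_formula(self, L):
        seq = random_seq(np.random.default_rng(L), L)
        variants = set(enumerate_substitution_variants(seq, 2))
        assert len(variants) == n_double_substitution_variants(L) == 9 * L * (L - 1) // 2


class TestExpectedVariantCount:
    def test_saturates_at_3l(self):
        assert expected_variant_count(21, 0.0007, 1e9) == pytest.approx(63.0)

    def test_zero_at_zero_abundance(self):
        assert expected_variant_count(21, 0.0007, 0) == 0.0
        assert expected_variant_count(30, 0.5, 0) == 0.0

    def test_abundant_sequences_have_variants(self):
        # around a hundred copies suffices for the first expected variant
        y = expected_variant_count(21, 0.0007, 100)
        assert y == pytest.approx(4.2606, abs=1e-3)
        assert y >= 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_variant_count(0, 0.1, 10)
        with pytest.raises(ValueError):
            expected_variant_count(21, 1.5, 10)
        with pytest.raises(ValueError):
            expected_variant_count(21, 0.1, -1)

    @given(
        L=st.integers(1, 40),
        p=st.floats(1e-6, 0.5),
        x1=st.integers(0, 10**6),
        x2=st.integers(0, 10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, L, p, x1, x2):
        y1 = expected_variant_count(L, p, x1)
        y2 = expected_variant_count(L, p, x2)
        assert 0.0 <= y1 <= 3 * L
        if x1 < x2:
            assert y1 < y2 or y1 == pytest.approx(3 * L)

    def test_per_read_error_rate(self):
        # p ~ 7e-4 at 36 cycles gives ~2.5% of reads with >= 1 error
        assert per_read_error_rate(0.0007, 36) == pytest.approx(0.0249, abs=1e-3)


class TestVariantGraph:
    def test_small_example(self):
        g = build_variant_graph([cr("AAA"), cr("AAC"), cr("ACA"), cr("CCC")])
        assert set(map(frozenset, g.edges)) == {
            frozenset({"AAA", "AAC"}), frozenset({"AAA", "ACA"})}

    def test_full_variant_shell_degree(self):
        parent = random_seq(np.random.default_rng(1), 21)
        reads = [cr(parent, 1000)] + [
            cr(v) for v in enumerate_substitution_variants(parent, 1)]
        g = build_variant_graph(reads)
        assert g.degree[parent] == 63

    def test_single_sequence_no_edges(self):
        g = build_variant_graph([cr("ACGUACGU")])
        assert g.number_of_edges() == 0

    def test_no_edges_between_different_lengths(self):
        g = build_variant_graph([cr("ACGU"), cr("ACG")])
        assert g.number_of_edges() == 0

    def test_agrees_with_brute_force_oracle(self, rng):
        for trial in range(5):
            length = int(rng.integers(4, 8))
            n = 200
            reads = [cr(s, int(rng.integers(1, 100))) for s in
                     {random_seq(rng, length) for _ in range(n)}]
            fast = build_variant_graph(reads)
            slow = brute_force_variant_graph(reads)
            assert set(map(frozenset, fast.edges)) == set(map(frozenset, slow.edges))

    def test_duplicate_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_variant_graph([cr("ACGU"), cr("ACGU")])


class TestErrorRateFit:
    def _graph_on_curve(self, p, rng, length=21):
        """Parents whose observed variant counts sit exactly on the
        expected curve (constructed, noise-free)."""
        reads = []
        xs = [10, 40, 160, 640, 2560, 10240, 40960, 163840]
        for x in xs:
            parent = random_seq(rng, length)
            y = int(round(expected_variant_count(length, p, x)))
            reads.append(cr(parent, x))
            for v in list(enumerate_substitution_variants(parent, 1))[:y]:
                reads.append(cr(v, 1))
        # dedupe collisions between shells (vanishingly rare but possible)
        seen, unique = set(), []
        for r in reads:
            if r.sequence not in seen:
                seen.add(r.sequence)
                unique.append(r)
        return build_variant_graph(unique)

    def test_exact_recovery_on_noise_free_data(self, rng):
        g = self._graph_on_curve(0.001, rng)
        fit = estimate_error_rate(g, 21)
        assert fit.p == pytest.approx(0.001, abs=5e-5)

    def test_parameter_recovery_from_simulation(self):
        rng = np.random.default_rng(7)
        reads, truth = simulate_error_population(150, 21, (10, 1e6), 0.0007, rng)
        g = build_variant_graph(reads)
        fit = estimate_error_rate(g, 21)
        assert 0.7 * 0.0007 <= fit.p <= 1.3 * 0.0007

    def test_grid_search_oracle_agrees(self):
        rng = np.random.default_rng(8)
        reads, _ = simulate_error_population(120, 21, (10, 1e6), 0.0007, rng)
        g = build_variant_graph(reads)
        fit = estimate_error_rate(g, 21)
        grid = grid_search_error_rate(g, 21)
        assert abs(fit.p - grid) / fit.p < 0.05

    def test_no_variants_reports_lower_bound_with_warning(self, rng):
        reads = [cr(random_seq(rng, 21), x) for x in (10, 1000, 100000)]
        g = build_variant_graph(reads)
        with pytest.warns(RuntimeWarning):
            fit = estimate_error_rate(g, 21)
        assert fit.at_bound
        assert fit.p == pytest.approx(1e-5)

    def test_insufficient_dynamic_range_raises(self, rng):
        reads = [cr(random_seq(rng, 21), x) for x in (50, 60, 70, 80)]
        g = build_variant_graph(reads)
        with pytest.raises(ValueError, match="dynamic range"):
            estimate_error_rate(g, 21)


class TestCulling:
    def test_variant_below_both_thresholds_culled(self):
        parent = "UACGACGACGACGACGACGAC"
        reads = [cr(parent, 10000), cr("A" + parent[1:], 11)]
        g = build_variant_graph(reads)
        kept, culled = cull_technical_variants(reads, g)
        assert {r.sequence for r in kept} == {parent}
        assert culled[0].reason == "low_abundance"

    def test_abundant_family_member_kept(self):
        parent = "UACGACGACGACGACGACGAC"
        member = "A" + parent[1:]
        reads = [cr(parent, 10000), cr(member, 5000)]
        g = build_variant_graph(reads)
        kept, _ = cull_technical_variants(reads, g)
        assert {r.sequence for r in kept} == {parent, member}

    def test_ratio_rule_culls_mid_abundance_variant(self):
        parent = "UACGACGACGACGACGACGAC"
        variant = "A" + parent[1:]
        reads = [cr(parent, 100000), cr(variant, 50)]  # 50 < 0.0012 * 100000
        g = build_variant_graph(reads)
        kept, culled = cull_technical_variants(reads, g)
        assert {r.sequence for r in kept} == {parent}
        assert culled[0].reason == "variant_of_parent"
        assert culled[0].parent == parent

    def test_isolated_read_at_threshold_kept(self):
        reads = [cr("UACGACGACGACGACGACGAC", 12)]
        g = build_variant_graph(reads)
        kept, culled = cull_technical_variants(reads, g)
        assert len(kept) == 1 and not culled

    def test_equal_abundance_neighbours_not_culled(self):
        parent = "UACGACGACGACGACGACGAC"
        reads = [cr(parent, 500), cr("A" + parent[1:], 500)]
        g = build_variant_graph(reads)
        kept, _ = cull_technical_variants(reads, g)
        assert len(kept) == 2

    def test_partition(self, rng):
        reads, _ = simulate_error_population(30, 21, (10, 1e5), 0.0007, rng)
        g = build_variant_graph(reads)
        kept, culled = cull_technical_variants(reads, g)
        assert len(kept) + len(culled) == len(reads)
        assert not ({r.sequence for r in kept}
                    & {c.read.sequence for c in culled})

    def test_simulation_cull_rates(self):
        """Parents at >= 1000 copies: nearly all error variants culled,
        every parent retained."""
        rng = np.random.default_rng(9)
        reads, truth = simulate_error_population(100, 21, (1000, 1e6), 0.0007, rng)
        g = build_variant_graph(reads)
        kept, _ = cull_technical_variants(reads, g)
        kept_seqs = {r.sequence for r in kept}
        variants = [s for s, l in truth.labels.items() if l == "technical_variant"]
        culled_frac = sum(1 for v in variants if v not in kept_seqs) / len(variants)
        assert culled_frac >= 0.99
        assert all(p in kept_seqs for p in truth.parents)

    def test_most_abundant_sequence_always_kept(self, rng):
        reads, _ = simulate_error_population(50, 21, (100, 1e6), 0.0007, rng)
        g = build_variant_graph(reads)
        kept, _ = cull_technical_variants(reads, g)
        top = max(reads, key=lambda r: r.abundance_total)
        assert top.sequence in {r.sequence for r in kept}
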