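"""Abundance-aware sequencing-error model and technical-variant culling.

Deep small-RNA datasets contain, for every abundant 'parent' sequence, a
cloud of low-abundance sequences differing by one or a few bases. With a
per-base substitution probability p, independent of base and position, the
expected number of *distinct* single-substitution variants of a parent of
length L observed X times is

    Y = 3 L [1 - (1 - p)^X]

which saturates at 3L (all possible single-base substitutions present). The
variant network over unique sequences (edges between equal-length sequences
at Hamming distance 1) makes both the fit of p and the relative-abundance
culling rule operational without any reference genome or quality scores.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar

from .preprocess import CollapsedRead
from .seq import CANONICAL_BASES

ABUNDANCE = "abundance"


def n_single_substitution_variants(length: int) -> int:
    """Number of possible 1-SNP (single-substitution) variants of an L-mer."""
    return 3 * length


def n_double_substitution_variants(length: int) -> int:
    """Number of possible 2-SNP variants of an L-mer: 9 L (L - 1) / 2."""
    return 9 * length * (length - 1) // 2


def enumerate_substitution_variants(sequence: str, n_subs: int = 1):
    """Yield every distinct sequence differing from ``sequence`` by exactly
    ``n_subs`` substitutions (exhaustive; intended for small inputs)."""
    L = len(sequence)
    for positions in itertools.combinations(range(L), n_subs):
        alt_sets = [
            [b for b in CANONICAL_BASES if b != sequence[i]] for i in positions
        ]
        for replacement in itertools.product(*alt_sets):
            variant = list(sequence)
            for pos, base in zip(positions, replacement):
                variant[pos] = base
            yield "".join(variant)


def expected_variant_count(L: int, p: float, X):
    """Expected number of distinct 1-SNP variants of a parent sequence.

    Parameters
    ----------
    L : read length (nt), >= 1
    p : per-base substitution probability, in [0, 1]
    X : parent abundance (copies sequenced), >= 0; scalar or array
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if np.any(np.asarray(X) < 0):
        raise ValueError("X must be >= 0")
    result = 3.0 * L * (1.0 - (1.0 - p) ** np.asarray(X, dtype=float))
    return result if np.ndim(X) else float(result)


def per_read_error_rate(p: float, L: int) -> float:
    """Probability that a read of length L contains at least one error."""
    return 1.0 - (1.0 - p) ** L


def build_variant_graph(reads: list[CollapsedRead]) -> nx.Graph:
    """Build the 1-SNP variant network over a collapsed read set.

    Nodes are unique sequences (with an ``abundance`` attribute); an edge
    joins two equal-length sequences at Hamming distance exactly 1. Edges are
    found by wildcard-key indexing: two sequences are Hamming-1 neighbours
    iff they share a key with one position masked, so the build is
    O(N * L) rather than all-pairs.
    """
    graph = nx.Graph()
    for read in reads:
        if graph.has_node(read.sequence):
            raise ValueError(f"duplicate sequence in collapsed set: {read.sequence}")
        graph.add_node(read.sequence, **{ABUNDANCE: read.abundance_total})
    buckets: dict[tuple[int, int, str], list[str]] = defaultdict(list)
    for read in reads:
        seq = read.sequence
        L = len(seq)
        for i in range(L):
            buckets[(L, i, seq[:i] + seq[i + 1 :])].append(seq)
    for members in buckets.values():
        if len(members) > 1:
            members.sort()
            graph.add_edges_from(itertools.combinations(members, 2))
    return graph


def brute_force_variant_graph(reads: list[CollapsedRead]) -> nx.Graph:
    """All-pairs Hamming oracle for :func:`build_variant_graph`."""
    graph = nx.Graph()
    for read in reads:
        graph.add_node(read.sequence, **{ABUNDANCE: read.abundance_total})
    for a, b in itertools.combinations(reads, 2):
        if len(a.sequence) == len(b.sequence):
            mm = sum(x != y for x, y in zip(a.sequence, b.sequence))
            if mm == 1:
                graph.add_edge(a.sequence, b.sequence)
    return graph


def observed_variant_counts(graph: nx.Graph, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (abundance, distinct-variant-count) pairs for length-L nodes.

    A node's variants are its strictly less abundant Hamming-1 neighbours:
    variants are the low-abundance accompaniment of a parent, and counting
    only downward edges keeps a variant's own count near zero, consistent
    with the Y(L, p, X) curve at small X.
    """
    xs, ys = [], []
    for node, data in graph.nodes(data=True):
        if len(node) != L:
            continue
        x = data[ABUNDANCE]
        y = sum(
            1 for nb in graph.neighbors(node) if graph.nodes[nb][ABUNDANCE] < x
        )
        xs.append(x)
        ys.append(y)
    order = np.argsort(xs, kind="stable")
    return np.asarray(xs, dtype=float)[order], np.asarray(ys, dtype=float)[order]


@dataclass
class ErrorModelFit:
    p: float
    L: int
    residual: float
    n_points: int
    bin_abundance: np.ndarray
    bin_variant_count: np.ndarray
    at_bound: bool = False

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("fitted p must be in (0, 1)")
        if self.n_points < 3:
            raise ValueError("fit requires at least 3 points")


def _log_bin(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-node counts in log2 abundance bins.

    Returns (geometric-mean abundance, mean variant count) per occupied bin.
    """
    bins = np.floor(np.log2(xs)).astype(int)
    bx, by = [], []
    for b in np.unique(bins):
        sel = bins == b
        bx.append(float(np.exp(np.mean(np.log(xs[sel])))))
        by.append(float(np.mean(ys[sel])))
    return np.asarray(bx), np.asarray(by)


def _sse(log10_p: float, L: int, bx: np.ndarray, by: np.ndarray) -> float:
    pred = expected_variant_count(L, 10.0 ** log10_p, bx)
    return float(np.sum((by - pred) ** 2))


def estimate_error_rate(
    graph: nx.Graph,
    L: int = 21,
    p_bounds: tuple[float, float] = (1e-5, 1e-2),
    binned: bool = True,
) -> ErrorModelFit:
    """Fit the per-base substitution probability p to the variant network.

    Least squares between observed distinct-variant counts of length-L nodes
    (aggregated in log2 abundance bins by default) and the expected curve
    Y = 3L[1-(1-p)^X]. Requires nodes spanning at least two decades of
    abundance; with no variants at all the fit degenerates to the lower
    bound and a warning is emitted.
    """
    xs, ys = observed_variant_counts(graph, L)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 nodes of length {L} to fit, have {len(xs)}")
    if xs.max() < 100.0 * max(xs.min(), 1.0):
        raise ValueError(
            "insufficient abundance dynamic range for the error-rate fit "
            f"(spans {xs.min():.0f}..{xs.max():.0f}); supply more data covering "
            ">= 2 decades of abundance"
        )
    bx, by = _log_bin(xs, ys) if binned else (xs, ys)
    if np.all(by == 0):
        warnings.warn(
            "no sequence variants observed; error rate at lower bound",
            RuntimeWarning,
        )
        return ErrorModelFit(
            p=p_bounds[0], L=L, residual=0.0, n_points=len(xs),
            bin_abundance=bx, bin_variant_count=by, at_bound=True,
        )
    lo, hi = np.log10(p_bounds[0]), np.log10(p_bounds[1])
    res = minimize_scalar(
        _sse, bounds=(lo, hi), args=(L, bx, by), method="bounded",
        options={"xatol": 1e-7},
    )
    p_hat = float(10.0 ** res.x)
    at_bound = p_hat <= p_bounds[0] * 1.001 or p_hat >= p_bounds[1] * 0.999
    if at_bound:
        warnings.warn("fitted error rate lies at a bound of the search interval",
                      RuntimeWarning)
    return ErrorModelFit(
        p=p_hat, L=L, residual=float(res.fun), n_points=len(xs),
        bin_abundance=bx, bin_variant_count=by, at_bound=at_bound,
    )


def grid_search_error_rate(
    graph: nx.Graph,
    L: int = 21,
    p_bounds: tuple[float, float] = (1e-5, 1e-2),
    n_grid: int = 600,
    binned: bool = True,
) -> float:
    """Independent grid-search estimate of p over a log-spaced grid
    (oracle for :func:`estimate_error_rate`)."""
    xs, ys = observed_variant_counts(graph, L)
    bx, by = _log_bin(xs, ys) if binned else (xs, ys)
    grid = np.logspace(np.log10(p_bounds[0]), np.log10(p_bounds[1]), n_grid)
    sse = [_sse(np.log10(p), L, bx, by) for p in grid]
    return float(grid[int(np.argmin(sse))])


@dataclass(frozen=True)
class CullDecision:
    read: CollapsedRead
    reason: str            # 'low_abundance' | 'variant_of_parent'
    parent: str | None = None


def cull_technical_variants(
    reads: list[CollapsedRead],
    graph: nx.Graph,
    ratio: float = 0.0012,
    min_abundance: int = 12,
) -> tuple[list[CollapsedRead], list[CullDecision]]:
    """Remove likely technical sequence variants by relative abundance.

    A read is culled iff its abundance is below ``min_abundance`` (default
    12: 'less than 12' copies), or it has a strictly more abundant
    Hamming-1 neighbour and its abundance is below ``ratio`` (default
    0.12%) of the most abundant such neighbour. Decisions are made against
    the original abundances in a single pass; reads with abundance equal to
    their best neighbour are never culled by the ratio rule.
    """
    kept, culled = [], []
    for read in reads:
        x = read.abundance_total
        if x < min_abundance:
            culled.append(CullDecision(read, "low_abundance"))
            continue
        best_parent = None
        best_abundance = x
        for nb in graph.neighbors(read.sequence):
            nx_ab = graph.nodes[nb][ABUNDANCE]
            if nx_ab > best_abundance:
                best_abundance = nx_ab
                best_parent = nb
        if best_parent is not None and x < ratio * best_abundance:
            culled.append(CullDecision(read, "variant_of_parent", best_parent))
        else:
            kept.append(read)
    return kept, culled
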