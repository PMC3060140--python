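"""Read clustering, locus merging, family assignment and representative
selection.

Reads that pass the hairpin screen are grouped transitively: two reads join
the same cluster when their Smith-Waterman similarity exceeds a fraction of
its maximum attainable value, and clusters sharing overlapping or adjacent
genomic windows are merged. Mature sequences are further grouped into
miRNA families by transitive Levenshtein distance.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import edlib
import networkx as nx
import numpy as np
from numba import njit

from .precursor import PrecursorCandidate
from .preprocess import CollapsedRead


@njit(cache=True)
def _sw_kernel(a, b, match, mismatch, gap):
    n, m = a.shape[0], b.shape[0]
    prev = np.zeros(m + 1, dtype=np.float64)
    cur = np.zeros(m + 1, dtype=np.float64)
    best = 0.0
    for i in range(1, n + 1):
        cur[0] = 0.0
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if cur[j - 1] + gap > v:
                v = cur[j - 1] + gap
            if v < 0.0:
                v = 0.0
            cur[j] = v
            if v > best:
                best = v
        prev, cur = cur, prev
    return best


def sw_score(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
             gap: float = -2.0) -> float:
    """Smith-Waterman local alignment score (linear gap penalty)."""
    if not a or not b:
        raise ValueError("Smith-Waterman requires non-empty sequences")
    from .seq import encode

    return float(_sw_kernel(encode(a), encode(b), match, mismatch, gap))


def sw_similarity(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                  gap: float = -2.0) -> float:
    """SW score divided by its maximum attainable value for the pair.

    The maximum attainable score is that of the shorter sequence aligned
    perfectly: ``min(len(a), len(b)) * match``. Symmetric in its arguments.
    """
    return sw_score(a, b, match, mismatch, gap) / (min(len(a), len(b)) * match)


def sw_score_oracle(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                    gap: float = -2.0) -> float:
    """Plain-python DP oracle for :func:`sw_score`."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + gap,
                          H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


def levenshtein(a: str, b: str) -> int:
    """Edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


def levenshtein_oracle(a: str, b: str) -> int:
    """Quadratic DP oracle for :func:`levenshtein`."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def transitive_cluster(
    items: Sequence[Hashable],
    pairwise_predicate: Callable[[Hashable, Hashable], bool],
) -> list[list]:
    """Partition items into connected components of the predicate graph.

    The predicate must be symmetric. Items are canonically sorted before
    component construction so the partition is invariant under input order;
    components are returned sorted by their smallest member.
    """
    ordered = sorted(set(items), key=str)
    graph = nx.Graph()
    graph.add_nodes_from(ordered)
    for a, b in itertools.combinations(ordered, 2):
        if pairwise_predicate(a, b):
            graph.add_edge(a, b)
    comps = [sorted(c, key=str) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: str(c[0]))
    return comps


def transitive_cluster_oracle(items, pairwise_predicate):
    """Brute-force BFS components (oracle for :func:`transitive_cluster`)."""
    ordered = sorted(set(items), key=str)
    unvisited = set(ordered)
    comps = []
    while unvisited:
        seed = min(unvisited, key=str)
        comp, frontier = {seed}, [seed]
        unvisited.discard(seed)
        while frontier:
            cur = frontier.pop()
            for other in list(unvisited):
                if pairwise_predicate(cur, other):
                    unvisited.discard(other)
                    comp.add(other)
                    frontier.append(other)
        comps.append(sorted(comp, key=str))
    comps.sort(key=lambda c: str(c[0]))
    return comps


@dataclass
class ReadCluster:
    """A transitive cluster of reads with their acceptable precursors."""

    members: list[CollapsedRead]
    precursors: list[PrecursorCandidate] = field(default_factory=list)

    @property
    def representative(self) -> CollapsedRead:
        return select_representative(self.members)

    @property
    def total_abundance(self) -> int:
        return sum(r.abundance_total for r in self.members)


def cluster_reads(
    reads: list[CollapsedRead],
    precursors_by_read: dict[str, list[PrecursorCandidate]],
    threshold: float = 0.6,
) -> list[ReadCluster]:
    """Transitively cluster reads whose SW similarity exceeds ``threshold``."""
    by_seq = {r.sequence: r for r in reads}
    comps = transitive_cluster(
        list(by_seq), lambda a, b: sw_similarity(a, b) > threshold
    )
    clusters = []
    for comp in comps:
        members = [by_seq[s] for s in comp]
        precursors = [p for s in comp for p in precursors_by_read.get(s, [])]
        clusters.append(ReadCluster(members, precursors))
    return clusters


def _cluster_loci(cluster: ReadCluster) -> list[tuple[str, str, int, int]]:
    return [
        (p.window.reference_id, p.window.strand, p.window.start, p.window.end)
        for p in cluster.precursors
    ]


def merge_by_locus(clusters: list[ReadCluster], merge_gap: int = 0) -> list[ReadCluster]:
    """Merge clusters whose precursor windows on the same reference and
    strand overlap or lie within ``merge_gap`` of each other (0 = abutting
    windows still merge)."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    loci = [_cluster_loci(c) for c in clusters]
    for i, j in itertools.combinations(range(len(clusters)), 2):
        linked = any(
            ri == rj and si == sj and ai < bj + merge_gap + 1 and aj < bi + merge_gap + 1
            for (ri, si, ai, bi) in loci[i]
            for (rj, sj, aj, bj) in loci[j]
        )
        if linked:
            graph.add_edge(i, j)
    merged = []
    for comp in sorted(nx.connected_components(graph), key=min):
        members, precursors, seen = [], [], set()
        for idx in sorted(comp):
            for r in clusters[idx].members:
                if r.sequence not in seen:
                    seen.add(r.sequence)
                    members.append(r)
            precursors.extend(clusters[idx].precursors)
        members.sort(key=lambda r: (-r.abundance_total, r.sequence))
        merged.append(ReadCluster(members, precursors))
    return merged


@dataclass
class FamilyAssignment:
    family_id: str
    members: list[str]


def assign_families(
    matures: dict[str, int] | Iterable[tuple[str, int]],
    known_catalog: dict[str, str] | None = None,
    max_dist: int = 3,
    min_reads: int = 4,
) -> list[FamilyAssignment]:
    """Group mature sequences into miRNA families.

    ``matures`` maps sequence -> abundance; only sequences with abundance
    >= ``min_reads`` (i.e. represented by more than ``min_reads``-1 reads)
    participate. Families are connected components under pairwise
    Levenshtein distance <= ``max_dist``. When a ``known_catalog``
    (family name -> mature sequence) is supplied its sequences join the
    clustering and a family containing a catalog member inherits its name;
    otherwise families get stable positional ids.
    """
    if not isinstance(matures, dict):
        matures = dict(matures)
    eligible = sorted(s for s, a in matures.items() if a >= min_reads)
    catalog = dict(known_catalog or {})
    catalog_by_seq: dict[str, list[str]] = defaultdict(list)
    for name, seq in catalog.items():
        catalog_by_seq[seq].append(name)
    pool = sorted(set(eligible) | set(catalog_by_seq))
    comps = transitive_cluster(pool, lambda a, b: levenshtein(a, b) <= max_dist)
    families = []
    counter = itertools.count(1)
    for comp in comps:
        members = [s for s in comp if s in matures and s in set(eligible)]
        if not members:
            continue  # catalog-only component
        names = sorted(n for s in comp for n in catalog_by_seq.get(s, []))
        family_id = names[0] if names else f"FAM{next(counter):04d}"
        families.append(FamilyAssignment(family_id, members))
    return families


def select_representative(group: Sequence[CollapsedRead]) -> CollapsedRead:
    """The maximal-abundance member; ties broken by lexicographically
    smaller sequence (stable across runs)."""
    if not group:
        raise ValueError("cannot select a representative from an empty group")
    return min(group, key=lambda r: (-r.abundance_total, r.sequence))


def group_site_variants(
    members: Sequence[CollapsedRead],
    site_of: dict[str, tuple[str, int, int]],
    min_overlap_slack: int = 2,
) -> list[list[CollapsedRead]]:
    """Group length variants and one-base 'wobbles' that map to the same
    precursor site: reads on the same reference whose mature intervals
    overlap by at least (length - slack) nt."""
    graph = nx.Graph()
    seqs = sorted(r.sequence for r in members if r.sequence in site_of)
    graph.add_nodes_from(seqs)
    for a, b in itertools.combinations(seqs, 2):
        ra, sa0, sa1 = site_of[a]
        rb, sb0, sb1 = site_of[b]
        if ra != rb:
            continue
        overlap = min(sa1, sb1) - max(sa0, sb0)
        need = min(sa1 - sa0, sb1 - sb0) - min_overlap_slack
        if overlap >= need:
            graph.add_edge(a, b)
    by_seq = {r.sequence: r for r in members}
    groups = []
    for comp in sorted(nx.connected_components(graph), key=min):
        groups.append([by_seq[s] for s in sorted(comp)])
    return groups
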