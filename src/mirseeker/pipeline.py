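"""End-to-end orchestration of the discovery pipeline.

Stages: preprocess -> sequencing-error culling -> contaminant/repeat
filtering -> cross-species precursor discovery -> transitive read
clustering with locus merging -> read-depth profile classification and
confidence assignment. Every stage records reads-in/reads-out in a run
manifest; re-running with the same inputs and configuration reproduces the
candidate table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .annotation_filters import (
    MatchPolicy,
    ReferenceCollection,
    filter_contaminants,
    filter_repeats,
)
from .clustering import (
    ReadCluster,
    assign_families,
    cluster_reads,
    merge_by_locus,
    select_representative,
)
from .error_model import (
    build_variant_graph,
    cull_technical_variants,
    estimate_error_rate,
)
from .folding import fold
from .precursor import (
    DEFAULT_FLANK_GRID,
    DEFAULT_MAPPING_POLICY,
    HairpinCriteria,
    PrecursorCandidate,
    check_hairpin,
    extract_windows,
    flag_organellar,
    map_reads,
)
from .preprocess import AdapterSpec, CollapsedRead, Reject, preprocess
from .profiles import (
    ClassifierThresholds,
    MiRNACandidate,
    assign_confidence,
    build_profile,
    classify_profile,
)


@dataclass
class PipelineConfig:
    adapters: AdapterSpec = field(default_factory=AdapterSpec)
    min_len: int = 18
    max_len: int = 35
    max_homopolymer: int = 6
    cull_ratio: float = 0.0012
    min_abundance: int = 12
    fit_length: int = 21
    fit_error_rate: bool = True
    contaminant_policy: MatchPolicy = field(default_factory=MatchPolicy)
    repeat_filter: bool = True
    mapping_policy: MatchPolicy = DEFAULT_MAPPING_POLICY
    flank_grid: tuple[tuple[int, int], ...] = DEFAULT_FLANK_GRID
    max_window: int = 300
    hairpin_criteria: HairpinCriteria = field(default_factory=HairpinCriteria)
    sw_threshold: float = 0.6
    merge_gap: int = 0
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    profile_max_mismatches: int = 3
    max_hits_per_read: int = 20

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    candidates: list[MiRNACandidate]
    clusters: list[ReadCluster]
    manifest: dict
    collapsed: list[CollapsedRead]
    kept_reads: list[CollapsedRead]
    rejects: list[Reject]

    def candidate_table(self) -> pd.DataFrame:
        """Final candidate table in the standard layout (name, sequence,
        length, abundance, star fields, confidence, family)."""
        rows = [
            {
                "read_name": c.name,
                "sequence": c.mature,
                "length": len(c.mature),
                "abundance": c.mature_abundance,
                "star_sequence": c.star or "",
                "star_length": len(c.star) if c.star else pd.NA,
                "star_abundance": c.star_abundance if c.star else pd.NA,
                "confidence": c.confidence,
                "family": c.family_id or "",
                "precursors": ";".join(c.precursor_ids),
                "organellar": c.organellar,
                "repeat_flagged": c.repeat_flagged,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "read_name", "sequence", "length", "abundance", "star_sequence",
                "star_length", "star_abundance", "confidence", "family",
                "precursors", "organellar", "repeat_flagged",
            ],
        )


def _best_precursor(cluster: ReadCluster) -> PrecursorCandidate | None:
    passing = [p for p in cluster.precursors if p.passed]
    if not passing:
        return None
    # fewest hit mismatches first (a hairpin's reverse complement is also a
    # hairpin, so the read's better-matching orientation decides the strand),
    # then the most stable fold; deterministic tie-break on locus
    passing.sort(
        key=lambda p: (p.window.mismatches, p.fold.score,
                       p.window.reference_id, p.window.start, p.window.strand)
    )
    return passing[0]


def run_pipeline(
    raw_reads,
    genomic: ReferenceCollection,
    contaminants: ReferenceCollection | None = None,
    repeats: ReferenceCollection | None = None,
    organellar: ReferenceCollection | None = None,
    config: PipelineConfig | None = None,
    known_catalog: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline on a read stream.

    ``raw_reads`` is an iterable of ``RawRead`` or ``(sequence, count,
    library)`` tuples (adapter-flanked fixed-cycle reads). Returns the
    candidate list plus a manifest of per-stage counts and the thresholds
    used.
    """
    config = config or PipelineConfig()
    manifest: dict = {"version": __version__, "config": config.snapshot(), "stages": {}}

    def stage(name, n_in, n_out, **extra):
        manifest["stages"][name] = {"in": int(n_in), "out": int(n_out), **extra}

    # 1. preprocess
    rejects: list[Reject] = []
    collapsed = preprocess(
        raw_reads, config.adapters, config.min_len, config.max_len,
        config.max_homopolymer, rejects,
    )
    total_in = sum(r.abundance_total for r in collapsed) + sum(r.count for r in rejects)
    stage("preprocess", total_in, sum(r.abundance_total for r in collapsed),
          unique=len(collapsed), rejected=sum(r.count for r in rejects))

    # 2. error model: variant network, optional fit, abundance culling
    graph = build_variant_graph(collapsed)
    fit_info = None
    if config.fit_error_rate:
        try:
            fit = estimate_error_rate(graph, config.fit_length)
            fit_info = {"p": fit.p, "residual": fit.residual, "n_points": fit.n_points}
        except ValueError:
            fit_info = None
    kept, culled = cull_technical_variants(
        collapsed, graph, config.cull_ratio, config.min_abundance
    )
    stage("error_model", len(collapsed), len(kept), culled=len(culled), fit=fit_info)

    # 3. contaminant and repeat filtering
    if contaminants is not None and len(contaminants):
        kept, removed_contaminants = filter_contaminants(
            kept, contaminants, config.contaminant_policy
        )
    else:
        removed_contaminants = []
    repeat_flagged: set[str] = set()
    if repeats is not None and len(repeats):
        kept, removed_repeats, flagged = filter_repeats(
            kept, repeats, config.contaminant_policy, enabled=config.repeat_filter
        )
        repeat_flagged = {r.sequence for r, _ in flagged}
    else:
        removed_repeats = []
    stage("annotation_filters",
          len(kept) + len(removed_contaminants) + len(removed_repeats), len(kept),
          contaminants=len(removed_contaminants), repeats=len(removed_repeats),
          repeat_flagged=len(repeat_flagged))

    # 4. precursor discovery
    hits = map_reads(kept, genomic, config.mapping_policy, config.max_hits_per_read)
    ref_by_id = {rec.id: rec for rec in genomic}
    fold_cache: dict[str, object] = {}
    precursors_by_read: dict[str, list[PrecursorCandidate]] = {}
    n_pass = 0
    for hit in hits:
        for window in extract_windows(
            hit, ref_by_id[hit.reference_id], config.flank_grid, config.max_window
        ):
            if window.sequence not in fold_cache:
                fold_cache[window.sequence] = fold(
                    window.sequence, max_len=max(config.max_window, 400)
                )
            cand = check_hairpin(
                window, fold_cache[window.sequence], config.hairpin_criteria
            )
            if cand.passed:
                n_pass += 1
            precursors_by_read.setdefault(hit.read, []).append(cand)
    flagged_reads = sorted(
        s for s, cands in precursors_by_read.items() if any(c.passed for c in cands)
    )
    stage("precursor_discovery", len(kept), len(flagged_reads),
          hits=len(hits), windows_passing=n_pass)

    # 5. clustering and locus merging
    flagged_collapsed = [r for r in kept if r.sequence in set(flagged_reads)]
    passing_by_read = {
        s: [c for c in cands if c.passed]
        for s, cands in precursors_by_read.items()
        if any(c.passed for c in cands)
    }
    clusters = cluster_reads(flagged_collapsed, passing_by_read, config.sw_threshold)
    n_before_merge = len(clusters)
    clusters = merge_by_locus(clusters, config.merge_gap)
    stage("clustering", n_before_merge, len(clusters))

    # 6. profiles, classification, confidence
    classified = []
    profile_info = []
    for idx, cluster in enumerate(clusters):
        best = _best_precursor(cluster)
        if best is None:
            continue
        if organellar is not None:
            best = flag_organellar([best], organellar)[0]
        pid = (f"{best.window.reference_id}:{best.window.start}-"
               f"{best.window.end}({best.window.strand})")
        profile = build_profile(
            pid, best.window.sequence, collapsed, config.profile_max_mismatches
        )
        pclass = classify_profile(profile, best.fold, config.classifier)
        rep = select_representative(cluster.members)
        name = f"CAND{idx + 1:04d}"
        classified.append((name, profile, pclass))
        profile_info.append((name, cluster, best, pclass))
    candidates = assign_confidence(classified)

    info_by_name = {name: (cluster, best) for name, cluster, best, _ in profile_info}
    for cand in candidates:
        cluster, best = info_by_name[cand.name]
        cand.organellar = best.organellar
        cand.repeat_flagged = any(
            r.sequence in repeat_flagged for r in cluster.members
        ) or cand.mature in repeat_flagged

    # families over the candidate matures
    fams = assign_families(
        {c.mature: c.mature_abundance for c in candidates}, known_catalog
    )
    fam_of = {m: f.family_id for f in fams for m in f.members}
    for cand in candidates:
        cand.family_id = fam_of.get(cand.mature)

    candidates.sort(key=lambda c: (-c.mature_abundance, c.mature))
    stage("profile_classification", len(clusters), len(candidates))
    manifest["counts_ok"] = True
    return PipelineResult(candidates, clusters, manifest, collapsed, kept, rejects)
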