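"""Synthetic small-RNA data with the statistical structure the pipeline
assumes, so every stage and the end-to-end analysis are testable without
external downloads.

The generator emulates: a heavy-tailed (log-uniform) abundance distribution
of parent sequences; independent per-base substitution errors at rate p
(uniform over the three alternative bases, independent of position — the
same simplifying assumptions the abundance-culling model makes); hairpin
precursors emitting sharply localized mature/star reads with a silent loop;
uniform mRNA-degradation read profiles with optional antisense emission;
contaminant reads copied from labelled reference decoys; and adapter-flanked
fixed-cycle reads. Every emitted unique sequence carries exactly one
ground-truth provenance label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation_filters import ReferenceCollection, ReferenceRecord
from .preprocess import AdapterSpec, CollapsedRead, RawRead
from .seq import CANONICAL_BASES, revcomp

_BASES = np.frombuffer("ACGU".encode(), dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(rng.choice(_BASES, size=length)).decode()


def log_uniform_int(rng: np.random.Generator, lo: float, hi: float, size=None):
    """Integer abundances drawn log-uniformly over [lo, hi] (heavy-tailed,
    spanning several decades like real small-RNA libraries)."""
    u = rng.uniform(math.log(lo), math.log(hi), size=size)
    return np.maximum(1, np.round(np.exp(u))).astype(int)


# ---------------------------------------------------------------------------
# sequencing-error population


@dataclass
class GroundTruth:
    """Per-sequence provenance labels for a simulated dataset."""

    labels: dict[str, str] = field(default_factory=dict)   # sequence -> label
    parents: dict[str, int] = field(default_factory=dict)  # parent -> abundance
    true_p: float | None = None
    designs: list["PrecursorDesign"] = field(default_factory=list)

    def label(self, sequence: str) -> str:
        return self.labels.get(sequence, "unknown")


def simulate_error_population(
    n_parents: int,
    length: int = 21,
    abundance_range: tuple[float, float] = (10, 1e6),
    p_error: float = 0.0007,
    rng: np.random.Generator | None = None,
    library: str = "lib1",
) -> tuple[list[CollapsedRead], GroundTruth]:
    """Parents plus their technical sequence variants under the multinomial
    error model.

    ``p_error`` is the probability, per sequenced copy and per base, of any
    *specific* substitution N -> N' (so the total per-base error rate is
    3 * p_error). Copies are allocated exactly: the number of copies with
    0/1/2 errors is Binomial in the per-copy class probabilities, 1-error
    copies are spread multinomially over the 3L possible 1-SNP variants and
    2-error copies over random base pairs. Under this model each specific
    variant is absent from all X copies with probability ~(1-p)^X, so the
    expected number of *distinct* 1-SNP variants follows 3L[1-(1-p)^X].
    Returns collapsed unique sequences (per-copy read objects would be
    pointless at abundances of 10^6; see :func:`as_raw_reads` for
    small-scale expansion).
    """
    rng = rng or np.random.default_rng(0)
    if not (0 <= p_error < 0.1):
        raise ValueError("p_error must be in [0, 0.1)")
    truth = GroundTruth(true_p=p_error)
    counts: dict[str, int] = {}

    parents = set()
    while len(parents) < n_parents:
        parents.add(random_seq(rng, length))
    abundances = log_uniform_int(rng, *abundance_range, size=n_parents)

    q = 3.0 * p_error  # per-base error rate
    L = length
    p1 = L * q * (1 - q) ** (L - 1)
    p2 = (L * (L - 1) / 2) * q * q * (1 - q) ** (L - 2)

    for parent, X in zip(sorted(parents), abundances):
        X = int(X)
        truth.parents[parent] = X
        truth.labels[parent] = "parent"
        c1 = rng.binomial(X, p1)
        c2 = rng.binomial(X, p2 / (1 - p1)) if p2 > 0 else 0
        counts[parent] = counts.get(parent, 0) + (X - c1 - c2)
        if c1:
            # multinomial allocation over the 3L possible 1-SNP variants
            alloc = rng.multinomial(c1, np.full(3 * L, 1.0 / (3 * L)))
            for idx in np.flatnonzero(alloc):
                pos, alt = divmod(int(idx), 3)
                base = parent[pos]
                alt_base = [b for b in CANONICAL_BASES if b != base][alt]
                var = parent[:pos] + alt_base + parent[pos + 1 :]
                counts[var] = counts.get(var, 0) + int(alloc[idx])
                truth.labels.setdefault(var, "technical_variant")
        for _ in range(int(c2)):
            pos = rng.choice(L, size=2, replace=False)
            var = list(parent)
            for pp in pos:
                choices = [b for b in CANONICAL_BASES if b != parent[pp]]
                var[pp] = choices[rng.integers(3)]
            vs = "".join(var)
            counts[vs] = counts.get(vs, 0) + 1
            truth.labels.setdefault(vs, "technical_variant")

    reads = [
        CollapsedRead(seq, n, {library: n})
        for seq, n in sorted(counts.items())
        if n > 0
    ]
    reads.sort(key=lambda r: (-r.abundance_total, r.sequence))
    return reads, truth


def as_raw_reads(
    collapsed: list[CollapsedRead], prefix: str = "r", max_total: int = 2_000_000
) -> list[RawRead]:
    """Expand a collapsed set into individual read objects (small sets only)."""
    total = sum(r.abundance_total for r in collapsed)
    if total > max_total:
        raise ValueError(f"refusing to expand {total} reads")
    out = []
    i = 0
    for read in collapsed:
        for lib, n in read.abundance_by_library.items():
            for _ in range(n):
                out.append(RawRead(f"{prefix}{i}", read.sequence, lib))
                i += 1
    return out


# ---------------------------------------------------------------------------
# designed hairpin precursors


@dataclass
class PrecursorDesign:
    """A designed stem-loop with known ground-truth geometry."""

    sequence: str
    structure: str
    mature_site: tuple[int, int]
    star_site: tuple[int, int]

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_site[0] : self.mature_site[1]]

    @property
    def star(self) -> str:
        return self.sequence[self.star_site[0] : self.star_site[1]]

    @property
    def designed_pairs(self) -> list[tuple[int, int]]:
        stack, pairs = [], []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                pairs.append((stack.pop(), i))
        return pairs


def design_precursor(
    rng: np.random.Generator | None = None,
    mature_len: int = 21,
    stem_mismatches: int = 2,
    loop_len: int = 12,
    stem_ext: int = 25,
    overhang: int = 2,
) -> PrecursorDesign:
    """Construct a hairpin precursor around a random mature sequence.

    Layout (5'->3'): paired extension | mature | loop | star arm | paired
    extension, where the star arm is the reverse complement of the mature
    carrying ``stem_mismatches`` substitutions, and the star interval is
    recorded with the 2-nt 3' overhang convention of the excised duplex.
    """
    rng = rng or np.random.default_rng(0)
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    if not (0 <= stem_mismatches <= mature_len // 3):
        raise ValueError("stem_mismatches out of range")
    mature = random_seq(rng, mature_len)
    star_arm = list(revcomp(mature))
    mism_pos = sorted(rng.choice(mature_len, size=stem_mismatches, replace=False))
    for pos in mism_pos:
        choices = [b for b in CANONICAL_BASES if b != star_arm[pos]]
        star_arm[pos] = choices[rng.integers(3)]
    star_arm = "".join(star_arm)
    ext5 = random_seq(rng, stem_ext)
    ext3 = revcomp(ext5)
    loop = random_seq(rng, loop_len)
    seq = ext5 + mature + loop + star_arm + ext3

    n = len(seq)
    arm = stem_ext + mature_len
    structure = ["."] * n
    # star arm position k (0-based within star_arm) faces mature base
    # mature_len-1-k; mismatched star positions stay unpaired
    mism_set = set(mism_pos)
    for i in range(arm):
        j = n - 1 - i
        if i < stem_ext:
            structure[i], structure[j] = "(", ")"
        else:
            mature_idx = i - stem_ext              # position in mature
            star_idx = mature_len - 1 - mature_idx  # position in star arm
            if star_idx not in mism_set:
                structure[i], structure[j] = "(", ")"
    m0 = stem_ext
    m1 = m0 + mature_len
    s0 = m0 + mature_len + loop_len + overhang
    s1 = min(n, s0 + mature_len)
    return PrecursorDesign(seq, "".join(structure), (m0, m1), (s0, s1))


def emit_profile_reads(
    design: PrecursorDesign,
    mature_abundance: int,
    star_abundance: int = 0,
    wobble_frac: float = 0.1,
    rng: np.random.Generator | None = None,
    library: str = "lib1",
) -> list[tuple[str, int, str]]:
    """Reads from the mature and star sites of a designed precursor.

    A ``wobble_frac`` fraction of each site's abundance is spread over
    +-1 nt offsets and +-1 nt length jitter (imprecise duplex excision);
    the loop region emits nothing. Returns ``(sequence, count, library)``
    tuples with counts summing exactly to the requested abundances.
    """
    rng = rng or np.random.default_rng(0)
    if mature_abundance < 1:
        raise ValueError("mature_abundance must be >= 1")
    out: list[tuple[str, int, str]] = []
    for (a, b), abundance, label in (
        (design.mature_site, mature_abundance, "mature"),
        (design.star_site, star_abundance, "star"),
    ):
        if abundance <= 0:
            continue
        n_wobble = int(round(wobble_frac * abundance))
        out.append((design.sequence[a:b], abundance - n_wobble, library))
        if n_wobble:
            variants = []
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    if (da, db) == (0, 0):
                        continue
                    va, vb = a + da, b + db
                    if 0 <= va < vb <= len(design.sequence) and vb - va >= 18:
                        variants.append(design.sequence[va:vb])
            alloc = rng.multinomial(n_wobble, np.full(len(variants), 1.0 / len(variants)))
            for seq, cnt in zip(variants, alloc):
                if cnt:
                    out.append((seq, int(cnt), library))
    return out


def emit_degradation_reads(
    window: str,
    n_reads: int,
    rng: np.random.Generator | None = None,
    length_range: tuple[int, int] = (18, 28),
    antisense: bool = False,
    copies_range: tuple[int, int] | None = None,
    library: str = "lib1",
) -> list[tuple[str, int, str]]:
    """Uniform mRNA-degradation reads over a window.

    Start positions are uniform over the window and lengths uniform in
    ``length_range``. With ``antisense=True`` reads come from the reverse
    strand. ``copies_range`` optionally draws a log-uniform abundance per
    sampled read (default: single copies).
    """
    rng = rng or np.random.default_rng(0)
    if len(window) < 50:
        raise ValueError("degradation window must be >= 50 nt")
    out = []
    if n_reads <= 0:
        return out
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_reads)
    starts = rng.integers(0, len(window) - lengths + 1)
    copies = (
        log_uniform_int(rng, *copies_range, size=n_reads)
        if copies_range
        else np.ones(n_reads, dtype=int)
    )
    for s, L, c in zip(starts, lengths, copies):
        seq = window[int(s) : int(s) + int(L)]
        if antisense:
            seq = revcomp(seq)
        out.append((seq, int(c), library))
    return out


# ---------------------------------------------------------------------------
# adapter ligation and the full experiment


def ligate_adapters(
    insert: str,
    spec: AdapterSpec | None = None,
    read_cycles: int = 36,
    five_prime_tail: int = 0,
) -> str:
    """Embed an insert in adapter context, producing a fixed-cycle read.

    The read is [last ``five_prime_tail`` bases of the 5' adapter] + insert
    + [head of the 3' adapter], truncated to ``read_cycles``; the inverse of
    adapter trimming on error-free reads.
    """
    spec = spec or AdapterSpec()
    if len(insert) + five_prime_tail >= read_cycles and len(insert) < read_cycles:
        raise ValueError("five_prime_tail leaves no room for the 3' adapter")
    if len(insert) >= read_cycles:
        raise ValueError(
            f"insert of length {len(insert)} cannot fit in {read_cycles} cycles"
        )
    tail = spec.five_prime[-five_prime_tail:] if five_prime_tail else ""
    head_len = read_cycles - len(tail) - len(insert)
    if head_len > len(spec.three_prime):
        # pad with adapter followed by poly-A (sequencer runs off the template)
        head = spec.three_prime + "A" * (head_len - len(spec.three_prime))
    else:
        head = spec.three_prime[:head_len]
    return tail + insert + head


@dataclass
class SimulationConfig:
    """Study conditions for a full simulated experiment.

    Defaults mirror the real dataset's structure at desk scale: parent
    abundances log-uniform over ~5 decades, substitution errors at
    p = 7e-4, 36-cycle reads, sharply localized precursor profiles and
    uniform degradation windows.
    """

    seed: int = 0
    n_parents: int = 30
    parent_length: int = 21
    abundance_law: tuple[float, float] = (10, 1e6)
    p_error: float = 0.0007
    read_cycles: int = 36
    n_precursors: int = 20
    n_degradation_windows: int = 20
    n_antisense_windows: int = 0
    degradation_reads_per_window: int = 40
    degradation_copies: tuple[int, int] = (1, 200)
    mature_abundance_range: tuple[int, int] = (50, 2000)
    star_fraction: float = 0.1
    wobble_frac: float = 0.1
    n_contaminants: int = 30
    contaminant_copies: tuple[int, int] = (12, 500)
    adapters: AdapterSpec = field(default_factory=AdapterSpec)
    libraries: tuple[str, ...] = ("GP", "Pallas")

    def __post_init__(self):
        if not (0 <= self.p_error < 0.1):
            raise ValueError("p_error must be in [0, 0.1)")
        for name in ("n_parents", "n_precursors", "n_degradation_windows",
                     "n_contaminants", "degradation_reads_per_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedExperiment:
    """Everything a full pipeline run needs, plus the ground truth."""

    raw_reads: list[tuple[str, int, str]]   # (36-cycle sequence, count, library)
    contaminants: ReferenceCollection
    repeats: ReferenceCollection
    genomic: ReferenceCollection
    truth: GroundTruth
    config: SimulationConfig


def make_contaminant_collection(
    rng: np.random.Generator, n_records: int = 6, length: int = 800
) -> ReferenceCollection:
    """Synthetic decoy collection standing in for rRNA/tRNA/snoRNA
    databases (labelled synthetic; no real database content)."""
    records = []
    classes = ("rRNA", "tRNA", "snoRNA")
    species = ("barley", "wheat", "rice")
    for i in range(n_records):
        cls = classes[i % len(classes)]
        records.append(
            ReferenceRecord(
                f"syn_{cls}_{i}", random_seq(rng, length), species[i % len(species)], cls
            )
        )
    return ReferenceCollection(records)


def make_repeat_collection(
    rng: np.random.Generator, n_records: int = 4, length: int = 1200
) -> ReferenceCollection:
    records = [
        ReferenceRecord(f"syn_repeat_{i}", random_seq(rng, length),
                        ("wheat", "rice")[i % 2], "repeat")
        for i in range(n_records)
    ]
    return ReferenceCollection(records)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Build a complete synthetic experiment: error population, planted
    hairpin precursors embedded in related-species 'genomic' references,
    degradation windows, contaminants, everything ligated into 36-cycle
    reads. Byte-deterministic for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(true_p=config.p_error)
    raw: list[tuple[str, int, str]] = []
    libraries = config.libraries

    def lib(i):
        return libraries[i % len(libraries)]

    # 1. sequencing-error population (random transcript fragments)
    if config.n_parents:
        pop, pop_truth = simulate_error_population(
            config.n_parents, config.parent_length, config.abundance_law,
            config.p_error, rng,
        )
        truth.labels.update(pop_truth.labels)
        truth.parents.update(pop_truth.parents)
        for i, read in enumerate(pop):
            if len(read.sequence) < config.read_cycles:
                raw.append(
                    (ligate_adapters(read.sequence, config.adapters,
                                     config.read_cycles), read.abundance_total, lib(i))
                )

    # 2. planted hairpin precursors inside "genomic" references
    genomic_records = []
    species_cycle = ("rice", "brachypodium", "barley", "wheat")
    for i in range(config.n_precursors):
        design = design_precursor(rng)
        truth.designs.append(design)
        flank5, flank3 = random_seq(rng, 300), random_seq(rng, 300)
        ref_seq = flank5 + design.sequence + flank3
        genomic_records.append(
            ReferenceRecord(f"syn_mir_locus_{i}", ref_seq,
                            species_cycle[i % 2], "genomic")
        )
        mature_ab = int(log_uniform_int(rng, *config.mature_abundance_range))
        star_ab = max(int(round(config.star_fraction * mature_ab)), 0)
        for seq, count, library in emit_profile_reads(
            design, mature_ab, star_ab, config.wobble_frac, rng, lib(i)
        ):
            truth.labels.setdefault(seq, "mirna" if seq == design.mature else (
                "star" if seq == design.star else "wobble"))
            raw.append((ligate_adapters(seq, config.adapters, config.read_cycles),
                        count, library))

    # 3. degradation windows (uniform profiles) in their own references;
    # sense-antisense windows emit reads in both orientations
    n_deg = config.n_degradation_windows
    for i in range(n_deg + config.n_antisense_windows):
        both_strands = i >= n_deg
        window = random_seq(rng, 300)
        ref_seq = random_seq(rng, 150) + window + random_seq(rng, 150)
        genomic_records.append(
            ReferenceRecord(f"syn_deg_locus_{i}", ref_seq, "rice", "genomic")
        )
        n_per = config.degradation_reads_per_window
        batches = (
            [(n_per - n_per // 2, False), (n_per // 2, True)]
            if both_strands
            else [(n_per, False)]
        )
        for n_batch, antisense in batches:
            for seq, count, library in emit_degradation_reads(
                window, n_batch, rng,
                antisense=antisense, copies_range=config.degradation_copies,
                library=lib(i),
            ):
                truth.labels.setdefault(
                    seq, "antisense" if both_strands else "degradation"
                )
                raw.append((ligate_adapters(seq, config.adapters, config.read_cycles),
                            count, library))

    # 4. contaminants copied from the decoy collections
    contaminants = make_contaminant_collection(rng)
    repeats = make_repeat_collection(rng)
    for i in range(config.n_contaminants):
        source = contaminants.records[int(rng.integers(len(contaminants)))]
        L = int(rng.integers(20, 25))
        s = int(rng.integers(0, len(source.sequence) - L + 1))
        seq = source.sequence[s : s + L]
        truth.labels.setdefault(seq, "contaminant")
        raw.append((ligate_adapters(seq, config.adapters, config.read_cycles),
                    int(log_uniform_int(rng, *config.contaminant_copies)), lib(i)))

    genomic = ReferenceCollection(genomic_records)
    return SimulatedExperiment(raw, contaminants, repeats, genomic, truth, config)
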