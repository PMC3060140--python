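# Methods

This note documents the models, parameter choices and numerical decisions
behind `mirseeker`, and what the synthetic benchmarks do and do not show.

## Setting and assumptions

The pipeline targets deep small-RNA sequencing of a species whose genome is
not available. Consequences baked into the design:

* reads cannot be error-corrected against a genome, so technical variants
  must be recognised statistically, from relative abundances;
* sequencer base qualities are ignored by design: published comparisons of
  quality strings against ground truth show them underestimating the true
  substitution rate severalfold, and the most troublesome errors ride on
  extremely abundant parents whose error copies are themselves abundant;
* precursor evidence comes from *related species*: a hairpin found in a
  relative's genome around a read's mapping site is treated as necessary
  (not sufficient) evidence that the read is a mature miRNA.

## Sequencing-error model

Let *p* be the probability, per sequenced copy and per base, of one
*specific* substitution N→N′ (so the total per-base error rate is 3*p*),
assumed independent of base identity and position. Under the resulting
multinomial model each of the 3*L* specific single-substitution variants of
a parent of length *L* and abundance *X* is absent from all copies with
probability (1−*p*)^*X*, giving the expected number of distinct 1-SNP
variants

    Y(L, p, X) = 3L [1 − (1 − p)^X]

which is 0 at X=0, strictly increasing in X, and saturates at 3L (63 for a
21-mer). At p = 7×10⁻⁴, Y(21, p, 100) ≈ 4.3: sequences with about a
hundred copies already carry variants. The defined-but-crude companion
quantity 1−(1−p)^L (the chance a read carries at least one error when p is
read as a per-base rate) is exposed as `per_read_error_rate`; note that
interpreting p as the specific-substitution probability makes the actual
per-read error rate 1−(1−3p)^L. The package reports fitted p̂ and leaves the
conversion to the caller rather than privileging either per-read figure.

**Fitting.** For each unique sequence of the fit length, the observed
variant count is its number of *strictly less abundant* Hamming-1
neighbours (variants are the low-abundance accompaniment of a parent;
counting only downward edges keeps a variant's own count near zero,
consistent with the curve at small X). Counts are aggregated in log2
abundance bins (geometric-mean X, mean Y per bin) and p̂ minimises the
squared error against Y(L, p, X) over log₁₀p in [10⁻⁵, 10⁻²] (bounded
scalar minimisation, xatol 10⁻⁷ in log space). The fit refuses to run on
data spanning less than two decades of abundance; with no variants at all
it returns the lower bound with a warning. A log-spaced grid search over
the same interval serves as an independent cross-check and agrees with the
optimiser to well under 5% on simulated data. The default fit length is 21
(the dominant small-RNA length class; 24 is the usual alternative).

**Culling rule.** A read is removed iff its abundance is below 12, or it
has a strictly more abundant Hamming-1 neighbour and its abundance is
below 0.12% of the best such neighbour. Both thresholds are the method's
published operating point and are configurable. Culling is a single pass
against pre-cull abundances (not iterated), ties never cull, and the
globally most abundant sequence is always retained.

## Adapter trimming

Adapters are found by a stepwise anchor search: for the 5′ adapter, its
rightmost k bases (k = 17→10, allowed mismatches 4,4,3,3,2,1,0,0) matched
within the first k+2 bases of the read; for the 3′ adapter, its leftmost k
bases (k = 22→7) searched left-to-right, first hit wins. The 3′ interior
mismatch allowances decay *quadratically* between the fixed endpoints
(22 bases/8 mismatches → 7 bases/1 mismatch): with a linear decay,
mid-length anchors (e.g. 13 bases with 4 mismatches) match random insert
sequence at ~10⁻³ per position, which integrated over a read would break
the ≥99% round-trip recovery the trimmer is held to. Anchors may overhang
the read end by up to 2 nt, but overhanging matches must be exact — a
truncated anchor carries too little information to spend a mismatch budget
on. Homopolymer filtering (runs > 6 nt) precedes trimming; trimmed inserts
outside 18–35 nt are gated out, which also removes untrimmed 36-cycle
reads.

## Matching and mapping

All read-to-reference matching is full-length, ungapped, substitutions
only, on both strands — at ≤3 mismatches over ≤35 nt, gapped alignments
cannot win, and this keeps an exact sliding-window oracle feasible in
tests. Stringency is tiered by reference species: contaminant filtering
uses ≤1 mismatch for the study species and close relatives, ≤3 otherwise
("erring on the conservative side": any tier that accepts removes the
read). Genomic mapping uses exact/1/3 mismatches for own/close/distant
species, with the distant tier additionally bounded by requiring the
alignment score (match +1, mismatch −1) to reach 80% of its maximum —
equivalently m ≤ ⌊0.1·L⌋, the tighter bound for reads under 30 nt.

## Folding and hairpin screening

The built-in folder maximises a pairing score (GC=3, AU=2, GU=1, +1 per
stacked pair, minimum loop 3 nt) with a two-matrix dynamic programme and a
fixed traceback preference (pairing > left-unpaired > right-unpaired >
bifurcation; stacking > branching inside a helix), so structures are
deterministic across runs and platforms. It is a structure-recovery tool,
not a thermodynamic model: on designed precursors it recovers >99% of
ground-truth stem pairs on average, which is all the downstream screen
consumes. Reported scores are negated pairing scores (lower = more
stable); the ViennaRNA bindings can be swapped in behind the same contract
(`fold(seq, engine="vienna")`), where scores are free energies.

Candidate windows around each mapping site come from the flank grid
{(0,250), (250,0), (60,190), (190,60), (125,125)} capped at 300 nt —
chosen to span typical plant pre-miRNA lengths; no published window sizes
exist for this step. The hairpin screen then requires, in order: the
mature site not in a terminal loop and not self-paired; ≤4 unpaired mature
bases; no internal unpaired run >2 within the mature arm; a locatable star
interval on the opposing arm (partner span, shifted 2 nt toward its 3′ end
— the duplex overhang convention); and ≥50% of the window paired. These
defaults emulate the common plant-miRNA screening criteria; the exact
thresholds used by any particular published screen are not recoverable, so
all are exposed in `HairpinCriteria` and nothing downstream assumes these
defaults reproduce any published cluster count.

## Clustering and families

Reads passing the screen are clustered transitively at Smith-Waterman
similarity >0.6 of the maximum attainable score, defined as
min(len(a),len(b))·match under match +1 / mismatch −1 / gap −2 (the
scoring scheme is a common default; it is configurable). Clusters whose
precursor windows overlap or abut on the same reference and strand are
merged. Mature sequences with more than 3 supporting reads join miRNA
families by transitive Levenshtein distance ≤3; a known-catalog sequence
landing in a family donates its name. Representatives of
length-variant/wobble groups are the most abundant member, ties broken
lexicographically so reruns are stable.

## Profile classification

For each cluster the best passing precursor is chosen by (hit mismatches,
fold score): preferring the orientation in which the defining read matches
with fewest mismatches resolves the strand, because a hairpin's reverse
complement is also a hairpin and would otherwise occasionally win with all
reads "antisense". All reads are then placed on the precursor (≤3
substitutions, both strands), keeping only each read's minimum-mismatch
placements — on a hairpin, an arm read also aligns antisense to the
opposite arm purely by complementarity, and counting those echoes would
make every genuine precursor look sense-antisense transcribed.

Peaks are maximal runs with sense depth ≥5% of the maximum. The decision
order is: (1) CODING_ORF if the window contains an AUG-anchored open
reading frame ≥80 codons (both strands, three frames; ORFs may run off the
window); (2) SENSE_ANTISENSE if ≥10% of placed read mass is antisense;
(3) DEGRADATION if ≥80% of positions are covered with no single ≤26-nt
peak holding ≥50% of the read mass; (4) MIRNA_TWO_PEAK for exactly two
≤26-nt peaks on opposite sides of the terminal loop with ≤2% of read mass
between them; (5) MIRNA_SINGLE_PEAK for one such peak; (6)
ATYPICAL_LOCALIZED when total peak span is ≤60 nt; else DEGRADATION.
Confidence is a pure function of the label: two peaks → `***` (mature =
most abundant read in the dominant peak, star = most abundant in the
other), one peak → `**`, atypical-localized → `*`.

The ORF threshold deserves a note: "substantial ORF" has no published
numeric definition, and on *random* 300-nt windows an AUG-anchored ORF of
≥50 codons occurs by chance in roughly a third of windows — a rule at 50
would dominate the classification of non-coding loci, whereas the
exclusion is described as affecting only a limited number of clusters. At
80 codons (240 nt, most of a 300-nt window) the chance rate is a few
percent. All thresholds live in `ClassifierThresholds` and are logged into
the run manifest.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the method relies on:
log-uniform parent abundances over ~5 decades; exact multinomial
allocation of 0/1/2-error copies (so distinct-variant counts follow
Y(L,p,X) by construction of the model, not by fitting); designed
stem-loops (25-nt paired extensions + 21-nt mature + 12-nt loop + star arm
with 2 mismatches, ~104 nt total) embedded in random "genomic" references;
mature/star read emission with ±1-nt wobble at 10% and a silent loop;
uniform-start degradation reads (18–28 nt) with optional antisense
emission; contaminant reads copied from synthetic labelled decoys; and
adapter ligation into 36-cycle reads. Default experiment scale — 20
precursors, 20 degradation windows, 30 error parents, ~10⁵–10⁶ total read
copies — keeps a full run around half a minute on one CPU while exercising
every stage.

It does **not** emulate: position- or context-dependent error rates
(uniformity is the same simplifying assumption the error model itself
makes; a hook exists), correlated multi-errors, ligation biases, real
repeat families or real contaminant databases, expression differences
between libraries, or genuine coding sequence (degradation windows are
random sequence, which is why a chance-ORF exclusion still counts as a
correct rejection in the discrimination benchmarks). Passing the synthetic
benchmarks therefore demonstrates internal correctness of each stage and
of their composition under the model's own assumptions — not performance
on real libraries, where database completeness and error-rate structure
dominate.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.Generator`; a fixed seed
  makes the generator byte-deterministic and the pipeline's candidate
  table identical across reruns (all orderings are canonicalised:
  abundance-then-lexicographic sorts, sorted components, fixed traceback).
* Dynamic-programming kernels (folder, Smith-Waterman) are numba-compiled;
  plain-Python oracles for both live in the package/tests and are held to
  exact agreement.
* Levenshtein distances use edlib, validated in tests against a quadratic
  DP oracle.
* Degenerate inputs: empty read sets produce empty tables and zeroed
  manifests; empty reference collections match nothing (with a warning);
  an all-zero profile yields no peaks; a variant-free graph fits p at the
  lower bound with a warning rather than failing.
* Problem sizes in the test-suite and acceptance benchmarks (150 fit
  parents, 100 cull parents, 100+100 classifier profiles, the default
  experiment scale above) were chosen as the smallest sizes at which the
  statistics they check are stable.

## Known limitations

* Precursors with multiple mature miRNAs per hairpin are not modelled
  separately; they surface as atypical profiles.
* The star-site estimate is interval arithmetic on the pair table, not a
  duplex re-fold; on bulged stems it can be offset by the bulge width.
* The 80%-of-max-score mapping rule is interpreted with match +1 /
  mismatch −1; mappers with other scoring give different effective bounds.
* Family assignment treats the abundance threshold per dataset, so a
  sequence just under threshold in every library never joins a family
  even if its pooled abundance qualifies.
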