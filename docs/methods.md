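# Methods

## Model and assumptions

`tetrace` detects transposition events purely from discordant read-pair
geometry. The underlying model: a sequencing fragment of size around the
library median spans at most one structural breakpoint; the two mates of
a pair spanning an insertion breakpoint map on the reference one at the
acceptor flank and one inside the donor element, in an orientation and at
a distance determined by which breakpoint was spanned and whether the
element inserted in sense or antisense. For an element shorter than twice
the mean fragment length the two breakpoint clusters overlap over the
element's middle on the donor side; on the acceptor side they approach
the insertion point from both flanks but cannot overlap, since reads
crossing the unsequenced junction stay unmapped. The caller demands this
overlap/adjacency configuration between clusters of compatible
signatures, which is what suppresses the one-sided cluster noise generic
SV callers report.

Assumptions: alignments are coordinate-sorted, retain alternative
mappings (secondary records and/or XA tags) with edit-distance (NM)
annotations, and come from a library with a unimodal insert-size
distribution per orientation convention; duplicates and trimming are
handled upstream. The method is pair-based only — no split-read or
assembly evidence — so breakpoint precision is interval-level (roughly
the read length to the insert dispersion), not single-base.

## Statistics and classification

Insert size is the distance between the leftmost mapping coordinates of
the relabelled mates (template-length fields are not trusted). *M* and
*MAD* are the median and the **unscaled** median absolute deviation of a
sample of uniquely mapped proper-orientation pairs (default: first 10⁶);
no 1.4826 normal-consistency factor is applied anywhere. The concordance
window is (M − 3·MAD, M + 3·MAD). Boundary inserts (d equal to either
limit) are classified concordant so that classification is total: every
mapping gets exactly one of {Conc, Del, Ins, Dup, Inv, Trans}. A MAD of
zero raises a degenerate-library flag, since every non-median insert
would otherwise be discordant.

The proper orientation is a library-level preset: (−, +) after
relabelling for large-insert (mate-pair) libraries, (+, −) for
paired-end; all rules are orientation-relative, so both presets share
one code path.

**Two-threshold discordance veto.** Classification keeps the 3-MAD rules,
but a fragment is *extracted* as discordant only if none of its mapping
combinations is "near-proper": proper orientation, same chromosome,
insert within 6 MAD of M (configurable; floor 3 MAD). Rationale: with a
strict 3-MAD cut, a few percent of perfectly ordinary fragments fall in
the insert-size tails and count as discordant with *all* their mappings;
around near-identical repeat copies their cross-copy mappings form
coherent mirror-geometry cluster pairs that can satisfy the donor-overlap
condition and generate systematic false inter-copy calls. Every calling
rule requires distances far beyond the 6-MAD band (deletion calls need
unsequenced gaps above d_inf ≈ M − 3·MAD), so the veto removes noise
without touching callable signal. The only cost is blindness to events
whose donor lies within ~6 MAD of the acceptor, a region already
compromised by the overlap geometry itself.

Pairs with both mates in extreme-coverage regions (window depth above
median + 3·MAD *and* above an absolute floor of 1000×, on 100 bp
windows) are discarded before clustering; these are centromeric/rDNA
pileups where mappings carry no locational information.

## Clustering

Discordant records are partitioned by (signature, chromosome couple,
orientation couple); partitions are independent, so cost scales with
per-chromosome-pair depth. Within a partition each record is a point
(l_a, l_b); two points link when |Δl_a| ≤ X and |Δl_b| ≤ Y, and clusters
are the connected components of that graph. The implementation scans
points sorted by l_a with a trailing window of width X (the "seed
trail"), which is provably equivalent to the full transitive closure —
any link farther than X on the sorted axis is impossible — and is
verified against a brute-force graph oracle in the tests.

Same-signature clusters whose interval hulls are within a merge gap
(default: the current Y) on both axes are merged transitively, repairing
clusters split by local coverage drops. A merge whose result would
exceed the d_sup size limit on either axis is abandoned and the
components kept separate: merging exists to repair splits, and letting a
few stray tail pairs chain onto a genuine cluster must not push it past
the size filter. After merging, clusters wider than d_sup on either axis
or with support below `min_support` (default 10 for mate-pair libraries,
3 recommended for short-fragment ones) are removed.

## Calling, the grid and pooling

Cluster couples are paired side-by-side (sorted-mate sides together,
unsorted-mate sides together): the sides that overlap (≥ 1 bp) become the
donor (their hull is the reported element; the overlap in bp is a
confidence indicator), and the other sides must be disjoint with a
bounded gap whose hull (widened to ≥ 1 bp) is the reported acceptor. The
gap bound follows from fragment geometry: gap + donor span ≤ 2·M + 6·MAD
(= 2·d_sup), the same quantity that bounds callable translocation length.
A fixed gap cap (e.g. d_sup) is wrong for short elements — mates must
stay inside the element, pushing the acceptor-side ends ~2·d_sup − S
apart for an element of length S — and is therefore only applied when
explicitly configured. Event types: Del×Dup → sense insertion;
Inv(−,−)×Inv(+,+) → antisense insertion (inverted flag set);
Trans×Trans of different orientation → inter-chromosomal insertion
(inverted when the orientation couples are the equal-strand ones). A Del
cluster that overlaps no Dup cluster and whose unsequenced inner gap
exceeds d_inf is reported as a plain deletion ("size over d_inf" is read
as that gap; the cluster hull always exceeds d_sup for Del clusters,
which would make the condition vacuous). Ins-signature clusters are
written to the cluster table but trigger no event type. A residual Del
cluster overlapping an insertion's donor sets a cut-and-paste advisory
flag (`companion_del`); cut- vs copy-and-paste is not otherwise
discriminated.

The cluster+call pass runs over a grid of (X, Y) values — default
X = 50..1000 step 50, Y = 100..5000 step 100, i.e. 1000 attempts — and
the per-point results are pooled: the registry is seeded from the point
with the most distinct insertion sites (ties by total support, then by
(X, Y) order), other points' events join only when they overlap no
registry event on either side, and a recurrence (overlap on both sides,
same event type) keeps the higher-support instance. Scanning matters in
both directions: large Y repairs sparse clusters, while small Y detaches
isolated insert-tail members whose inclusion would push a cluster past
the d_sup size filter. Output lines sharing overlapping acceptor
intervals share an acceptor id; coordinates in files are 1-based
inclusive (0-based half-open internally).

## Annotation and donor scoring

Annotation is plain ≥ 1 bp interval intersection against named BED/GFF3
features; multiple names are comma-joined in genomic order and absences
render as `*`. Donor scoring, run per acceptor id with ≥ 2 candidate
donors: a discordant pair is *anchored* when one mate lies within the
acceptor interval extended by d_sup on each side; for each anchored
fragment the best per-candidate edit distance of the other mate's
mappings is collected, and the fragment votes for a candidate only when
it beats every other by at least `min_score_delta` (default 1 — a single
discriminating substitution changes edit distance by exactly one).
Indifferent fragments are discarded, so byte-identical candidates score
uniformly zero and are flagged ambiguous; a single-candidate group
renders `*`.

## Depth filter

Read depth on consecutive 100 bp windows is corrected for GC bias by
median-ratio normalisation on 1% GC bins (bins with < 20 windows fall
back to ratio 1; a GC-uniform genome is untouched). Windows with
corrected depth above median + 3·MAD (one-sided high — only excess
coverage creates the ambiguous-acceptor problem) merge into segments
tolerating a single-window gap, and acceptor sites overlapping a segment
longer than 500 bp are removed from the output, with the offending
segment logged.

## The simulator and what it does (not) emulate

The genome generator plants, on a random-sequence multi-chromosome
background, a TE family of three 3 kb copies (two identical, one with
five private substitutions), singleton elements of 1.5–2.5 kb, and runs
of two contiguous ~1 kb elements. It emulates the features that make
donor attribution and composite detection hard: exact and near-exact
repeats with unique flanks. It does **not** emulate nested/fragmented
repeat landscapes, segmental duplications, indel polymorphism between
copies, or GC-dependent coverage bias — passing tests demonstrate the
geometry and scoring logic, not robustness to every genomic context.

The injector copy-and-pastes donor spans (normal: exact annotated span;
composite: hull of a contiguous block; long: span plus a uniform
100–1000 bp flank per side; short: a uniform 30–70% interior sub-span),
reverse-complementing inverted events and duplicating `tsd_len` bases of
target sequence on both sides (default 5, range 0–10); event classes
default to equal proportions. It records the truth table and a piecewise
modified→reference coordinate map.

Two read-generation paths share the sampled fragments:

* **Exact placement** writes a coordinate-sorted SAM by construction:
  each read maps through the coordinate map (junction-crossing reads
  stay unmapped, as in real alignments), and reads inside a family copy
  receive one mapping per member with the edit distance implied by the
  substitutions covered. This is the noiseless, aligner-free path used
  by the benchmarks; it emulates a BWA-style all-hits alignment but not
  alignment errors, soft-clipping or mapping-quality artefacts.
* **Mate-pair FASTQ simulation** mirrors the circularisation protocol:
  fragment size from the long mode of a learned/declared empirical
  distribution, circularisation, splice length from the short mode,
  splice start uniform over the s + 1 offsets keeping the junction
  inside the splice — so a read is junction-chimeric with probability
  (rl − 1)/(s + 1), and the chimera rate *emerges* from geometry
  (expected fraction = E[(rl − 1)/(s + 1)] over splice lengths, times
  the non-contaminant share). Parasitic short fragments are emitted with
  probability given by the learned contamination odds (ratio of the two
  smoothed mode heights; split point at the inter-mode minimum; a
  unimodal library yields zero odds and a 300–700 bp fallback splice
  distribution). Per-cycle qualities are drawn from learned per-position
  histograms and substitution errors injected at the phred-implied
  probability, uniformly over the three alternative bases; indel errors,
  optical duplicates and adapter read-through are out of scope.

Identical inputs and seed give byte-identical FASTQ/SAM.

## Numerical and engineering choices

* All randomness flows through `numpy.random.default_rng` seeds;
  outputs are deterministically ordered (clusters by coordinates, events
  by acceptor) so equal configurations give byte-identical files.
* Combination enumeration per fragment is capped at 10 000 (mirroring
  aligner reporting caps); duplicate mappings are collapsed first.
* Degenerate inputs: empty alignment → empty outputs with headers; empty
  insert sample → hard error; zero-coverage mask input → empty mask with
  a warning; malformed annotation lines are skipped with line numbers.
* Mapping-quality/alignment-score variants of the donor-score margin
  were not implemented: edit distance is the one score both real
  BWA-style inputs and the placement fixtures guarantee.
* Whether `c_inf` (the lower coverage limit) has any downstream use is
  unresolved; it is computed and reported but unused.

## Problem sizes used by the test suite and the reproduction script

The end-to-end benchmark uses two 1 Mb chromosomes, 20 events (5 per
class, donors < 2·L), tsd 5, error-free placement at 20× with L = 3 kb
and fragment-size spread giving MAD ≈ 150 bp, and a 2 × 3 scaled grid
(X ∈ {100, 250}, Y ∈ {300, 600, 1500}) whose Y range brackets the
insert-tail gap scale like the full 1000-point grid does. Donor scoring
runs 50 replicates on a 120 kb chromosome with two 2 kb candidates
differing by three substitutions; simulator fidelity uses 10⁵ reads over
500 kb. Per-cycle quality fidelity is asserted at the 1% chi-square
level per cycle with the failure count held within the test's own
false-positive budget (99.9th percentile of Binomial(n_cycles, 0.01)),
a minimum p above 10⁻⁴ and a median p above 0.01 — a plain minimum-p
assertion over ~100 cycles would fail for most seeds even when the
simulator is exactly correct.

## Known limitations

Events whose donor lies within ~6 MAD of their acceptor are vetoed with
the insert-size tails; elements longer than 2·L lose the donor-side
overlap and are not callable (only per-side clusters remain); zygosity
is not inferred; chimeric/recombinant donors (template-switching
retrotransposition) are reported as two high-scoring candidates, not
reconstructed; insertions into high-coverage repeat arrays are
deliberately filtered out.
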