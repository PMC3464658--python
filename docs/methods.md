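# Methods

This note records the model, the parameter choices and the numerical
decisions behind `tandemdup`, in the spirit of a software methods appendix.

## Model and assumptions

A tandem duplication copies a segment of the sequence into its own
neighborhood; afterwards substitutions, short indels and occasional
inversions erode the similarity, and unrelated DNA (spacers) may separate
the copies. The detector assumes only that (i) copies of one unit lie at
most `T` apart, (ii) a duplication unit is at least `ℓ` long, and (iii) the
remaining similarity is strong enough for seeded local alignment to find
fragments of it. Duplications are intra-sequence by definition: multi-record
FASTA inputs are processed per sequence, and anchors never span sequences.

Coordinates are 0-based half-open everywhere in memory; GFF3 and the anchor
table are converted at the I/O boundary (1-based inclusive on disk), BED is
written as-is. This confines every off-by-one to the readers and writers.

## Parameters

| name | symbol | default | meaning |
|------|--------|---------|---------|
| `min_unit_length` | ℓ | 500 bp | smallest reportable duplication unit |
| `max_copy_gap` | T | 150 kb | largest gap between copies of one array |
| `max_chain_gap` | L | 40 kb | largest anchor gap inside a chain; array margin |
| `max_out_edges` | k | 15 | out-degree cap in the anchor graph |
| match/mismatch | | +1 / −3 | nucleotide scoring |
| gap open/extend | | −5 / −2 | a run of g gap columns costs −5 − 2g |
| `seed_k` | | 12 | exact seed length of the self-aligner |
| `xdrop` | | 20 | ungapped extension drop-off |
| `min_anchor_score` | | 30 | reporting threshold for anchors |
| `min_overlap` | | 0.5 | projection overlap joining two G2 vertices |
| `min_unit_fraction` | | 0.5 | unit coverage required of a tandem unit |
| `detection_threshold` | | 0.70 | evaluation coverage criterion |
| `max_enlarge` | | 0.25 | final TU enlargement per side |

ℓ, T, L, k and the nucleotide scoring are the method's published operating
point for a plant genome; seed length, X-drop and the anchor reporting
threshold are this implementation's defaults (the original aligner's
internals are not public) and are configurable. The gap-cost convention
(open + extend per gap column, so a 1-base gap costs −7) is one of the two
common readings of "open/extend −5/−2"; it only shifts anchor scores by a
constant per gap run and no downstream decision depends on the distinction.

## Anchoring

The built-in self-aligner indexes all unmasked exact 12-mers and their
reverse complements, pairs occurrences (ordered pairs only — the upper
half-plane — with the trivial diagonal excluded by construction), clusters
seed pairs greedily along dotplot diagonals (band 25 bp, seed gap ≤ 200 bp),
extends cluster ends by ungapped X-drop, and rescores each candidate by
walking the cigar of an edlib global alignment of the paired substrings
under the +1/−3/−5/−2 scheme. A diagonal run whose two intervals would
overlap is the signature of a tandem period shorter than the run; such runs
are split into consecutive period-length anchors instead of being discarded,
so contiguous repeats (period < run length) yield proper non-self-overlapping
anchors. DUST-style masking (window 64, threshold 20, the published
defaults — the triplet statistic `10·Σc(c−1)/2 / (n−1)`) soft-masks
low-complexity DNA before seeding; masked positions are excluded from
seeds but keep their coordinates, so output positions are unaffected.

Near-duplicate anchors (mutual overlap > 50% of the smaller interval on
*both* projections) are deduplicated greedily by score, then length, then
id. This keeps the max-flow fallback of the chainer (all single-anchor
chains) essentially free of pairwise conflicts.

## Chaining

The chain extraction is the method's core. Vertex costs `−m_a·score`
deliberately favor anchors lying in multiply-duplicated regions; edge costs
are the dotplot distance `2·max(Δ0,Δ1) − min(Δ0,Δ1)` (gaps clamped at 0 for
slightly overlapping projections, measured in traversal order so they stay
non-negative on the minus strand), rescaled so the mean edge cost equals the
absolute mean vertex cost. Midpoints order the anchors; full-interval gaps
measure distance.

Successive shortest paths run on the split-vertex unit-capacity network,
with node potentials initialized by topological relaxation on the acyclic
base network and maintained through reduced costs, so Dijkstra stays valid
despite negative vertex costs. The flow is solved independently per weakly
connected component: each component raises its flow one unit at a time and
stops at the first value whose decomposed chains all satisfy the t-chain
conditions (projections disjoint, gap ≤ T) and are pairwise disjoint on at
least one axis. Read globally instead, the stopping rule would accept the
very first flow value on any genome with several unrelated arrays (one
self-consistent chain), which cannot be the intended behavior; per-component
refinement also matches the termination argument, since maximum flow in a
component is all single-anchor chains. Augmentation costs are non-decreasing
within a component (flow-cost convexity), which the test suite asserts.

Chains from *different* components can still, rarely, overlap on both axes
through the gaps inside their projections; a final global sweep keeps the
cheaper chain of any such pair so that the returned set is unconditionally
consistent. Anchors not placed in any chain are forwarded to the array
stage as residual anchors.

## Arrays and the reference unit

G2 connects chains and residual anchors whose projection intervals overlap
by at least half of the smaller interval ("sufficient" overlap is not
quantified in the method's description; 0.5 is this package's default and is
configurable). Connected components, enlarged by L per side and clamped to
the sequence, are the tandem arrays; components containing only residual
anchors are kept but flagged `anchors_only`.

The reference unit candidate is the longest projection of the minimum-cost
chain (ties: longer projection, then chain id). Two reductions then
alternate:

1. **Head–tail reduction.** If some self-HSP of the candidate starts within
   `max(100 bp, 5%)` of its left end and finishes within the same margin of
   its right end, the candidate still contains a whole internal duplication
   (a tandem of 2k copies is also a tandem of k doubled copies); it is cut
   down to the HSP's first interval — one copy. This also phase-aligns the
   unit with the copy starts when spacers separate the copies, a case the
   50% rule below cannot reach (two copies plus a spacer longer than a copy
   are less than 50% self-similar).
2. **Self-similarity trimming.** While at least 50% of the candidate is
   covered by off-diagonal self-alignments, the candidate is trimmed past
   the inner boundary of the lowest-scoring HSP on whichever side lies
   closer to it, removing at least one HSP copy per iteration.

If a trim would undercut ℓ the untrimmed candidate is kept and flagged
`unresolved_unit`; arrays whose candidate is shorter than ℓ are discarded.

## Reconstruction

The unit is searched against its array region. The default backend is an
internal translated search: both sequences are translated in all frames
(region: both strands), exact 3-mer amino-acid seeds are clustered along
nucleotide diagonals, and each cluster is refined by a local BLOSUM62
alignment (gap −11/−1) whose coordinates map back to nucleotides. Stop
codons are treated as X. This keeps the test suite free of external
binaries; a nucleotide mode (the anchoring aligner run cross-sequence) and
an external TBLASTX mode (used when the binary is on PATH) are available
behind a flag, and on exact copies the translated and nucleotide modes agree
to within codon rounding.

Hits are chained in G3 with the same machinery as G1 but different
consistency semantics, because the per-chain t-chain test is meaningless
across two different axes. A G3 chain is *valid* when its region projection
is between ℓ and 1.5× the unit length (one chain should be one copy of the
unit) and its unit projection covers at least `min_unit_fraction` of the
unit. The flow runs to completion, every valid chain from any flow value's
decomposition enters a candidate pool, and weighted interval scheduling
(weight |cost|) selects the maximum-score region-disjoint subset — chains
sharing a hit necessarily overlap on the region, so the selection is
vertex-disjoint. A single stopping rule cannot serve here: the first
consistent flow value is value 1 whenever one dominant chain exists
(dropping all other copies), and any single later value fragments the
dominant chain before the weaker copies' chains have formed. Arrays whose
search returns no chained hits keep their reference unit and are flagged
`unit_only`.

Selected chains become tandem units, enlarged by up to 25% of their own
length per side (the ambiguity "25% of the TU vs of the unit" is resolved
toward the TU's own length); adjacent TUs split an insufficient gap equally
and nothing leaves the array region, so TUs stay pairwise disjoint.

## Simulation

The generator emulates exactly the structure the detector targets: i.i.d.
background at GC 0.36 (plant-like), 8 arrays per genome of 2–6 copies of a
600–3000 bp unit, copies mutated independently from the ancestral unit at
3% substitutions and 0.5% indels (geometric lengths, p = 0.7, capped at
50 bp), inverted with probability 0.05, separated by 200–2000 bp spacers,
all within a 300 kb background budget by default. The sequence is assembled
left to right, so truth coordinates are exact by construction;
`genome_length` is the background budget and the emitted genome is longer
by the planted copies and the net indel drift. The companion annotation
writer emits one gene per planted copy, decoy genes in the background, and
a protein-hit table connecting copies of one array (e-value 1e−10,
coverages ≥ 0.7), which exercises the evaluation module without BLASTP.

What the simulation does **not** model: transposons and satellite repeats
(so the background is cleaner than real intergenic DNA and anchor
specificity is optimistic), duplication-after-duplication histories, large
rearrangements, GC heterogeneity, and sequencing gaps. Passing the planted
recovery tests therefore demonstrates the pipeline's geometry and chaining
logic under controlled divergence, not its precision on a repeat-rich real
genome, where the DUST masking and the coverage-weighted vertex costs do
more of the work.

## Numerical and degenerate-case choices

- Strictness: "overlap" in all consistency tests means intersection length
  > 0; the evaluation uses ≥ 0.70 for unit/feature coverage but strictly
  > 0.70 for array-span coverage, following the stated criteria.
- Edge rescaling degenerates (no edges, or zero mean distance) to scale 1,
  logged.
- Dijkstra ties resolve by node id; chain, array and unit ids are assigned
  in deterministic (sequence, start, end) order, and every writer sorts its
  records, so reruns are byte-identical.
- Anchors with equal midpoints are incomparable under ≺ (strict order), so
  no edge joins them.
- Orphan statistics use 0.70 in both directions ("covers or is covered");
  only the detection direction is specified in the evaluation criteria.
- The TGA criterion measures coverage of the array *span* (first to last
  member gene), not of the union of member genes.

## Problem sizes

The shipped tests run the full pipeline on 20 simulated genomes of roughly
100–500 kb and one 300 kb-background benchmark genome, sizes at which a
laptop-class core finishes the whole suite in a few minutes; genome-scale
inputs run through the same code paths per sequence, with the anchor table
import available for swapping in a faster external self-aligner.

## Known limitations

- Sensitivity inherits the seed-and-extend floor: duplications older than
  roughly 15–20% nucleotide divergence rarely seed 12-mers densely enough
  to anchor (the translated re-search partially compensates inside arrays
  whose unit was found).
- The reference unit is a single interval; arrays whose copies are
  themselves mosaics of sub-units are reported at whichever granularity the
  head–tail reduction converges to, not hierarchically.
- Nested or intertwined arrays sharing a region are separated only as far
  as property (5) forces them apart.
- The translated search reports frame-local fragments around frameshifts;
  G3 chaining re-joins them, but unit boundaries can wobble by a few codons
  (hence the 25% enlargement step).
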