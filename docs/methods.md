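# Methods

## The model

A VNTR composite retrotransposon's central domain is modelled as an ordered
string of repeat units (RUs) drawn from a coded alphabet: twenty base types
A–T with lengths between 36 and 53 bp, plus named sequence variants of a
base type (prime marks and superscripts: B′, B^5′, C^T, …). An element's
domain is then a *repeat schema* — the token string plus coordinates — and a
subfamily is characterized by three layers of structure: a conserved 5′
array, optional internal expansion arrays (a short motif with one
run-variable position, e.g. K<sub>n</sub>GC′ with n = 1–4), and a conserved
3′ array ending at the terminal unit. Between two orthologous elements
(descendants of one insertion, hence diverging only at the DNA level) the
domain differs by copy-number indels whose breakpoints carry microhomology.

## The packaged repeat-unit library

Real RU consensus sequences exist only as figure panels, so the packaged
library is **synthetic**: `synthetic_data.build_ru_library` generates
GC-rich consensi (base composition A/C/G/T = 0.15/0.35/0.35/0.15)
deterministically (seed 20150516) under the published constraints:

* every unit length stated in the text is honoured exactly
  (A 40, B 39, D 40, E 41, G 41, H 42, I 47, K 49, N 53, O 42, P 42, Q 43,
  R 38 bp); lengths never stated are package choices in the plausible range
  (C 37, F 48, J 44, L 50, M 45, S 41, T 36 bp);
* A and B are the only derivation roots; S is flagged
  derivation-undetermined; the remaining parent edges follow the described
  lineage relationships (E/G/H/I arising with SVA_B, F/K/L derived from the
  intermediates, D/N/O/P in LAVA, Q/R in orangutan);
* C equals A with a 3 bp internal deletion and no substitutions, so that
  the documented 3 bp A↔C repeat-unit conversion is reproducible
  byte-exactly;
* separability: same-length types differ by ≥ 8 edits, any two types by
  ≥ 3 (the A–C pair sits exactly at 3, forced by the designed deletion),
  and variants lie within 3 edits of their base — so a unit carrying ≤ 2
  substitutions can never jump to another type (a length difference alone
  bounds the Levenshtein distance from below).

The packaged FASTA (`data/ru_library.synthetic.fasta`) is the frozen
builder output; a test asserts file/builder identity. Consequences for
interpretation: tests against this library validate the *algorithms*
(segmentation, array derivation, event calling), not the sequences of the
real alphabet; any conclusion tied to actual RU base composition would need
the real consensi.

## Segmentation

Minimum-cost tiling DP: `D(0)=0`,
`D(j) = min over (j−i) ∈ [W_min, W_max] of D(i) + unitcost(i,j) + τ`, with

* `unitcost` = minimum Levenshtein distance of `seq[i:j]` to any library
  entry (base types and variants); computed by a numba kernel that sweeps
  one edit-distance table per entry and start position, yielding the costs
  for **all** window widths at once; an independent edlib-based oracle
  re-derives these costs in the tests;
* an unclassified option 'X' at cost `⌈0.5·(j−i)⌉` — the cost a random
  GC-rich window pays, so real units always undercut it;
* `W_min=25, W_max=60` (unit lengths 30–50 bp plus the 53 bp N type, with
  margin), startup penalty `τ=2` against over-segmentation;
* ties broken by fewer tokens, then lexicographically smallest code string,
  then leftmost-longest first token (a second DP pass restricted to
  minimum-cost transitions);
* the final token may be shorter than `W_min`: it is matched against
  equal-length consensus *prefixes* at Hamming cost and flagged
  `truncated` (3′-variable ends are tolerated in the source material);
* sequences with > 10 % N are refused as assembly gaps; N mismatches every
  base including N.

Tokens are assigned `(type, variant)` by nearest type (a type's score is
the minimum over its base and variants), then nearest variant; identity
below 0.75 sends the token to 'X'. The 0.75 bar separates 37–53 bp units
with a few substitutions (identity ≥ 0.9) from random GC-rich strings
(identity ≈ 0.5–0.65 against this alphabet).

De-novo discovery sorts units by exact length, single-links within a length
class at identity ≥ 0.9, and takes a per-column majority consensus
(alphabetical tie-break, tied columns reported) — the majority-rule
procedure that produced the alphabet in the first place.

## Conserved arrays and motifs

The conserved 5′ array is derived greedily: extend the prefix P while the
fraction of schemata *starting with P* stays ≥ θ (default 0.7; the source
material never states its support level, so θ is a parameter). The suffix
is symmetric from the 3′ end. Where a second 5′ structure coexists (as in
LAVA_C1, where N-bearing and N-less variants are equally represented), the
best alternative continuations with ≥ 20 % support are reported instead of
being forced into one consensus.

A θ-greedy prefix necessarily absorbs the *constant leading edge* of an
internal expansion array (every element's interior starts with at least one
K), so two further steps recover the published delineation:

* **motif mining** scans whole run-length-compressed schemata (not just the
  strict interior, which the absorption would starve): repeated compressed
  subsequences of 2–6 symbols with at most one run-variable position,
  occurring ≥ 2 times in ≥ θ of elements; ranked by coverage
  (occurrences × length), with cyclic-rotation deduplication and
  containment filtering. The twice-per-element rule keeps single-copy
  structure such as the conserved prefix itself out of the motif list.
* **core arrays** trim the derived prefix of trailing tokens that belong to
  the top motif, and reduce the derived suffix to one complete motif
  instance plus its non-motif tail — which is exactly how the published 3′
  array KGC′T is written (one KGC′ copy plus terminal T).

Position-specific consensi are per-column majorities over the token
substrings occupying one conserved slot, restricted to elements whose
schema carries the conserved array at that slot (rejected if more than half
do not), at the modal substring length.

## Ortholog comparison

Indels between a pair (ordered long/short by length; polarity left
unresolved — without an outgroup insertion cannot be told from deletion)
are called in two stages: a token-level edit script localizes candidate
regions ('equal' token runs are verified at the nucleotide level, since
runs of unclassified tokens can hide length differences), windows are
widened across whole runs of any unit type seen in the edited region (the
script cannot know *which* copy of a tandem run changed) plus one anchor
token, and overlapping windows are merged. Within each window a numba
Gotoh global alignment with match +2, mismatch −3, gap open −5, gap extend
−1 (a gap of length L costs −5 − L) fixes the breakpoints; the affine
penalty keeps indels contiguous in GC-rich repeats, and the scoring is
exposed in `MechanismConfig`.

Events are left-normalized (deletions shift 5′-ward while flank and
segment ends match; insertions rotate likewise), and events closer than
10 bp are merged into one flagged complex event whose `inserted_bases`
carry the short-side replacement (a large indel can mask two independent
events).

Microhomology: with segment S, left flank Lf, right flank Rf,
`mh_exact_right = max m: S[:m]==Rf[:m]`, `mh_exact_left` symmetric, and
`mh_relaxed` the largest m with running identity ≥ 0.9 that ends on a
matching base — divergence after the event means identity inside a real
microhomology need not be 100 %, and 0.9 operationalizes that.

Mechanism labels are *compatibilities*, never exclusive calls: whole-unit
boundary-aligned events (checked across the indel's whole ambiguity range,
since normalization may park the representative one base off a token
boundary) are `precise_ru_indel`; ≤ 5 bp events that change the containing
token's best type are `ru_conversion_microindel`; `mh_mediated` at
mh ≥ 5 bp, `nahr_compatible` at mh ≥ 34 bp (the minimal efficient
processing segment), `slippage_compatible` when length + mh ≤ 200 bp (an
Okazaki-fragment span), `mmej_signature` when microhomology co-occurs with
inserted junction bases. `unclassified` only when nothing applies.

## Synthetic data

Element sets are drawn from subfamily grammars (key-value files under
`data/grammars/`): conserved prefix, interior (repeated motif with a
run-variable position, or an unstructured token pool for LAVA-like
interiors), conserved suffix, plus an optional alternative prefix with its
population fraction. Only the structures actually printed in the source
are copied verbatim (SVA_A "ABCA", SVA_F "ABCAAAB′CACAAF", interior
K<sub>n</sub>GC′, suffix "KGC′T", LAVA_E "ANBB"); other grammar content is
illustrative and consistent with the prose. Default n = 10 elements per
subfamily (the study's human sample size; 5–20 elsewhere) and substitution
rate 0.005/bp — a realistic within-subfamily divergence for young
subfamilies; no value is derivable from the text, so it is a package
choice. Substitutions are uniform over the three alternative bases; there
is no sequencing-error model because elements are assembly-derived.

Planted ortholog events copy the first m bases of the deleted span onto
the right flank of the ancestral haplotype before deleting, making the
designed microhomology the maximal exact one; designed mismatches inside
the tract model post-event divergence; flank bases are adjusted so the
planted representation is already left-normalized and the homology cannot
extend by accident. `make_random_planted_pair` places a single event on a
structureless GC-rich background (rejection-sampled until the design is
exact) — used wherever recovered microhomology must equal the designed
value, because on a tandem background a deleted unit's homology with its
neighbouring copies legitimately dominates. Ground truth (`SimTruth`)
replays to the emitted sequence byte-exactly, and a duplication's
truth coordinates are recorded in normalized (leftmost) form.

What the generator does *not* emulate: assembly gaps and truncations,
CpG-biased or lineage-specific substitution spectra, real RU base
composition, and recombination between elements. Passing tests therefore
demonstrate correct recovery of the modelled structure, not performance on
genome-derived sequence.

## Problem sizes and numerical choices

The test and acceptance workloads use 5–10 elements per subfamily
(matching the study's sample sizes), 50 sequences for the
segmentation-vs-enumeration oracle (≤ 200 bp, where exhaustive tiling
enumeration is exact and fast), 200 mutated-recovery trials, and 100
planted pairs each for the microhomology-oracle and recovery suites; these
sizes give stable rates while keeping a full run in minutes on one CPU.
Alignment matrices are int32; window sizes are bounded by run-aware
expansion, with the worst case (fully diverged unclassified sequences) a
single full-length global alignment. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
outputs everywhere, including the CLI.

## Known limitations

* The derived conserved arrays depend on θ; at θ = 0.7 an indel-polymorphic
  position present in ≥ 70 % of elements still enters the consensus.
* Motif mining caps patterns at 6 compressed symbols with one variable run;
  nested or doubly-variable arrays are reported only via their sub-patterns.
* `mh_relaxed` is a greedy scan, not an alignment; a microhomology
  interrupted by an indel (rather than substitutions) is underestimated.
* Merged complex events report replacement strings rather than attempting
  to re-split them into elementary events.
* Token-level localization assumes the schemata of the two orthologs are
  individually correct; systematic mis-segmentation of both haplotypes in
  the same region can displace a called breakpoint by a full unit.
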