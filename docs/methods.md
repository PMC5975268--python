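# Methods

## Model and conventions

A gene order is modelled as an unsigned permutation: genes are assumed
non-duplicated and non-overlapping, and strandedness is irrelevant
because a tandem duplication random loss (TDRL) never inverts genes.
Strand signs in input files are therefore parsed and dropped (with a
logged notice). A *circular* gene order is the rotation class of a
permutation; `tdrlkit` stores the rotation beginning with the smallest
gene label as the canonical representative, which makes class equality,
hashing and all output orderings deterministic. Positions are 1-based.
Labels may be integers or gene-name strings; `LabelMap` bridges the two.

A TDRL is the triple `(F, S, p)`: tandem-duplicate the whole genome
starting at origin gene `p`, keep the `F`-genes in the first copy and
the `S`-genes in the second. The origin is stored as a *gene*, not a
numeric position, so triples survive relabelling and rotation. Triples
with empty `F` or `S` are representable — they are identity maps and are
needed for the `2n²` identity-enumeration count — but operations that
require a proper rearrangement reject them explicitly.

## Distance

For linear orders the unit-cost TDRL distance is `⌈log₂ k⌉` where `k` is
the number of maximal value-consecutive increasing runs of the source
order relabelled by its positions in the target (`k = 1` gives distance
0 by convention). The circular distance is the minimum of the linear
distance over all `n × n` pairs of linearizations; choosing a single
linearization can overestimate it, which the tests demonstrate
constructively. This min-over-representatives definition is validated
empirically rather than proven: `bfs_distance_oracle` performs
breadth-first search over *all* `n·2ⁿ` triples (guarded to `n ≤ 8`,
with per-state neighbor caching) and agrees with the formula on every
ordered pair of 5-gene classes and on 100 seeded pairs each at
`n = 6, 7`.

## Enumeration

Enumeration of all equivalent TDRLs is descent-based. Fix an origin `p`
and write each of the `n` target linearizations as its position sequence
in `π_p`. A linearization contributes a triple exactly when that
sequence has one descent — `F` is the part before the descent, `S` the
part after — and a zero-descent sequence flags the identity case, where
every prefix cut of `π_p` (including empty `F` or `S`) fixes the order.
This is `O(n³)` overall and reproduces the counting laws structurally:
`2n` triples for a proper rearrangement (two per origin, `F/S` swaps of
each other), `2n²` for identity pairs. The implementation asserts both
counts, and the test suite checks set-equality against the `n·2ⁿ`
brute-force oracle for `n ≤ 8`. Avoiding the exponential scan matters:
the mitochondrial case study has `n = 38`.

Output order is deterministic — origins along the source's canonical
rotation, the "direct" labeling (origin gene in `S`) before its swap —
so TSV and SVG outputs are byte-identical across runs.

## Minimal partial duplications

Every whole-genome TDRL is realizable as a partial duplication of a
contiguous window of `π_p`. The minimal window runs from the first
`S`-gene to the last `F`-gene; genes before it are untouched `F`-prefix,
genes after it untouched `S`-suffix, and the window never wraps past the
end of `π_p`. The window is a property of the *labelled* triple: `(F, S,
p)` and `(S, F, p)` generally have different windows, and per-origin
reporting (matrix rows, minimum-duplication search) uses the smaller of
the two, breaking ties toward the smaller `|F|`, then lexicographically.
Minimality was verified exhaustively during development against a
replacement oracle (simulate every contiguous window, compare rotation
classes) for *all* non-identity triples at `n = 4..6`; the shipped
property tests re-check seeded instances up to `n = 8`. The
partial-to-whole correspondence (`F = S′`, `S = N ∪ F′`, origin = gene
following the window) is exposed as `whole_from_partial` and round-trips
in tests.

The published figure convention may box the window of the labeling as
drawn rather than the per-origin minimum; since the figure is not
machine-readable, the per-origin minimum is adopted and both labelings'
windows are always present in the TSV.

## Constraint filters

*Conserved groups*: a TDRL respects a gene set `G` iff `G ⊆ F` or
`G ⊆ S` — the group is then lost from one copy jointly and never broken.
Groups are treated as sets even when supplied as ordered lines.

*Intergenic pairs*: an ordered pair `(x, y)` framing an intergenic
region of the target is explainable by a TDRL iff some third gene's lost
copy falls between `x` and `y`. Betweenness is evaluated on the
positional interval of `x` and `y` in `π_p`: if both genes keep the same
copy, a gene of the opposite set must lie strictly between them; if they
keep different copies, any gene strictly between them loses a copy in
the separating stretch. The alternative reading — arcs of the circular
2n-gene intermediate — contradicts the worked behaviour this
implementation reproduces (only the origin-2 TDRL of the eight-gene
example explains a region between genes 1 and 2, with witness gene 3),
and is therefore rejected. Pairs that are not adjacent in the target
trigger a warning but are still evaluated. Both filters are invariant
under swapping `F` and `S`.

## Synthetic data

`random_circular_order` draws a uniform permutation and canonicalizes
it, which is uniform over rotation classes (every class contains exactly
`n` representatives); `random_d1_pair` applies a uniformly drawn
non-identity TDRL (origin uniform, each gene in `F` with probability
1/2, identity maps rejection-sampled away), so generated pairs are at
distance exactly one by construction and the generating event is always
recoverable from the enumeration. Generators are pure functions of
`(parameters, seed)`. What they do *not* emulate: real mitochondrial
rearrangement is biased (hot spots, transcript-coupled losses), and real
annotations carry missing or duplicated genes; passing tests show
combinatorial correctness on clean permutations, not robustness to
annotation noise.

The bundled case-study pair (`data/psocoptera_synthetic.fa`) is a
**synthetic reconstruction**, not the annotated GenBank records: the
ancestral Pancrustacea mitochondrial gene order plus the unique circular
order at TDRL distance one from it whose maximal conserved segments are
exactly the six published ones and which carries the trnQ–nad2 and
cob–nad1 adjacencies framing the reported intergenic regions.
(Uniqueness: with all six multi-gene segments conserved and all other
adjacencies broken, the 15 breakpoint units must alternate strictly
between `F` and `S` along the origin representative, and the two
adjacency requirements fix the rotation.) That the reconstruction
reproduces the published 34-of-38 (origin `cox2`) and minimum 29-of-38
duplicated-marker counts is a strong consistency check computed by the
tests, not an input.

## Problem sizes and numerical choices

Exhaustive oracles are guarded (`n ≤ 8` for BFS, `n ≤ 10` for
brute-force enumeration) and raise with advice beyond that; the
polynomial paths run comfortably at `n = 38` and beyond. Property tests
use seeded or derandomised draws at `n ≤ 13`; oracle cross-checks use
all 5-gene pairs and 100 seeded pairs per direction at `n = 6, 7`.
Degenerate inputs: singleton orders are valid (`n = 1`); identity pairs
route to the `2n²` enumeration and are rejected by matrix rendering and
minimum-duplication search with explicit errors; empty-window partials
are rejected by `whole_from_partial`.

## Known limitations

- Only unit-cost TDRLs; weighted cost models and signed/oriented
  rearrangements (inversions, DCJ) are out of scope.
- Only the distance ≤ 1 case is enumerated; multi-event scenarios are
  not reconstructed.
- The circular-distance definition is empirical (oracle-validated), not
  accompanied by a proof.
- Conserved-segment detection considers same-direction matches only,
  consistent with TDRLs never inverting gene order.
- Figure markers (filter passes, minimum duplication) are computed
  automatically; the original figures placed them manually, so marker
  placement is an extension rather than a replication.
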