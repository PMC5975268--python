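# tdrlkit

Tandem duplication random loss (TDRL) rearrangement analysis for circular
gene orders, such as animal mitochondrial genomes.

A TDRL tandem-duplicates a contiguous stretch of genes and then loses one
copy of each duplicated gene. It is a major driver of mitochondrial gene
order evolution, but it is ambiguous: many distinct TDRL events transform
one observed gene order into another, so the event can never be
reconstructed from the two orders alone. `tdrlkit` computes TDRL distances
between circular gene orders and, for pairs one event apart, enumerates
the *complete* set of equivalent TDRLs, filters them by biological side
information, finds the ones duplicating the fewest genes, and draws the
result.

## Model

A circular gene order on `n` distinct genes is the rotation-equivalence
class `π°` of a permutation; `π_p` denotes the unique linearization
starting with gene `p`. A TDRL is a triple `(F, S, p)` where `(F, S)`
bipartitions the gene set: the whole genome is duplicated in tandem
starting at origin `p`, genes of `F` keep their first copy, genes of `S`
their second. The result is `F`-genes then `S`-genes, each in `π_p`
order; `(S, F, p)` yields the same circular order. For a proper
rearrangement exactly `2n` triples are equivalent (two per origin),
`2n²` for identity maps.

With unit event costs, the distance between linear orders is
`⌈log₂ k⌉`, where `k` counts the maximal value-consecutive increasing
runs of the source relabelled by target positions; the circular distance
minimizes this over all `n × n` linearization pairs (a fixed
linearization can overestimate it). Every TDRL is also realizable as a
*partial* duplication of just the window from the first `S`-gene to the
last `F`-gene of `π_p` — the minimal set of genes that must physically
duplicate.

## Worked example

```python
from tdrlkit import CircularGeneOrder, enumerate_equivalent_tdrls, \
    minimum_duplication_set, distance_both_directions

source = CircularGeneOrder(range(1, 9))
target = CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))
print(distance_both_directions(source, target))   # (1, 2)

result = enumerate_equivalent_tdrls(source, target)
print(len(result.entries))                        # 16
winners = minimum_duplication_set(result)
print(winners[0].window_size,                     # 4
      sorted({e.origin for e in winners}))        # [1, 2, 3, 7, 8]
```

The pair is one TDRL apart in the forward direction (two backwards — the
distance is directional), and sixteen equivalent triples explain it, e.g.
`({4,6}, {1,2,3,5,7,8}, 3)`: duplicate starting at gene 3, keep 4 and 6
in the first copy. Its minimal partial form duplicates only the window
`(3 4 5 6)`, and four genes is the minimum over all sixteen, attained at
origins 1, 2, 3, 7 and 8. Constraint filters narrow the set further:
requiring groups `{1,2}` and `{7,8}` to stay intact removes origins 2
and 8, and only the origin-2 TDRL can explain an intergenic region
between genes 1 and 2 (gene 3 is lost between them).

The scripts in `examples/` walk through each capability, including the
38-marker barklouse mitochondrial case study (`05_case_study.py`), where
the enumeration finds a TDRL duplicating 29 of 38 markers — five fewer
than the origin-`cox2` event suggested by tree-based reconstruction.
The bundled case-study orders are a synthetic reconstruction derived
from published constraints on the pair (see `tdrlkit.datasets`).

A thin CLI mirrors the library:

```sh
tdrlkit dist A.fa B.fa
tdrlkit enum A.fa B.fa --conserved groups.txt --min-dup --tsv out.tsv --svg fig.svg
tdrlkit conserved A.fa B.fa
tdrlkit simulate --n 10 --seed 7 --out pair
```

Gene-order files are FASTA-like: a `>name` header, then whitespace-
separated gene names (strand signs are parsed and ignored — a TDRL never
changes strandedness).

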